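{
 "ordering": "periphery-to-midline, anterior-to-posterior",
 "freqs_hz": [
  0.5,
  1.0,
  1.5,
  2.0,
  2.5,
  3.0,
  3.5,
  4.0,
  4.5,
  5.0,
  5.5,
  6.0,
  6.5,
  7.0,
  7.5,
  8.0,
  8.5,
  9.0,
  9.5,
  10.0,
  10.5,
  11.0,
  11.5,
  12.0,
  12.5,
  13.0,
  13.5,
  14.0,
  14.5,
  15.0,
  15.5,
  16.0,
  16.5,
  17.0,
  17.5,
  18.0,
  18.5,
  19.0,
  19.5,
  20.0,
  20.5,
  21.0,
  21.5,
  22.0,
  22.5,
  23.0,
  23.5,
  24.0,
  24.5,
  25.0,
  25.5,
  26.0,
  26.5,
  27.0,
  27.5,
  28.0,
  28.5,
  29.0,
  29.5,
  30.0,
  30.5,
  31.0,
  31.5,
  32.0,
  32.5,
  33.0,
  33.5,
  34.0,
  34.5,
  35.0,
  35.5,
  36.0,
  36.5,
  37.0,
  37.5,
  38.0,
  38.5,
  39.0,
  39.5,
  40.0
 ],
 "channel_neighborhoods": [
  [
   "TP7",
   "T7",
   "FT7",
   "C5",
   "CP5"
  ],
  [
   "C5",
   "CP5",
   "FC5",
   "P7",
   "F7"
  ],
  [
   "P7",
   "F7",
   "P5",
   "C3",
   "F5"
  ],
  [
   "C3",
   "F5",
   "CP3",
   "FC3",
   "AF7"
  ],
  [
   "FC3",
   "AF7",
   "PO7",
   "P3",
   "F3"
  ],
  [
   "P3",
   "F3",
   "PO3",
   "C1",
   "CP1"
  ],
  [
   "C1",
   "CP1",
   "AF3",
   "FC1",
   "Fp1"
  ],
  [
   "FC1",
   "Fp1",
   "P1",
   "O1",
   "F1"
  ],
  [
   "O1",
   "F1",
   "Fpz",
   "AFz",
   "Fz"
  ],
  [
   "AFz",
   "Fz",
   "FCz",
   "Cz",
   "CPz"
  ],
  [
   "Cz",
   "CPz",
   "Pz",
   "POz",
   "Oz"
  ],
  [
   "POz",
   "Oz",
   "Fp2",
   "F2",
   "O2"
  ],
  [
   "F2",
   "O2",
   "P2",
   "FC2",
   "AF4"
  ],
  [
   "FC2",
   "AF4",
   "PO4",
   "C2",
   "CP2"
  ],
  [
   "C2",
   "CP2",
   "F4",
   "AF8",
   "P4"
  ],
  [
   "AF8",
   "P4",
   "PO8",
   "FC4",
   "C4"
  ],
  [
   "FC4",
   "C4",
   "CP4",
   "F6",
   "P6"
  ],
  [
   "F6",
   "P6",
   "F8",
   "P8",
   "FC6"
  ],
  [
   "P8",
   "FC6",
   "FT8",
   "C6",
   "CP6"
  ],
  [
   "C6",
   "CP6",
   "T8",
   "TP8",
   "TP7"
  ],
  [
   "TP8",
   "TP7",
   "T7",
   "FT7",
   "C5"
  ],
  [
   "FT7",
   "C5",
   "CP5",
   "FC5",
   "P7"
  ],
  [
   "FC5",
   "P7",
   "F7",
   "P5",
   "C3"
  ],
  [
   "P5",
   "C3",
   "F5",
   "CP3",
   "FC3"
  ],
  [
   "CP3",
   "FC3",
   "AF7",
   "PO7",
   "P3"
  ],
  [
   "PO7",
   "P3",
   "F3",
   "PO3",
   "C1"
  ],
  [
   "PO3",
   "C1",
   "CP1",
   "AF3",
   "FC1"
  ],
  [
   "AF3",
   "FC1",
   "Fp1",
   "P1",
   "O1"
  ],
  [
   "P1",
   "O1",
   "F1",
   "Fpz",
   "AFz"
  ],
  [
   "Fpz",
   "AFz",
   "Fz",
   "FCz",
   "Cz"
  ],
  [
   "FCz",
   "Cz",
   "CPz",
   "Pz",
   "POz"
  ]
 ],
 "frequency_neighborhoods": [
  [
   0,
   1,
   2,
   3,
   4
  ],
  [
   3,
   4,
   5,
   6,
   7
  ],
  [
   6,
   7,
   8,
   9,
   10
  ],
  [
   9,
   10,
   11,
   12,
   13
  ],
  [
   12,
   13,
   14,
   15,
   16
  ],
  [
   15,
   16,
   17,
   18,
   19
  ],
  [
   18,
   19,
   20,
   21,
   22
  ],
  [
   21,
   22,
   23,
   24,
   25
  ],
  [
   24,
   25,
   26,
   27,
   28
  ],
  [
   27,
   28,
   29,
   30,
   31
  ],
  [
   30,
   31,
   32,
   33,
   34
  ],
  [
   33,
   34,
   35,
   36,
   37
  ],
  [
   36,
   37,
   38,
   39,
   40
  ],
  [
   39,
   40,
   41,
   42,
   43
  ],
  [
   42,
   43,
   44,
   45,
   46
  ],
  [
   45,
   46,
   47,
   48,
   49
  ],
  [
   48,
   49,
   50,
   51,
   52
  ],
  [
   51,
   52,
   53,
   54,
   55
  ],
  [
   54,
   55,
   56,
   57,
   58
  ],
  [
   57,
   58,
   59,
   60,
   61
  ],
  [
   60,
   61,
   62,
   63,
   64
  ],
  [
   63,
   64,
   65,
   66,
   67
  ],
  [
   66,
   67,
   68,
   69,
   70
  ],
  [
   69,
   70,
   71,
   72,
   73
  ],
  [
   72,
   73,
   74,
   75,
   76
  ],
  [
   75,
   76,
   77,
   78,
   79
  ]
 ]
}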
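# Default categorical labelling of the 33 grasp conditions.
#
# Schemes:
#   grasp_type     -- power | precision | intermediate
#   thumb_position -- abducted | adducted
#   object_shape   -- large_bar | small_bar | large_sphere | small_sphere |
#                     disk | card | scissors
#
# This assignment follows the common one-handed grasp repertoire and is a
# plausible default shipped as configuration data, not ground truth.
conditions:
  1:  {name: large_diameter,      grasp_type: power,        thumb_position: abducted, object_shape: large_bar}
  2:  {name: small_diameter,      grasp_type: power,        thumb_position: abducted, object_shape: small_bar}
  3:  {name: medium_wrap,         grasp_type: power,        thumb_position: adducted, object_shape: large_bar}
  4:  {name: adducted_thumb,      grasp_type: power,        thumb_position: adducted, object_shape: large_bar}
  5:  {name: light_tool,          grasp_type: power,        thumb_position: abducted, object_shape: small_bar}
  6:  {name: prismatic_4_finger,  grasp_type: precision,    thumb_position: abducted, object_shape: small_bar}
  7:  {name: prismatic_3_finger,  grasp_type: precision,    thumb_position: abducted, object_shape: small_bar}
  8:  {name: prismatic_2_finger,  grasp_type: precision,    thumb_position: abducted, object_shape: small_bar}
  9:  {name: palmar_pinch,        grasp_type: precision,    thumb_position: abducted, object_shape: small_sphere}
  10: {name: power_disk,          grasp_type: power,        thumb_position: abducted, object_shape: disk}
  11: {name: power_sphere,        grasp_type: power,        thumb_position: abducted, object_shape: large_sphere}
  12: {name: precision_disk,      grasp_type: precision,    thumb_position: abducted, object_shape: disk}
  13: {name: precision_sphere,    grasp_type: precision,    thumb_position: abducted, object_shape: small_sphere}
  14: {name: tripod,              grasp_type: precision,    thumb_position: abducted, object_shape: small_sphere}
  15: {name: fixed_hook,          grasp_type: power,        thumb_position: adducted, object_shape: large_bar}
  16: {name: lateral,             grasp_type: intermediate, thumb_position: adducted, object_shape: card}
  17: {name: index_finger_ext,    grasp_type: intermediate, thumb_position: adducted, object_shape: small_bar}
  18: {name: extension_type,      grasp_type: power,        thumb_position: adducted, object_shape: card}
  19: {name: distal_type,         grasp_type: power,        thumb_position: adducted, object_shape: scissors}
  20: {name: writing_tripod,      grasp_type: intermediate, thumb_position: abducted, object_shape: small_bar}
  21: {name: tripod_variation,    grasp_type: precision,    thumb_position: abducted, object_shape: small_bar}
  22: {name: parallel_extension,  grasp_type: precision,    thumb_position: abducted, object_shape: card}
  23: {name: adduction_grip,      grasp_type: intermediate, thumb_position: adducted, object_shape: scissors}
  24: {name: tip_pinch,           grasp_type: precision,    thumb_position: abducted, object_shape: small_sphere}
  25: {name: lateral_tripod,      grasp_type: intermediate, thumb_position: adducted, object_shape: small_bar}
  26: {name: sphere_4_finger,     grasp_type: precision,    thumb_position: abducted, object_shape: large_sphere}
  27: {name: quadpod,             grasp_type: precision,    thumb_position: abducted, object_shape: large_sphere}
  28: {name: sphere_3_finger,     grasp_type: precision,    thumb_position: abducted, object_shape: large_sphere}
  29: {name: stick,               grasp_type: intermediate, thumb_position: adducted, object_shape: small_bar}
  30: {name: palmar,              grasp_type: power,        thumb_position: abducted, object_shape: large_bar}
  31: {name: ring,                grasp_type: power,        thumb_position: adducted, object_shape: small_bar}
  32: {name: ventral,             grasp_type: power,        thumb_position: abducted, object_shape: large_bar}
  33: {name: inferior_pincer,     grasp_type: precision,    thumb_position: abducted, object_shape: small_sphere}
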
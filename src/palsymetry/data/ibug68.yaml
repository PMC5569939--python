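# Default 68-point facial landmark scheme (iBUG convention, 0-based indices).
# "left" means image-left, i.e. the subject's right side on a frontal photo.
name: ibug68
size: 68
subsets:
  jaw: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16]
  left_brow: [17, 18, 19, 20, 21]
  right_brow: [22, 23, 24, 25, 26]
  nose: [27, 28, 29, 30, 31, 32, 33, 34, 35]
  left_eye: [36, 37, 38, 39, 40, 41]
  right_eye: [42, 43, 44, 45, 46, 47]
  outer_mouth: [48, 49, 50, 51, 52, 53, 54, 55, 56, 57, 58, 59]
  inner_mouth: [60, 61, 62, 63, 64, 65, 66, 67]
  mouth: [48, 49, 50, 51, 52, 53, 54, 55, 56, 57, 58, 59, 60, 61, 62, 63, 64, 65, 66, 67]
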
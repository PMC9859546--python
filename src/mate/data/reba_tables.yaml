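# REBA scoring matrices, transcribed from the published worksheet
# (Hignett & McAtamney 2000, "Rapid Entire Body Assessment (REBA)",
# Applied Ergonomics 31(2)).
# table_a: index [neck 1-3][trunk 1-5][legs 1-4]
# table_b: index [lower_arm 1-2][upper_arm 1-6][wrist 1-3]
# table_c: index [score_a 1-12][score_b 1-12]
table_a:
  - - [1, 2, 3, 4]
    - [2, 3, 4, 5]
    - [2, 4, 5, 6]
    - [3, 5, 6, 7]
    - [4, 6, 7, 8]
  - - [1, 2, 3, 4]
    - [3, 4, 5, 6]
    - [4, 5, 6, 7]
    - [5, 6, 7, 8]
    - [6, 7, 8, 9]
  - - [3, 3, 5, 6]
    - [4, 5, 6, 7]
    - [5, 6, 7, 8]
    - [6, 7, 8, 9]
    - [7, 8, 9, 9]
table_b:
  - - [1, 2, 2]
    - [1, 2, 3]
    - [3, 4, 5]
    - [4, 5, 5]
    - [6, 7, 8]
    - [7, 8, 8]
  - - [1, 2, 3]
    - [2, 3, 4]
    - [4, 5, 5]
    - [5, 6, 7]
    - [7, 8, 8]
    - [8, 9, 9]
table_c:
  - [1, 1, 1, 2, 3, 3, 4, 5, 6, 7, 7, 7]
  - [1, 2, 2, 3, 4, 4, 5, 6, 6, 7, 7, 8]
  - [2, 3, 3, 3, 4, 5, 6, 7, 7, 8, 8, 8]
  - [3, 4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9]
  - [4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9, 9]
  - [6, 6, 6, 7, 8, 8, 9, 9, 10, 10, 10, 10]
  - [7, 7, 7, 8, 9, 9, 9, 10, 10, 11, 11, 11]
  - [8, 8, 8, 9, 10, 10, 10, 10, 10, 11, 11, 11]
  - [9, 9, 9, 10, 10, 10, 11, 11, 11, 12, 12, 12]
  - [10, 10, 10, 11, 11, 11, 11, 12, 12, 12, 12, 12]
  - [11, 11, 11, 11, 12, 12, 12, 12, 12, 12, 12, 12]
  - [12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12]
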
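# RULA scoring matrices, transcribed from the published worksheet
# (McAtamney & Corlett 1993, "RULA: a survey method for the investigation
# of work-related upper limb disorders", Applied Ergonomics 24(2)).
# table_a: index [upper_arm 1-6][lower_arm 1-3][wrist 1-4][wrist_twist 1-2]
# table_b: index [neck 1-6][trunk 1-6][legs 1-2]
# table_c: index [score_a 1-8 (8 = 8+)][score_b 1-7 (7 = 7+)]
table_a:
  - - [[1, 2], [2, 2], [2, 3], [3, 3]]
    - [[2, 2], [2, 2], [3, 3], [3, 3]]
    - [[2, 3], [3, 3], [3, 3], [4, 4]]
  - - [[2, 3], [3, 3], [3, 4], [4, 4]]
    - [[3, 3], [3, 3], [3, 4], [4, 4]]
    - [[3, 4], [4, 4], [4, 4], [5, 5]]
  - - [[3, 3], [4, 4], [4, 4], [5, 5]]
    - [[3, 4], [4, 4], [4, 4], [5, 5]]
    - [[4, 4], [4, 4], [4, 5], [5, 5]]
  - - [[4, 4], [4, 4], [4, 5], [5, 5]]
    - [[4, 4], [4, 4], [4, 5], [5, 5]]
    - [[4, 4], [4, 5], [5, 5], [6, 6]]
  - - [[5, 5], [5, 5], [5, 6], [6, 7]]
    - [[5, 6], [6, 6], [6, 7], [7, 7]]
    - [[6, 6], [6, 7], [7, 7], [7, 8]]
  - - [[7, 7], [7, 7], [7, 8], [8, 9]]
    - [[8, 8], [8, 8], [8, 9], [9, 9]]
    - [[9, 9], [9, 9], [9, 9], [9, 9]]
table_b:
  - [[1, 3], [2, 3], [3, 4], [5, 5], [6, 6], [7, 7]]
  - [[2, 3], [2, 3], [4, 5], [5, 5], [6, 7], [7, 7]]
  - [[3, 3], [3, 4], [4, 5], [5, 6], [6, 7], [7, 7]]
  - [[5, 5], [5, 6], [6, 7], [7, 7], [7, 7], [8, 8]]
  - [[7, 7], [7, 7], [7, 8], [8, 8], [8, 8], [8, 8]]
  - [[8, 8], [8, 8], [8, 8], [8, 9], [9, 9], [9, 9]]
table_c:
  - [1, 2, 3, 3, 4, 5, 5]
  - [2, 2, 3, 4, 4, 5, 5]
  - [3, 3, 3, 4, 4, 5, 6]
  - [3, 3, 3, 4, 5, 6, 6]
  - [4, 4, 4, 5, 6, 7, 7]
  - [4, 4, 5, 6, 6, 7, 7]
  - [5, 5, 6, 6, 7, 7, 7]
  - [5, 5, 6, 7, 7, 7, 7]
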
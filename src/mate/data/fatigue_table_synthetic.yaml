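# SYNTHETIC S-N failure-probability surface for vertebral bone.
#
# This is a representative stand-in, not transcribed material-test data:
# replace it with a table from cadaveric fatigue testing before drawing
# conclusions about real workers.  It was generated from a log-linear S-N
# model with an endurance region below 30 %UCS:
#   median log10(cycles to failure) = (100 - S) / 12.5
#   P(fail within N) = Phi((log10 N - median) / 0.8)
# which reproduces the qualitative shape of published vertebral fatigue
# data (single-cycle failure near 100 %UCS, ~10^5-cycle survival near the
# endurance region).  Probabilities rounded to 4 decimals; surface is
# non-decreasing along both axes as the loader requires.
load_levels: [30, 40, 50, 60, 70, 80, 90, 100]   # % of ultimate compressive strength
cycle_levels: [1, 10, 100, 1000, 10000, 100000]  # loading cycles
probability:
  - [0.0000, 0.0000, 0.0000, 0.0006, 0.0228, 0.2266]
  - [0.0000, 0.0000, 0.0002, 0.0122, 0.1587, 0.5987]
  - [0.0000, 0.0001, 0.0062, 0.1056, 0.5000, 0.8944]
  - [0.0000, 0.0030, 0.0668, 0.4013, 0.8413, 0.9878]
  - [0.0013, 0.0401, 0.3085, 0.7734, 0.9772, 0.9994]
  - [0.0228, 0.2266, 0.6915, 0.9599, 0.9987, 1.0000]
  - [0.1587, 0.5987, 0.9332, 0.9970, 1.0000, 1.0000]
  - [0.5000, 0.8944, 0.9938, 0.9999, 1.0000, 1.0000]
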
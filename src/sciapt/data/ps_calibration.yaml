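# Published per-order candidate matrix for 10-ABB phosphatidylserine
# aptamers.  Index = SCI order (0-based); each entry lists the ABBs tied at
# the lowest log-energy for that order.  Used by calibration mode to exercise
# enumeration, categorization, length and ranking independently of the
# reconstructed energy functional.
target: PS
matrix:
  - [G]
  - [G]
  - [C]
  - [G]
  - [G]
  - [C]
  - [G]
  - [A, G, C, T, U]
  - [A, T, U]
  - [G]
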
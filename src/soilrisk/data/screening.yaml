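# Soil risk screening values Si (mg/kg), pH-banded in GB 15618-2018 style
# (agricultural land other than paddy). Each entry: [ph_lo, ph_hi, Si] with
# the band (ph_lo, ph_hi]; bands jointly cover (0, 14]. Edit freely.
Cr:
  - [0.0, 5.5, 150]
  - [5.5, 6.5, 150]
  - [6.5, 7.5, 200]
  - [7.5, 14.0, 250]
Cd:
  - [0.0, 5.5, 0.3]
  - [5.5, 6.5, 0.3]
  - [6.5, 7.5, 0.3]
  - [7.5, 14.0, 0.6]
As:
  - [0.0, 5.5, 40]
  - [5.5, 6.5, 40]
  - [6.5, 7.5, 30]
  - [7.5, 14.0, 25]
Pb:
  - [0.0, 5.5, 70]
  - [5.5, 6.5, 90]
  - [6.5, 7.5, 120]
  - [7.5, 14.0, 170]
Hg:
  - [0.0, 5.5, 1.3]
  - [5.5, 6.5, 1.8]
  - [6.5, 7.5, 2.4]
  - [7.5, 14.0, 3.4]
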
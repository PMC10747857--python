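# Exposure variables per cohort. A scalar is a fixed value; a mapping
# {family, params} is a distribution. The six stochastic variables are
# CS (supplied separately), IRing, ED, AF, SA and BW; EF and ABS are fixed.
# Units: IRing mg/day, EF days/yr, ED yr, BW kg, AF mg/cm2, SA cm2, ABS -.
# Triangular defaults bracket conventional USEPA central values; editable.
adult:
  IRing: {family: triangular, params: [50, 100, 200]}
  EF: 350
  ED: {family: triangular, params: [10, 24, 40]}
  BW: {family: triangular, params: [50, 61.8, 80]}
  AF: {family: triangular, params: [0.02, 0.07, 0.3]}
  SA: {family: triangular, params: [4000, 5700, 7000]}
  ABS: 0.001
child:
  IRing: {family: triangular, params: [100, 200, 300]}
  EF: 350
  ED: {family: triangular, params: [3, 6, 10]}
  BW: {family: triangular, params: [10, 15, 25]}
  AF: {family: triangular, params: [0.1, 0.2, 0.3]}
  SA: {family: triangular, params: [2000, 2800, 3500]}
  ABS: 0.001
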
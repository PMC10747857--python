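# Nemerow-index grading scheme: class k covers [breaks[k-1], breaks[k]).
# Canonical five-level Nemerow breakpoints; edit to taste.
breaks: [0.7, 1.0, 2.0, 3.0]
labels: [unpolluted, warning, low, medium, high]
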
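# Treatment success: positive-symptom total has dropped below 11
# (one closed side of a vertical discriminant line), regardless of the
# negative-symptom total.
kind: halfspace
side: improved
discriminant:
  weights: [1.0, 0.0]
  offset: -11.0
  positive_label: not_improved
  negative_label: improved
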
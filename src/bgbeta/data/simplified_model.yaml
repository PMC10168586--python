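# Versioned calibration of the Simplified Model (two-loop network).
#
# The reference tuning of the two-loop network (current/drive adjustments
# and loop-connection intensities) is reproduced here by an explicit
# calibration: auxiliary populations are rate-matched to their real
# counterparts, I_e offsets keep each real population inside its
# physiological rate window once the nuclei absent from the Simplified
# Model (D1, GPe-TA) no longer inhibit it, and the loop weight gains set
# the working point at which each isolated loop shows a clear beta-band
# resonance at its natural frequency (STR loop ~13 Hz, STN loop ~19 Hz).
# Regenerate with scripts/calibrate_simplified.py.

I_e_offsets:
  D2: 0.0
  FSN: 14.893816745386804
  GPTI-A: 10.999425085925424
  GPTI-B: -140.62021053160885
  STN: 18.70536769895177
achieved_rates:
  D2: 3.293
  FSN: 18.232738095238094
  GPTI-A: 52.95448717948718
  GPTI-B: 32.989102564102566
  STN: 17.456495098039216
auxiliary_I_e:
  GPTI*: -124.21875
  STN*: -21.875
auxiliary_nu_scale:
  D2*: 0.6656249999999999
loop_weight_gain:
  stn: 1.75
  str: 1.75
nu_ext_overrides:
  D2: 1.264607085333375
target_rates:
  D2: 2.33
  FSN: 18.4
  GPTI: 55.1
  STN: 16.7
version: 0
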
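# Species-level response parameters for tropical maize.
#
# PRFTC: relative photosynthesis factor vs daily mean temperature (deg C).
# RGFIL: relative grain-fill rate factor vs daily mean temperature (deg C).
# Both are piecewise-linear breakpoint tables (temperature -> factor in [0,1]);
# editing this file changes the simulated high-temperature response without
# touching code.
tbase: 8.0
photoperiod_threshold: 12.5
prftc:
  - [6.2, 0.0]
  - [16.5, 1.0]
  - [33.0, 1.0]
  - [44.0, 0.0]
rgfil:
  - [5.5, 0.0]
  - [16.0, 1.0]
  - [27.0, 1.0]
  - [35.0, 0.0]
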
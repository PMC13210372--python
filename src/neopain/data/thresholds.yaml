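# Clinical concept thresholds, in each concept's native units.
#
# Facial activation thresholds (C1-C4) are stratified by gestational age:
# strata are [24,28), [28,32), [32,37), [37,44] weeks, and values rise from
# 0.60 (extremely preterm, underdeveloped facial musculature) to 0.75 (term)
# within +/-0.15 of the 0.70 default. F0 elevation (C6) uses the preterm
# (<37 w) / term (>=37 w) split. All comparisons are strict.
facial_strata: ["<28", "28-32", "32-37", ">=37"]
concepts:
  C1:
    name: brow_lowering
    default: 0.70
    by_stratum: {"<28": 0.60, "28-32": 0.65, "32-37": 0.70, ">=37": 0.75}
  C2:
    name: eye_squeeze
    default: 0.70
    by_stratum: {"<28": 0.60, "28-32": 0.65, "32-37": 0.70, ">=37": 0.75}
  C3:
    name: nasolabial_furrow
    default: 0.70
    by_stratum: {"<28": 0.60, "28-32": 0.65, "32-37": 0.70, ">=37": 0.75}
  C4:
    name: mouth_opening
    default: 0.70
    by_stratum: {"<28": 0.60, "28-32": 0.65, "32-37": 0.70, ">=37": 0.75}
  C5:
    name: cry_intensity
    rms: 0.30               # frame RMS energy
    sustain_ms: 500.0       # minimum sustained vocalization
  C6:
    name: f0_elevation
    f0_preterm_hz: 450.0    # ga < 37 w
    f0_term_hz: 500.0       # ga >= 37 w
  C7:
    name: harmonic_distortion
    hnr_max: 0.50           # harmonic-to-noise power ratio, fires below
    irregularity_min: 0.30  # normalized spectral flux, fires above
  C8:
    name: silence_periods
    pause_ms: 200.0         # pause gaps during cry episodes
  C9:
    name: hr_acceleration
    pct_increase: 15.0      # % above 2-min baseline
    abs_bpm: 180.0          # absolute branch
  C10:
    name: o2_desaturation
    drop_points: 4.0        # percentage-point drop within 30 s
    abs_pct: 92.0           # absolute branch
    window_s: 30.0
  C11:
    name: respiratory_irregularity
    cv: 0.25                # coefficient of variation over 1-min window
    window_s: 60.0
  C12:
    name: bp_elevation
    delta_mmhg: 10.0        # MAP increase from baseline
# Flat fallbacks used by the rule engine when gestational age is unknown
flat_defaults:
  brow: 0.70
  cry: 0.60
  hr: 0.50
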
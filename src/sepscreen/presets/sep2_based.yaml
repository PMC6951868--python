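# Scenario closest to the CMS severe-sepsis (SEP-2-derived) definition:
# every parameter enabled, including SBP decrease >40 mm Hg from baseline.
name: sep2_based
sbp_drop_enabled: true
sbp_drop_mmHg: 40.0
sbp_low_mmHg: 90.0
map_low_mmHg: 65.0
lactate_high_mmol_L: 2.0
bilirubin_low_mg_dL: 2.0
bilirubin_cap_mg_dL: null
creatinine_high_mg_dL: 2.0
creatinine_delta_required: false
creatinine_delta_mg_dL: 0.5
platelets_inr_enabled: true
platelets_low_per_uL: 100000.0
inr_high: 1.5
lactate_lookback_h: 12.0
creatinine_lookback_h: 72.0
default_lookback_h: 30.0
temp_high_C: 38.3
temp_low_C: 36.0
hr_high_bpm: 90.0
rr_high_bpm: 20.0
wbc_high_per_mm3: 12000.0
wbc_low_per_mm3: 4000.0
band_high_pct: 10.0
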
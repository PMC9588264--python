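# Institutional target/OAR constraint table for 70 Gy / 28 fx prostate
# proton plans. Types: V_rel (% of ROI >= dose), V_abs (cm3 >= dose),
# mean (Gy), D_cc (min dose of the hottest `volume_cc`, Gy).
- {roi: bladder, type: V_abs, dose_gy: 70, limit_cc: 10}
- {roi: bladder, type: V_rel, dose_gy: 65, limit_pct: 15}
- {roi: bladder, type: V_rel, dose_gy: 61, limit_pct: 25}
- {roi: bladder, type: V_rel, dose_gy: 55, limit_pct: 30}
- {roi: bladder, type: V_rel, dose_gy: 44, limit_pct: 50}
- {roi: bladder, type: V_rel, dose_gy: 39, limit_pct: 60}
- {roi: rectum, type: V_abs, dose_gy: 70, limit_cc: 10}
- {roi: rectum, type: V_rel, dose_gy: 65, limit_pct: 10}
- {roi: rectum, type: V_rel, dose_gy: 61, limit_pct: 15}
- {roi: rectum, type: V_rel, dose_gy: 53, limit_pct: 30}
- {roi: rectum, type: V_rel, dose_gy: 35, limit_pct: 50}
- {roi: femur_right, type: V_rel, dose_gy: 39, limit_pct: 5}
- {roi: femur_left, type: V_rel, dose_gy: 39, limit_pct: 5}
- {roi: penile_bulb, type: mean, limit_gy: 39}
- {roi: body, type: D_cc, volume_cc: 0.03, limit_gy: 74.9}
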
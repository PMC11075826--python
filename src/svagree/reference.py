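"""Reference agreement estimates.

These are the published estimates from the agreement study of volume-clamp
pulse-wave-analysis (PWA) versus suprasternal Doppler-ultrasound stroke
volume during LBNP with isometric handgrip in 16 healthy volunteers.  The
default synthetic-cohort calibration is designed so that the full pipeline
recovers these numbers; :func:`svagree.pipeline.replicate` prints the
side-by-side comparison.
"""

REFERENCE_ESTIMATES: dict[str, float] = {
    "bias_ml": 27.0,                    # mean SV_PWA - SV_US
    "loa_half_width_ml": 30.1,          # 1.96 x total SD
    "ws_loa_half_width_ml": 11.1,       # 1.96 x residual SD
    "percentage_error_pct": 14.6,       # within-subject LOA / grand mean x 100
    "mean_slope_ml_per_ml": -0.15,      # diff on mean-of-methods
    "sloped_loa_half_width_ml": 30.9,   # about the sloped bias line
    "sloped_ws_loa_half_width_ml": 10.2,
    "sloped_percentage_error_pct": 13.4,
    "svr_slope_ml_per_unit": 0.60,      # mL per mmHg.min/L
    "svr_slope_male": 0.86,
    "svr_slope_female": 0.40,
    "time_slope_ml_per_30s": 0.58,      # within IHG periods
    "precision_us_ml": 3.7,             # 1.96 x residual SD at LBNP 0 rest
    "precision_pwa_ml": 3.7,
    "max_svr_excursion": 10.0,          # mmHg.min/L at maximum vasoconstriction
    "predicted_diff_increase_ml": 6.0,  # svr slope x max excursion
}
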
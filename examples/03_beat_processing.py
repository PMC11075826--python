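"""From beat waveforms to 30-s analysis records.

Shows the waveform-level operations (time-weighted MAP, velocity-time
integral, LVOT area) on a synthesized beat, then the full preprocessing
of a cohort: post-handgrip exclusion windows, completed-levels-only
filtering and trimmed 30-s binning.
"""

from svagree import (lvot_area, simulate_cohort, sv_from_vti,
                     synthesize_beat_waveforms, time_weighted_map,
                     velocity_time_integral)
from svagree.pipeline import preprocess

beats, profiles = simulate_cohort(n_subjects=4, rng_seed=7)

beat = beats.iloc[0]
pressure, velocity = synthesize_beat_waveforms(beat, sampling_rate=1000.0,
                                               lvot_area_cm2=3.5)
vti = velocity_time_integral(velocity, 1000.0)
print(f"one beat (RR {beat.rr:.2f} s): "
      f"time-weighted MAP {time_weighted_map(pressure, 1000.0):.1f} mmHg "
      f"(true {beat['map']:.1f})")
print(f"VTI {vti:.2f} cm x LVOT area {lvot_area(2.11):.2f} cm^2 -> "
      f"SV {sv_from_vti(vti, 3.5):.1f} mL (true {beat.sv_us:.1f})")
# The Doppler stroke volume is the velocity-time integral of aortic flow
# times the outflow-tract cross-section.

bins = preprocess(beats, profiles)
print(f"\n{len(beats)} beats -> {len(bins)} 30-s bins "
      "(5% trimmed means; 30 s after each handgrip release excluded)")
print(bins[["subject_id", "lbnp", "phase", "period_time_bin",
            "sv_us", "sv_pwa", "svr_us", "diff"]].head(8).round(2).to_string())
# `diff` (PWA - US) and `svr_us` per bin are the inputs of the
# agreement models.
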
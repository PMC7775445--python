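"""Simulate one subject's EEG, preprocess it, and extract ERP measures.

A subject profile drives a forward model (P1/P2/P3 components + 1/f noise);
the continuous recording is re-referenced, band-passed, epoched and
baseline-corrected; component amplitudes (signed area, uV*ms) and latencies
(50% fractional-area, ms) are then measured on difference waves.
"""

import pandas as pd

from salience_cpt import (
    TaskParams,
    behavioral_summary,
    classify_trials,
    generate_sequence,
    measures_table,
    outcome_frame,
    preprocess_continuous,
    simulate_behavior,
    simulate_continuous,
    simulate_profiles,
)

pd.set_option("display.width", 120)

sequence = generate_sequence(TaskParams(rng_seed=7))
profile = simulate_profiles(1, seed=7)[0]
print(f"subject {profile.subject_id}: ADHD index {profile.adhd_index}, "
      f"age {profile.age:.1f}")

continuous, events, _ = simulate_continuous(profile, sequence, seed=8)
responses = simulate_behavior(profile, sequence, seed=9)
outcomes = classify_trials(sequence, responses)

summary = behavioral_summary(outcomes)
print(f"mean RT (standard Go): {summary.rt_mean_standard:.1f} ms, "
      f"salience RT effect: {summary.salience_rt_effect:+.1f} ms")
print(f"commission ratio: {summary.commission_ratio:.3f}, "
      f"omission ratio: {summary.omission_ratio:.3f}")

epochs = preprocess_continuous(continuous, events,
                               metadata=outcome_frame(outcomes))
print(measures_table(epochs).round(2).to_string(index=False))
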
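"""Generate and validate a Salience-CPT trial sequence.

The task is a 'not-X' continuous performance task with a rare salient
stimulus: 8 blocks of 100 trials, each block holding 25% NoGo ('X'),
10% SalientGo (red square) and 65% StandardGo letters, with enforced
spacing between special trials.
"""

import collections

from salience_cpt import TaskParams, generate_sequence, validate_sequence

params = TaskParams(rng_seed=7)
sequence = generate_sequence(params)
frame = sequence.to_frame()

print(f"{len(frame)} trials, {params.n_blocks} blocks "
      f"of {params.trials_per_block}")
print("composition:", dict(collections.Counter(frame["condition"])))
print("trial duration:",
      frame["onset_ms"].diff().dropna().unique().tolist(), "ms")

report = validate_sequence(sequence)
print("all design constraints satisfied:", report.all_ok)

sequence.to_tsv("sequence.tsv")
print("wrote sequence.tsv (+ .json sidecar with seed and parameters)")
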
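"""Build a sparse-sampling session schedule and check its accounting.

One 1-h session acquires 360 volumes at a 10-s repetition gap: five
stimulus volumes and three silent-baseline volumes per block of eight,
45 volumes per flux level, and no exemplar repeated on adjacent trials.
"""

import numpy as np

import fluxwin as fw

design = fw.generate_session_design(n_volumes=360, n_levels=5, seed=0)
print("volumes            :", design.n_volumes)
print("stimulus volumes   :", int((design.trials.level > 0).sum()))
print("silence volumes    :", int((design.trials.level == 0).sum()))
print("volumes per level  :", design.level_counts().tolist())

stim = design.trials[design.trials.level > 0]
ex = stim.exemplar_id.to_numpy()
print("adjacent exemplar repeats:", int(np.sum(ex[1:] == ex[:-1])))

multi = fw.concatenate_sessions(
    [fw.generate_session_design(360, 5, seed=s) for s in range(5)]
)
print("\nfive concatenated sessions -> volumes per level:",
      multi.level_counts().tolist())

design.write_events_tsv("scratch_events.tsv")
print("wrote scratch_events.tsv (onset, duration, trial_type, exemplar)")
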
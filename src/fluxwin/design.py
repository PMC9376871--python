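"""Sparse temporal-sampling session schedules.

One fMRI volume is acquired every ``tr_s`` seconds (default 10 s) with a
short acquisition window (``ta_s`` = 1.35 s) at the end of the repetition
gap, so each volume samples the near-plateau BOLD response to a 6-s
stimulus that finished playing in scanner silence.  Within every run of
eight volumes, five carry a flux stimulus and three are silent baseline;
the five flux levels appear equally often over a session and consecutive
stimulus trials never repeat an exemplar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ConstraintError

__all__ = ["SessionDesign", "generate_session_design", "concatenate_sessions"]

SILENCE = "silence"
STIM_PER_BLOCK = 5
SILENCE_PER_BLOCK = 3
BLOCK = STIM_PER_BLOCK + SILENCE_PER_BLOCK


@dataclass
class SessionDesign:
    """Ordered volume schedule for one or more sparse-sampling sessions.

    ``trials`` has one row per volume with columns ``volume``, ``session``,
    ``condition`` (``"level1"``.. or ``"silence"``), ``level`` (1-based int,
    0 for silence), ``exemplar_id`` (-1 for silence), ``onset_s`` (stimulus
    onset; NaN for silence) and ``acq_onset_s``.
    """

    trials: pd.DataFrame
    tr_s: float = 10.0
    ta_s: float = 1.35
    stim_dur_s: float = 6.0
    n_levels: int = 5

    @property
    def n_volumes(self) -> int:
        return len(self.trials)

    @property
    def n_sessions(self) -> int:
        return int(self.trials["session"].nunique())

    def session_lengths(self) -> list[int]:
        return self.trials.groupby("session").size().tolist()

    def level_counts(self) -> pd.Series:
        stim = self.trials[self.trials["level"] > 0]
        return stim.groupby("level").size()

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type, exemplar)."""
        stim = self.trials[self.trials["level"] > 0]
        return pd.DataFrame(
            {
                "onset": stim["onset_s"].to_numpy(),
                "duration": self.stim_dur_s,
                "trial_type": stim["condition"].to_numpy(),
                "exemplar": stim["exemplar_id"].to_numpy(),
            }
        )

    def write_events_tsv(self, path) -> None:
        self.to_events().to_csv(path, sep="\t", index=False)


def _level_sequence(n_stim: int, n_levels: int, rng: np.random.Generator) -> np.ndarray:
    """Equal-count level sequence with no two consecutive equal levels."""
    if n_stim % n_levels:
        raise ConstraintError(
            f"{n_stim} stimulus volumes not divisible by {n_levels} levels"
        )
    if n_levels == 1:
        return np.ones(n_stim, dtype=int)
    # greedy: any level holding more than half the remaining slots must be
    # placed now, otherwise draw among admissible levels weighted by count
    counts = np.full(n_levels, n_stim // n_levels)
    seq = np.empty(n_stim, dtype=int)
    prev = -1
    for i in range(n_stim):
        remaining = n_stim - i
        cand = np.flatnonzero(counts > 0)
        cand = cand[cand != prev - 1]
        if len(cand) == 0:
            raise ConstraintError("could not build a non-repeating level sequence")
        cmax = counts[cand].max()
        if 2 * cmax >= remaining:  # must drain the dominant level(s) now
            top = cand[counts[cand] == cmax]
            pick = int(rng.choice(top))
        else:
            w = counts[cand] / counts[cand].sum()
            pick = int(rng.choice(cand, p=w))
        seq[i] = pick + 1
        counts[pick] -= 1
        prev = pick + 1
    return seq


def generate_session_design(
    n_volumes: int = 360,
    n_levels: int = 5,
    seed: int = 0,
    n_exemplars_per_level: int = 45,
    tr_s: float = 10.0,
    ta_s: float = 1.35,
    stim_dur_s: float = 6.0,
) -> SessionDesign:
    """Pseudo-random sparse-sampling schedule for one session.

    Volumes are organized in blocks of eight (five stimulus + three
    silence, shuffled within block) so the 5:3 stimulus:silence ratio holds
    at every scale.  Levels appear equally often; consecutive stimulus
    trials differ in level (hence always in exemplar), and exemplars cycle
    through each level's pool so no exemplar repeats before the pool is
    exhausted.  Stimulus onset precedes volume acquisition by
    ``stim_dur_s - ta_s`` so the volume covers the final ``ta_s`` of the
    trial.
    """
    if n_volumes % BLOCK:
        raise ConstraintError(f"n_volumes must be divisible by {BLOCK}")
    if n_levels < 1:
        raise ConstraintError("need at least one level")
    rng = np.random.default_rng(seed)

    n_blocks = n_volumes // BLOCK
    n_stim = n_blocks * STIM_PER_BLOCK
    levels_seq = _level_sequence(n_stim, n_levels, rng)

    # exemplar assignment: shuffled cycle through each level's pool
    pools = {
        lv: list(rng.permutation(n_exemplars_per_level))
        for lv in range(1, n_levels + 1)
    }
    counters = {lv: 0 for lv in pools}
    exemplars = np.empty(n_stim, dtype=int)
    prev_ex = -1
    for i, lv in enumerate(levels_seq):
        pool = pools[lv]
        k = counters[lv]
        ex = lv * 10_000 + pool[k % len(pool)]
        if ex == prev_ex:  # only possible when n_levels == 1
            ex = lv * 10_000 + pool[(k + 1) % len(pool)]
            counters[lv] += 1
            if ex == prev_ex:
                raise ConstraintError(
                    "cannot avoid consecutive identical exemplars"
                )
        counters[lv] += 1
        exemplars[i] = ex
        prev_ex = ex

    # interleave: per block, shuffle 5 stimulus slots and 3 silences
    is_stim = np.concatenate(
        [
            rng.permutation(
                np.array([True] * STIM_PER_BLOCK + [False] * SILENCE_PER_BLOCK)
            )
            for _ in range(n_blocks)
        ]
    )
    level_col = np.zeros(n_volumes, dtype=int)
    ex_col = np.full(n_volumes, -1, dtype=int)
    level_col[is_stim] = levels_seq
    ex_col[is_stim] = exemplars

    vol = np.arange(n_volumes)
    acq_onset = vol * tr_s + (tr_s - ta_s)
    onset = np.where(level_col > 0, acq_onset - (stim_dur_s - ta_s), np.nan)
    trials = pd.DataFrame(
        {
            "volume": vol,
            "session": 0,
            "condition": [
                f"level{lv}" if lv > 0 else SILENCE for lv in level_col
            ],
            "level": level_col,
            "exemplar_id": ex_col,
            "onset_s": onset,
            "acq_onset_s": acq_onset,
        }
    )
    return SessionDesign(
        trials=trials,
        tr_s=tr_s,
        ta_s=ta_s,
        stim_dur_s=stim_dur_s,
        n_levels=n_levels,
    )


def concatenate_sessions(designs: list[SessionDesign]) -> SessionDesign:
    """Concatenate sessions with global volume re-indexing.

    Session membership is retained so the design matrix can carry
    per-session intercepts and drift regressors; per-level volume counts
    add across sessions (e.g. five 360-volume sessions give 225 volumes per
    level).
    """
    if not designs:
        raise ConsistencyError("need at least one session")
    first = designs[0]
    for d in designs[1:]:
        if (d.tr_s, d.ta_s, d.stim_dur_s, d.n_levels) != (
            first.tr_s,
            first.ta_s,
            first.stim_dur_s,
            first.n_levels,
        ):
            raise ConsistencyError("sessions have heterogeneous timing/levels")
    frames = []
    offset = 0
    t_offset = 0.0
    for s, d in enumerate(designs):
        tr = d.trials.copy()
        tr["session"] = s
        tr["volume"] = np.arange(len(tr)) + offset
        tr["onset_s"] = tr["onset_s"] + t_offset
        tr["acq_onset_s"] = tr["acq_onset_s"] + t_offset
        frames.append(tr)
        offset += len(tr)
        t_offset += len(tr) * d.tr_s
    return SessionDesign(
        trials=pd.concat(frames, ignore_index=True),
        tr_s=first.tr_s,
        ta_s=first.ta_s,
        stim_dur_s=first.stim_dur_s,
        n_levels=first.n_levels,
    )
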
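"""Salience-CPT trial-sequence design.

The task is a 'not-X' continuous performance task with three conditions:

* ``StandardGo`` — any letter except X, respond;
* ``NoGo`` — the letter X, withhold the response;
* ``SalientGo`` — a red square, respond (physically salient, task-irrelevant
  salience).

Stimuli are presented for 150 ms followed by a 1500 ms inter-stimulus
interval (1650 ms trial duration), in blocks of 100 trials with a fixed
per-block composition (25% NoGo, 10% SalientGo). The order within blocks is
pseudo-randomized under separation constraints that keep special (NoGo /
SalientGo) trials apart.

Note on the separation rule: the published composition (65 StandardGo per
100-trial block) cannot accommodate two StandardGo trials between *every*
pair of consecutive special trials (34 gaps x 2 = 68 > 65). This module
therefore enforces the strongest feasible version of the rule: at least
``min_standard_between_specials`` StandardGo trials between two specials of
the *same* condition (NoGo-NoGo, SalientGo-SalientGo) and at least
``min_standard_mixed`` StandardGo trials between specials of different
conditions, both enforced across block boundaries.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("StandardGo", "NoGo", "SalientGo")
SPECIALS = ("NoGo", "SalientGo")

#: Uppercase letters other than X (the NoGo stimulus).
DEFAULT_LETTER_POOL = tuple(c for c in string.ascii_uppercase if c != "X")


class TaskDesignError(ValueError):
    """Invalid task parameters."""


class UnsatisfiableConstraintError(TaskDesignError):
    """The composition cannot satisfy the separation constraints."""


@dataclass(frozen=True)
class TaskParams:
    """Design parameters of the Salience CPT.

    Defaults reproduce the published design: 8 blocks x 100 trials,
    25 NoGo + 10 SalientGo + 65 StandardGo per block, 150 ms stimulus,
    1500 ms ISI.
    """

    n_blocks: int = 8
    trials_per_block: int = 100
    frac_nogo_per_block: float = 0.25
    frac_salient_per_block: float = 0.10
    stim_duration: float = 150.0
    isi: float = 1500.0
    min_standard_between_specials: int = 2
    min_standard_mixed: int = 1
    letter_pool: tuple = DEFAULT_LETTER_POOL
    rng_seed: int = 0

    @property
    def trial_duration(self) -> float:
        return self.stim_duration + self.isi

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_nogo_per_block(self) -> int:
        return round(self.trials_per_block * self.frac_nogo_per_block)

    @property
    def n_salient_per_block(self) -> int:
        return round(self.trials_per_block * self.frac_salient_per_block)

    @property
    def n_standard_per_block(self) -> int:
        return self.trials_per_block - self.n_nogo_per_block - self.n_salient_per_block

    def validate(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise TaskDesignError("n_blocks and trials_per_block must be positive")
        if self.frac_nogo_per_block + self.frac_salient_per_block >= 1:
            raise TaskDesignError(
                "frac_nogo_per_block + frac_salient_per_block must be < 1"
            )
        if self.min_standard_between_specials < 0 or self.min_standard_mixed < 0:
            raise TaskDesignError("separation minima must be >= 0")
        if self.min_standard_mixed > self.min_standard_between_specials:
            raise TaskDesignError(
                "min_standard_mixed cannot exceed min_standard_between_specials"
            )
        for frac, name in (
            (self.frac_nogo_per_block, "frac_nogo_per_block"),
            (self.frac_salient_per_block, "frac_salient_per_block"),
        ):
            n = self.trials_per_block * frac
            if abs(n - round(n)) > 1e-9:
                raise TaskDesignError(
                    f"{name} x trials_per_block = {n} is not an integer count"
                )
        if (self.frac_nogo_per_block > 0 or self.frac_salient_per_block > 0) and (
            not self.letter_pool
        ):
            pass  # letters only needed for StandardGo trials
        if self.n_standard_per_block > 0 and not self.letter_pool:
            raise TaskDesignError("letter_pool is empty but StandardGo trials exist")
        if "X" in self.letter_pool:
            raise TaskDesignError("letter_pool must not contain 'X'")
        # Necessary feasibility bound: every consecutive-special gap needs at
        # least min_standard_mixed standards, same-condition adjacencies need
        # min_standard_between_specials.  The weakest arrangement alternates
        # conditions as much as possible.
        n_special = self.n_nogo_per_block + self.n_salient_per_block
        if n_special > 0:
            n_minor = min(self.n_nogo_per_block, self.n_salient_per_block)
            # Max number of mixed adjacencies in one block is 2 * n_minor.
            n_gaps = n_special - 1
            mixed = min(2 * n_minor, n_gaps)
            same = n_gaps - mixed
            need = (
                mixed * self.min_standard_mixed
                + same * self.min_standard_between_specials
            )
            if need > self.n_standard_per_block:
                raise UnsatisfiableConstraintError(
                    f"composition needs >= {need} StandardGo separators per block "
                    f"but only {self.n_standard_per_block} are available"
                )


@dataclass(frozen=True)
class Trial:
    """One trial: 0-based global index, block id, condition, stimulus, onset (ms)."""

    index: int
    block: int
    condition: str
    stimulus: str
    onset: float


@dataclass
class TrialSequence:
    """Ordered, blocked list of condition-labelled trials with onsets."""

    params: TaskParams
    trials: list

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "block": [t.block for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "stimulus": [t.stimulus for t in self.trials],
                "onset_ms": [t.onset for t in self.trials],
            }
        )

    def to_tsv(self, path) -> None:
        """Serialize as TSV with a JSON sidecar recording the seed/params."""
        path = str(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = dict(asdict(self.params))
        sidecar["letter_pool"] = list(sidecar["letter_pool"])
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)


def _required_gap(cond_a: str, cond_b: str, params: TaskParams) -> int:
    if cond_a == cond_b:
        return params.min_standard_between_specials
    return params.min_standard_mixed


class _BlockPlacementDeadEnd(UnsatisfiableConstraintError):
    """A block cannot be placed given the carry-in from the previous block."""


def _block_special_order(
    rng: np.random.Generator, params: TaskParams, prev_tail: tuple,
    max_tries: int = 2000,
) -> tuple:
    """Choose a special-condition order + gap sizes for one block.

    ``prev_tail`` is (condition of last special so far or None, number of
    StandardGo trials since it).  Returns (order, gaps) where gaps has one
    entry before each special and one trailing entry, summing with the
    specials to trials_per_block.
    """
    n_std = params.n_standard_per_block
    specials = ["NoGo"] * params.n_nogo_per_block + (
        ["SalientGo"] * params.n_salient_per_block
    )
    prev_cond, prev_run = prev_tail
    for _ in range(max_tries):
        order = [str(c) for c in rng.permutation(specials)]
        mins = []
        last = prev_cond
        carry = prev_run
        ok = True
        for cond in order:
            if last is None:
                req = 0
            else:
                req = max(0, _required_gap(last, cond, params) - carry)
            mins.append(req)
            last = cond
            carry = 0
        need = sum(mins)
        if need <= n_std:
            # Distribute the slack standards over the gaps (incl. trailing).
            slack = n_std - need
            extra = rng.multinomial(slack, np.full(len(mins) + 1, 1.0 / (len(mins) + 1)))
            gaps = [m + e for m, e in zip(mins, extra[:-1])] + [int(extra[-1])]
            return order, gaps
    raise _BlockPlacementDeadEnd(
        "could not place special trials under the separation constraints "
        "(composition too dense)"
    )


def generate_sequence(params: TaskParams | None = None) -> TrialSequence:
    """Generate a pseudo-randomized Salience-CPT sequence.

    Uses constrained placement: per block, a random order of the special
    trials is drawn and re-drawn until the separation minima fit into the
    available StandardGo trials (carrying the constraint across block
    boundaries), then the remaining standards are distributed randomly over
    the gaps.  Identical seed => identical sequence.

    Placement is block-by-block without lookahead, so for very dense
    compositions a block can dead-end on the carry left by its predecessor
    even when a valid global arrangement exists; in that case the whole
    sequence is regenerated from the continuing random stream (bounded number
    of restarts) before giving up.
    """
    if params is None:
        params = TaskParams()
    params.validate()
    rng = np.random.default_rng(params.rng_seed)

    for _attempt in range(200):
        try:
            return _generate_once(rng, params)
        except _BlockPlacementDeadEnd:
            continue
    raise UnsatisfiableConstraintError(
        "could not place special trials under the separation constraints "
        "after repeated attempts (composition too dense)"
    )


def _generate_once(rng: np.random.Generator, params: TaskParams) -> TrialSequence:
    trials: list = []
    idx = 0
    prev_tail = (None, 0)
    for block in range(params.n_blocks):
        if params.n_nogo_per_block + params.n_salient_per_block == 0:
            order, gaps = [], [params.n_standard_per_block]
        else:
            order, gaps = _block_special_order(rng, params, prev_tail)

        def emit(condition: str) -> None:
            nonlocal idx
            if condition == "NoGo":
                stim = "X"
            elif condition == "SalientGo":
                stim = "red_square"
            else:
                stim = str(rng.choice(params.letter_pool))
            trials.append(
                Trial(
                    index=idx,
                    block=block,
                    condition=condition,
                    stimulus=stim,
                    onset=idx * params.trial_duration,
                )
            )
            idx += 1

        for gap, cond in zip(gaps[:-1], order):
            for _ in range(gap):
                emit("StandardGo")
            emit(cond)
        for _ in range(gaps[-1]):
            emit("StandardGo")

        if order:
            prev_tail = (order[-1], gaps[-1])
        else:
            prev_tail = (prev_tail[0], prev_tail[1] + gaps[-1])

    return TrialSequence(params=params, trials=trials)


@dataclass
class ConstraintReport:
    """Per-constraint validation outcome for a TrialSequence."""

    composition_ok: bool
    separation_ok: bool
    onset_ok: bool
    stimulus_ok: bool
    first_violation_index: int | None = None
    messages: list = field(default_factory=list)

    @property
    def all_ok(self) -> bool:
        return (
            self.composition_ok
            and self.separation_ok
            and self.onset_ok
            and self.stimulus_ok
        )


def validate_sequence(seq: TrialSequence) -> ConstraintReport:
    """Check composition, separation, onset arithmetic and stimulus coding."""
    p = seq.params
    report = ConstraintReport(True, True, True, True)

    def fail(which: str, index: int | None, msg: str) -> None:
        setattr(report, which, False)
        if index is not None and report.first_violation_index is None:
            report.first_violation_index = index
        report.messages.append(msg)

    # composition per block
    df = seq.to_frame()
    if len(df) != p.n_trials:
        fail("composition_ok", None, f"expected {p.n_trials} trials, got {len(df)}")
    for block, grp in df.groupby("block"):
        counts = grp["condition"].value_counts()
        expected = {
            "NoGo": p.n_nogo_per_block,
            "SalientGo": p.n_salient_per_block,
            "StandardGo": p.n_standard_per_block,
        }
        for cond, n_exp in expected.items():
            if int(counts.get(cond, 0)) != n_exp:
                fail(
                    "composition_ok",
                    None,
                    f"block {block}: {cond} count {counts.get(cond, 0)} != {n_exp}",
                )

    # separation, scanned over the concatenated sequence (across blocks)
    last_special: tuple | None = None  # (condition, position)
    standards_since = 0
    for t in seq.trials:
        if t.condition == "StandardGo":
            standards_since += 1
            continue
        if last_special is not None:
            req = _required_gap(last_special[0], t.condition, p)
            if standards_since < req:
                fail(
                    "separation_ok",
                    t.index,
                    f"trial {t.index}: only {standards_since} StandardGo since "
                    f"special at {last_special[1]} (need {req})",
                )
        last_special = (t.condition, t.index)
        standards_since = 0

    # onsets and stimulus coding
    for t in seq.trials:
        if abs(t.onset - t.index * p.trial_duration) > 1e-9:
            fail("onset_ok", t.index, f"trial {t.index}: onset {t.onset} wrong")
        cond_from_stim = (
            "NoGo"
            if t.stimulus == "X"
            else "SalientGo" if t.stimulus == "red_square" else "StandardGo"
        )
        if cond_from_stim != t.condition or (
            t.condition == "StandardGo" and t.stimulus not in p.letter_pool
        ):
            fail("stimulus_ok", t.index, f"trial {t.index}: stimulus/condition mismatch")

    return report
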
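"""Experiment designs and the trial loop.

A :class:`Design` is an ordered list of trials, each presenting a set of
CSs and (optionally) a US, partitioned into labelled blocks.  The trial
loop couples *performance* -- computed each epoch with the within-trial
decayed alpha -- with *learning* -- applied once per trial with the
terminal (last-epoch) alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    AssociativeState,
    ConfigurationError,
    SubjectParams,
    ValidationError,
    combine,
    decay_alpha,
    distribute,
    learning_update,
    response_vector,
)

__all__ = [
    "Trial",
    "Design",
    "TRAJECTORY_COLUMNS",
    "run_design",
    "build_acquisition",
    "build_extinction",
    "build_reversal",
    "build_compound",
    "build_partial_reinforcement",
]

logger = logging.getLogger(__name__)

#: Canonical long-format trajectory schema.
TRAJECTORY_COLUMNS = [
    "subject",
    "block",
    "trial",
    "epoch",
    "stimulus",
    "us",
    "v_forward",
    "v_backward",
    "v_comb",
    "r_cs",
    "r_us",
    "r1",
    "r2",
    "r3",
    "r4",
    "r5",
    "r6",
]


@dataclass(frozen=True)
class Trial:
    """One conditioning trial.

    ``cues`` are the CSs presented; ``us`` is the reference US for the
    trial (the one delivered when ``reinforced`` and the one against
    which performance is evaluated either way).  A 10-s CS is divided
    into ``n_epochs`` successive epochs of ``epoch_duration`` seconds
    (default 4 x 2.5 s).
    """

    cues: Tuple[str, ...]
    us: str
    reinforced: bool = True
    n_epochs: int = 4
    epoch_duration: float = 2.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "cues", tuple(self.cues))
        if self.n_epochs < 1:
            raise ValidationError(f"n_epochs must be >= 1, got {self.n_epochs!r}")
        if self.epoch_duration <= 0:
            raise ValidationError("epoch_duration must be positive")
        if self.us in self.cues:
            raise ConfigurationError(f"US {self.us!r} listed among cues")

    @property
    def present(self) -> Tuple[str, ...]:
        """All stimuli present on the trial (US included iff reinforced)."""
        return self.cues + ((self.us,) if self.reinforced else ())


@dataclass(frozen=True)
class Design:
    """An ordered trial sequence with a parallel block labelling."""

    trials: Tuple[Trial, ...]
    blocks: Tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        blocks = tuple(self.blocks)
        if not blocks and self.trials:
            blocks = ("T1",) * len(self.trials)
        if len(blocks) != len(self.trials):
            raise ConfigurationError(
                f"blocks ({len(blocks)}) must label every trial ({len(self.trials)})"
            )
        object.__setattr__(self, "blocks", blocks)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def stimuli(self) -> Tuple[str, ...]:
        seen: List[str] = []
        for t in self.trials:
            for sid in t.cues + (t.us,):
                if sid not in seen:
                    seen.append(sid)
        return tuple(seen)


def _block_labels(n: int, trials_per_block: Optional[int], prefix: str) -> List[str]:
    if trials_per_block is None:
        return [f"{prefix}1"] * n
    if trials_per_block < 1:
        raise ValidationError("trials_per_block must be >= 1")
    return [f"{prefix}{i // trials_per_block + 1}" for i in range(n)]


def _check_positive(name: str, value: int) -> None:
    if value <= 0:
        raise ValidationError(f"{name} must be positive, got {value!r}")


def build_acquisition(
    n_trials: int,
    cs_id: str = "CS",
    us_id: str = "US",
    n_epochs: int = 4,
    trials_per_block: Optional[int] = None,
) -> Design:
    """Continuous reinforcement: ``n_trials`` CS+US pairings."""
    _check_positive("n_trials", n_trials)
    trials = [Trial((cs_id,), us_id, True, n_epochs) for _ in range(n_trials)]
    return Design(tuple(trials), tuple(_block_labels(n_trials, trials_per_block, "T")))


def build_extinction(
    n_acq: int,
    n_ext: int,
    cs_id: str = "CS",
    us_id: str = "US",
    n_epochs: int = 4,
    trials_per_block: Optional[int] = None,
) -> Design:
    """Acquisition (blocks T*) followed by CS-alone extinction (blocks E*)."""
    _check_positive("n_acq", n_acq)
    _check_positive("n_ext", n_ext)
    trials = [Trial((cs_id,), us_id, True, n_epochs) for _ in range(n_acq)]
    trials += [Trial((cs_id,), us_id, False, n_epochs) for _ in range(n_ext)]
    blocks = _block_labels(n_acq, trials_per_block, "T") + _block_labels(
        n_ext, trials_per_block, "E"
    )
    return Design(tuple(trials), tuple(blocks))


def build_reversal(
    n_train: int,
    n_rev: int,
    cs_a: str = "A",
    cs_b: str = "B",
    us_id: str = "US",
    n_epochs: int = 4,
    trials_per_block: Optional[int] = None,
) -> Design:
    """A+/B- discrimination then contingency reversal (A-/B+).

    ``n_train`` trials of each contingency, strictly alternating A first,
    then ``n_rev`` of each with the contingencies swapped.  ``n_rev = 0``
    yields a plain discrimination.  Training blocks are labelled T*,
    reversal blocks R*.
    """
    _check_positive("n_train", n_train)
    if n_rev < 0:
        raise ValidationError(f"n_rev must be >= 0, got {n_rev!r}")
    trials: List[Trial] = []
    for _ in range(n_train):
        trials.append(Trial((cs_a,), us_id, True, n_epochs))
        trials.append(Trial((cs_b,), us_id, False, n_epochs))
    for _ in range(n_rev):
        trials.append(Trial((cs_a,), us_id, False, n_epochs))
        trials.append(Trial((cs_b,), us_id, True, n_epochs))
    blocks = _block_labels(2 * n_train, trials_per_block, "T") + _block_labels(
        2 * n_rev, trials_per_block, "R"
    )
    return Design(tuple(trials), tuple(blocks))


def build_compound(
    n_trials: int,
    cs_ids: Sequence[str] = ("A", "B"),
    us_id: str = "US",
    n_epochs: int = 4,
    trials_per_block: Optional[int] = None,
) -> Design:
    """Reinforced compound conditioning (e.g. AB+ overshadowing)."""
    _check_positive("n_trials", n_trials)
    if not cs_ids:
        raise ConfigurationError("cs_ids must be nonempty")
    trials = [Trial(tuple(cs_ids), us_id, True, n_epochs) for _ in range(n_trials)]
    return Design(tuple(trials), tuple(_block_labels(n_trials, trials_per_block, "T")))


def build_partial_reinforcement(
    n_trials: int,
    p_reinforced: float,
    cs_id: str = "CS",
    us_id: str = "US",
    seed: int = 0,
    n_epochs: int = 4,
    trials_per_block: Optional[int] = None,
) -> Design:
    """Bernoulli(p) reinforcement schedule; same seed, same design."""
    _check_positive("n_trials", n_trials)
    if not (0.0 <= p_reinforced <= 1.0):
        raise ValidationError(
            f"p_reinforced must lie in [0, 1], got {p_reinforced!r}"
        )
    rng = np.random.default_rng(seed)
    flags = rng.random(n_trials) < p_reinforced
    trials = [
        Trial((cs_id,), us_id, bool(flag), n_epochs) for flag in flags
    ]
    return Design(tuple(trials), tuple(_block_labels(n_trials, trials_per_block, "T")))


def run_design(
    design: Design,
    params: SubjectParams,
    subject_id: int = 0,
) -> pd.DataFrame:
    """Simulate one subject through a design; returns a long trajectory.

    Per trial: (a) V_COMB is computed for each presented CS from the
    current state; (b) per epoch e, alpha decays to
    ``alpha * decay_per_epoch**(e-1)`` and V_COMB is distributed into
    R_CS/R_US (the V fields are constant within a trial -- learning is
    per-trial); (c) the pooled-error update is applied once using the
    terminal (last-epoch) alpha.  Deterministic given (design, params).
    """
    for sid in design.stimuli:
        params.salience(sid)  # raises ConfigurationError if missing
    for t in design.trials:
        if t.us not in params.beta:
            raise ConfigurationError(f"trial US {t.us!r} has no beta salience")
        for cue in t.cues:
            if cue not in params.alpha:
                raise ConfigurationError(f"cue {cue!r} has no alpha salience")

    state = AssociativeState.zeros(params.stimuli)
    rows: List[tuple] = []
    for trial_idx, (trial, block) in enumerate(
        zip(design.trials, design.blocks), start=1
    ):
        for cs in trial.cues:
            vf = state.v(cs, trial.us)
            vb = state.v(trial.us, cs)
            vcomb = combine(vf, vb, params.c)
            for epoch in range(1, trial.n_epochs + 1):
                a_eff = decay_alpha(
                    params.alpha[cs], epoch, params.decay_per_epoch
                )
                if vcomb == 0.0:
                    r_cs, r_us = 0.0, 0.0
                else:
                    r_cs, r_us = distribute(vcomb, a_eff, vf, params.c)
                r = response_vector(r_cs, r_us, params.links, params.c)
                rows.append(
                    (subject_id, block, trial_idx, epoch, cs, trial.us,
                     vf, vb, vcomb, r_cs, r_us, *r)
                )
        alpha_terminal = {
            cs: decay_alpha(params.alpha[cs], trial.n_epochs, params.decay_per_epoch)
            for cs in trial.cues
        }
        state = learning_update(state, trial.present, params, alpha_terminal)
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "subject=%s trial=%d block=%s present=%s state=%r",
                subject_id, trial_idx, block, trial.present, state,
            )
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
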
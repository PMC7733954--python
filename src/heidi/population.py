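"""Individual-differences engine.

The model attributes both quantitative and qualitative variation in
conditioned behaviour to variation in the perceived saliences alpha_CS
and beta_US, which are fixed within a subject but vary across subjects.
This module samples per-subject parameter sets from distributions on
[0, 1], turns simulated response vigor into observable counts via a
Poisson emission model (an explicit artifact choice: the model itself
maps V to vigor, not to counts), and computes the sign-/goal-tracking
bias score and phenotype labels.

Bias score: (goal - sign) / (goal + sign); negative values indicate a
sign-tracker (ST), nonnegative a goal-tracker (GT), classified on the
final training block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    HeidiError,
    LinkMatrix,
    SubjectParams,
    ValidationError,
)
from .designs import Design, run_design

__all__ = [
    "UndefinedBiasError",
    "DistributionSpec",
    "PopulationSpec",
    "BEHAVIOR_COLUMNS",
    "sample_subjects",
    "generate_counts",
    "bias_score",
    "classify",
    "classify_population",
    "simulate_population",
]

#: Canonical behavioural-table schema (CSV export).
BEHAVIOR_COLUMNS = [
    "subject",
    "stimulus",
    "block",
    "sign_count",
    "goal_count",
    "bias",
    "label",
]


class UndefinedBiasError(HeidiError):
    """Bias score requested with zero total responses."""


@dataclass(frozen=True)
class DistributionSpec:
    """A named sampling distribution with support inside [0, 1].

    Families: ``beta(a, b)``, ``uniform(lo, hi)`` with 0 <= lo <= hi <= 1,
    and ``point(v)`` (a degenerate point mass, handy for tests).
    """

    family: str
    params: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        fam, p = self.family, self.params
        if fam == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValidationError(f"beta requires two positive shapes, got {p}")
        elif fam == "uniform":
            if len(p) != 2 or not (0.0 <= p[0] <= p[1] <= 1.0):
                raise ValidationError(
                    f"uniform requires 0 <= lo <= hi <= 1, got {p}"
                )
        elif fam == "point":
            if len(p) != 1 or not (0.0 <= p[0] <= 1.0):
                raise ValidationError(f"point requires one value in [0, 1], got {p}")
        else:
            raise ValidationError(f"unknown distribution family {fam!r}")

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        if self.family == "beta":
            return rng.beta(self.params[0], self.params[1], size=size)
        if self.family == "uniform":
            lo, hi = self.params
            return lo + (hi - lo) * rng.random(size)
        # point
        v = self.params[0]
        return v if size is None else np.full(size, v)


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling specification for a set of subjects.

    ``count_scale`` (k) converts response vigor (units of V) into a
    Poisson rate of observable responses per epoch record.
    """

    n_subjects: int
    alpha_distribution: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("beta", (2.0, 2.0))
    )
    beta_distribution: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("beta", (2.0, 2.0))
    )
    count_scale: float = 20.0
    seed: int = 0
    c: float = 1.0
    decay_per_epoch: float = 1.0
    links: LinkMatrix = field(default_factory=LinkMatrix)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError(
                f"n_subjects must be >= 1, got {self.n_subjects!r}"
            )
        if not self.count_scale > 0:
            raise ValidationError(
                f"count_scale must be positive, got {self.count_scale!r}"
            )


def _subject_rng(master_seed: int, subject: int, stream: int) -> np.random.Generator:
    # One stream per (subject, purpose); subject i's stream is invariant
    # to n_subjects.
    ss = np.random.SeedSequence(master_seed, spawn_key=(stream, subject))
    return np.random.default_rng(ss)


def sample_subjects(
    spec: PopulationSpec,
    cs_ids: Sequence[str] = ("CS",),
    us_ids: Sequence[str] = ("US",),
) -> List[SubjectParams]:
    """Draw ``n_subjects`` parameter sets; reproducible under ``spec.seed``.

    Each CS salience is an independent draw from ``alpha_distribution``
    and each US salience from ``beta_distribution``.  To model a shared
    US across CSs, list the US once in ``us_ids``; distinct USs get
    independent beta draws (which decouples the biases they support).
    """
    subjects = []
    for i in range(spec.n_subjects):
        rng = _subject_rng(spec.seed, i, stream=0)
        alpha = {cs: float(spec.alpha_distribution.sample(rng)) for cs in cs_ids}
        beta = {us: float(spec.beta_distribution.sample(rng)) for us in us_ids}
        subjects.append(
            SubjectParams(
                alpha=alpha,
                beta=beta,
                c=spec.c,
                decay_per_epoch=spec.decay_per_epoch,
                links=spec.links,
            )
        )
    return subjects


def bias_score(goal_count: float, sign_count: float) -> float:
    """(goal - sign) / (goal + sign), in [-1, 1].

    Negative = sign-tracking bias.  Undefined (raises) when both counts
    are zero.
    """
    if goal_count < 0 or sign_count < 0:
        raise ValidationError("counts must be nonnegative")
    total = goal_count + sign_count
    if total == 0:
        raise UndefinedBiasError("bias undefined: zero total responses")
    return (goal_count - sign_count) / total


def classify(bias_final_block: float, threshold: float = 0.0) -> str:
    """Sign rule on the final-block bias: ST if bias < threshold, else GT.

    A bias of exactly ``threshold`` (default 0) is classified GT.
    """
    return "ST" if bias_final_block < threshold else "GT"


def classify_population(biases: Sequence[float], method: str = "sign") -> List[str]:
    """Classify a set of final-block biases.

    ``method='sign'`` applies the fixed-zero rule; ``method='median'``
    performs a median split (below the group median -> ST).
    """
    biases = np.asarray(biases, dtype=float)
    if method == "sign":
        threshold = 0.0
    elif method == "median":
        threshold = float(np.median(biases))
    else:
        raise ValidationError(f"unknown classification method {method!r}")
    return [classify(b, threshold) for b in biases]


def generate_counts(
    trajectory: pd.DataFrame,
    spec: PopulationSpec,
    sign_col: str = "r1",
    goal_col: str = "r4",
) -> pd.DataFrame:
    """Emit Poisson response counts from a simulated trajectory.

    Per epoch record, sign counts ~ Poisson(k * max(r1, 0)) and goal
    counts ~ Poisson(k * max(r4, 0)); counts are summed per subject x
    stimulus x block.  Each subject draws from its own RNG stream
    derived from ``spec.seed``, so subject i's counts do not depend on
    how many other subjects are simulated.

    The bias column is NaN for cells with zero total responses; labels
    are assigned from each subject's final-block bias (per stimulus) and
    are NaN where that bias is undefined.
    """
    if trajectory.empty:
        raise ConfigurationError("trajectory is empty")
    out = []
    for subject, traj in trajectory.groupby("subject", sort=True):
        rng = _subject_rng(spec.seed, int(subject), stream=1)
        sign_rate = spec.count_scale * np.clip(traj[sign_col].to_numpy(), 0, None)
        goal_rate = spec.count_scale * np.clip(traj[goal_col].to_numpy(), 0, None)
        traj = traj.assign(
            _sign=rng.poisson(sign_rate), _goal=rng.poisson(goal_rate)
        )
        grouped = (
            traj.groupby(["stimulus", "block"], sort=False)[["_sign", "_goal"]]
            .sum()
            .reset_index()
        )
        grouped.insert(0, "subject", subject)
        out.append(grouped)
    table = pd.concat(out, ignore_index=True).rename(
        columns={"_sign": "sign_count", "_goal": "goal_count"}
    )
    total = table["sign_count"] + table["goal_count"]
    table["bias"] = np.where(
        total > 0,
        (table["goal_count"] - table["sign_count"]) / total.where(total > 0, 1),
        np.nan,
    )
    # phenotype from the final block of each subject x stimulus
    final = (
        table.groupby(["subject", "stimulus"], sort=False)
        .tail(1)
        .set_index(["subject", "stimulus"])["bias"]
    )
    labels = final.map(lambda b: classify(b) if np.isfinite(b) else np.nan)
    table["label"] = [
        labels.loc[(s, st)] for s, st in zip(table["subject"], table["stimulus"])
    ]
    return table[BEHAVIOR_COLUMNS]


def simulate_population(
    spec: PopulationSpec,
    design: Design,
    cs_ids: Optional[Sequence[str]] = None,
    us_ids: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a population, run everyone through ``design``, emit counts.

    Returns ``(trajectories, behavioral_table)``; CS/US ids default to
    those appearing in the design.
    """
    if cs_ids is None or us_ids is None:
        us_set = {t.us for t in design.trials}
        cs_set = [s for s in design.stimuli if s not in us_set]
        cs_ids = cs_ids if cs_ids is not None else tuple(cs_set)
        us_ids = us_ids if us_ids is not None else tuple(sorted(us_set))
    subjects = sample_subjects(spec, cs_ids, us_ids)
    trajectories = pd.concat(
        [run_design(design, params, subject_id=i) for i, params in enumerate(subjects)],
        ignore_index=True,
    )
    table = generate_counts(trajectories, spec)
    return trajectories, table
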
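"""Per-subject parameter recovery.

Estimates the perceived saliences (alpha_CS, beta_US) of a single
subject from an observed trajectory, by running the forward model over a
coarse grid on [0, 1]^2 and refining the best cell with a bounded
Nelder-Mead search.  The default loss is the sum of squared errors on
the R_CS / R_US components per trial x epoch; a Poisson likelihood on
sign/goal response counts is available for count data.

The scaling constant c, the within-trial decay and the count scale k are
taken as known and held fixed: they are not jointly identifiable with
(alpha, beta) from a single acquisition trajectory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    GOAL_RESPONSE,
    SIGN_RESPONSE,
    ConfigurationError,
    LinkMatrix,
    ValidationError,
    combine,
    decay_alpha,
    distribute,
)
from .designs import Design

__all__ = ["FitResult", "fit_subject", "fit_subjects", "forward_components"]

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Outcome of a single-subject fit."""

    alpha_hat: float
    beta_hat: float
    loss: float
    converged: bool
    trace: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "alpha_hat": self.alpha_hat,
            "beta_hat": self.beta_hat,
            "loss": self.loss,
            "converged": self.converged,
            "trace": self.trace,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _single_cs(design: Design) -> Tuple[str, str]:
    """The (cs, us) pair of a single-CS design; error otherwise."""
    if len(design) == 0:
        raise ConfigurationError("degenerate design: no trials")
    cues = {cue for t in design.trials for cue in t.cues}
    uss = {t.us for t in design.trials}
    if len(cues) != 1 or len(uss) != 1:
        raise ConfigurationError(
            "fitting supports single-CS single-US designs; got "
            f"cues={sorted(cues)}, uss={sorted(uss)}"
        )
    for t in design.trials:
        if len(t.cues) != 1:
            raise ConfigurationError("fitting requires one cue per trial")
    return cues.pop(), uss.pop()


def forward_components(
    design: Design,
    alpha: float,
    beta: float,
    c: float = 1.0,
    decay_per_epoch: float = 1.0,
    links: Optional[LinkMatrix] = None,
) -> pd.DataFrame:
    """Fast forward model for a single-CS design.

    Returns one row per trial x epoch with R_CS, R_US and the canonical
    sign (r1) / goal (r4) response vigors; identical to the corresponding
    columns of :func:`heidi.designs.run_design` but without the full
    state bookkeeping, which keeps repeated evaluation inside the fit
    loop cheap.
    """
    _single_cs(design)
    links = links or LinkMatrix()
    cs_w1, us_w1 = links.cs_links[SIGN_RESPONSE], links.us_links[SIGN_RESPONSE]
    cs_w4, us_w4 = links.cs_links[GOAL_RESPONSE], links.us_links[GOAL_RESPONSE]
    v_f = 0.0
    v_b = 0.0
    rows = []
    for trial_idx, trial in enumerate(design.trials, start=1):
        vcomb = combine(v_f, v_b, c)
        for epoch in range(1, trial.n_epochs + 1):
            a_eff = decay_alpha(alpha, epoch, decay_per_epoch)
            if vcomb == 0.0:
                r_cs, r_us = 0.0, 0.0
            else:
                r_cs, r_us = distribute(vcomb, a_eff, v_f, c)
            r1 = (r_cs * cs_w1 + r_us * us_w1) / c
            r4 = (r_cs * cs_w4 + r_us * us_w4) / c
            rows.append((trial_idx, epoch, r_cs, r_us, r1, r4))
        a_term = decay_alpha(alpha, trial.n_epochs, decay_per_epoch)
        if trial.reinforced:
            v_f += a_term * (c * beta - v_f)
            v_b += beta * (c * a_term - v_b)
        else:
            # CS alone: US asymptote term is zero, backward link frozen
            v_f += a_term * (0.0 - v_f)
    return pd.DataFrame(
        rows, columns=["trial", "epoch", "r_cs", "r_us", "r1", "r4"]
    )


def _align(observed: pd.DataFrame, design: Design, cols: List[str]) -> np.ndarray:
    """Validate that observed rows enumerate the design's trial x epoch
    records in order, and return the observation matrix."""
    if observed is None or len(observed) == 0:
        raise ConfigurationError("empty observations")
    for col in ["trial", "epoch"] + cols:
        if col not in observed.columns:
            raise ConfigurationError(f"observations lack column {col!r}")
    obs = observed.sort_values(["trial", "epoch"]).reset_index(drop=True)
    expected = [
        (i, e)
        for i, t in enumerate(design.trials, start=1)
        for e in range(1, t.n_epochs + 1)
    ]
    got = list(zip(obs["trial"].astype(int), obs["epoch"].astype(int)))
    if got != expected:
        raise ConfigurationError(
            "observations do not enumerate the design's trial x epoch records"
        )
    return obs[cols].to_numpy(dtype=float)


def fit_subject(
    observed: pd.DataFrame,
    design: Design,
    c: float = 1.0,
    decay_per_epoch: float = 1.0,
    links: Optional[LinkMatrix] = None,
    loss: str = "sse",
    count_scale: float = 20.0,
    grid_size: int = 11,
    refine: bool = True,
) -> FitResult:
    """Recover (alpha, beta) for one subject.

    ``loss='sse'`` expects observed columns r_cs, r_us (squared error);
    ``loss='poisson'`` expects sign_count, goal_count (negative Poisson
    log-likelihood with rates ``count_scale * max(r, 0)``).  Deterministic
    given the inputs and grid specification.
    """
    if grid_size < 2:
        raise ValidationError("grid_size must be >= 2")
    if loss == "sse":
        y = _align(observed, design, ["r_cs", "r_us"])

        def objective(ab: np.ndarray) -> float:
            sim = forward_components(
                design, ab[0], ab[1], c, decay_per_epoch, links
            )
            pred = sim[["r_cs", "r_us"]].to_numpy()
            return float(((pred - y) ** 2).sum())

    elif loss == "poisson":
        if count_scale <= 0:
            raise ValidationError("count_scale must be positive")
        y = _align(observed, design, ["sign_count", "goal_count"])

        def objective(ab: np.ndarray) -> float:
            sim = forward_components(
                design, ab[0], ab[1], c, decay_per_epoch, links
            )
            rates = count_scale * np.clip(sim[["r1", "r4"]].to_numpy(), 0, None)
            return float((rates - y * np.log(rates + 1e-9)).sum())

    else:
        raise ValidationError(f"unknown loss {loss!r}")

    if not any(not t.reinforced for t in design.trials):
        logger.info(
            "design has no nonreinforced trials; (alpha, beta) are inferred "
            "from acquisition curvature and the R_CS/R_US split alone"
        )

    grid = np.linspace(0.05, 0.95, grid_size)
    trace: List[dict] = []
    best_ab, best_loss = None, np.inf
    for a in grid:
        for b in grid:
            val = objective(np.array([a, b]))
            if val < best_loss:
                best_ab, best_loss = (float(a), float(b)), float(val)
    trace.append(
        {"stage": "grid", "alpha": best_ab[0], "beta": best_ab[1], "loss": best_loss}
    )

    converged = True
    alpha_hat, beta_hat, final_loss = best_ab[0], best_ab[1], best_loss
    if refine:
        res = optimize.minimize(
            objective,
            x0=np.array(best_ab),
            method="Nelder-Mead",
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 600},
        )
        alpha_hat = float(np.clip(res.x[0], 0.0, 1.0))
        beta_hat = float(np.clip(res.x[1], 0.0, 1.0))
        final_loss = float(res.fun)
        converged = bool(res.success)
        trace.append(
            {
                "stage": "refine",
                "alpha": alpha_hat,
                "beta": beta_hat,
                "loss": final_loss,
            }
        )
    return FitResult(alpha_hat, beta_hat, final_loss, converged, trace)


def fit_subjects(
    observed: pd.DataFrame,
    design: Design,
    subject_col: str = "subject",
    **kwargs,
) -> pd.DataFrame:
    """Batch :func:`fit_subject` over a long table with a subject column."""
    rows = []
    for subject, sub in observed.groupby(subject_col, sort=True):
        res = fit_subject(sub, design, **kwargs)
        rows.append(
            {
                "subject": subject,
                "alpha_hat": res.alpha_hat,
                "beta_hat": res.beta_hat,
                "loss": res.loss,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)
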
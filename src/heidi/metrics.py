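"""Summary analyses of trajectories and behavioural tables.

z-transformed epoch x block profiles put sign- and goal-tracking
measures on a common scale (standardization pools across blocks and
epochs within each group and response type), and cross-block Pearson
correlations quantify the stability of individual differences.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

__all__ = ["z_transform", "block_correlation", "epoch_profile"]


def z_transform(values, ddof: int = 0) -> np.ndarray:
    """Standardize to mean 0, SD 1.

    The population-SD convention (``ddof=0``) is the default; pass
    ``ddof=1`` for the sample-SD convention.  Raises on fewer than two
    values or zero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("z_transform requires at least 2 values")
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("z_transform undefined for zero-variance input")
    return (x - x.mean()) / sd


def block_correlation(
    table: pd.DataFrame,
    measure: str,
    block_x: str,
    block_y: str,
    subject_col: str = "subject",
    block_col: str = "block",
) -> float:
    """Pearson correlation of a per-subject measure between two blocks.

    Mirrors the block-5 vs block-6 stability analysis of response counts:
    each subject contributes one (x, y) point.  Symmetric in its block
    arguments.
    """
    wide = table.pivot_table(
        index=subject_col, columns=block_col, values=measure, aggfunc="sum"
    )
    for b in (block_x, block_y):
        if b not in wide.columns:
            raise ValidationError(f"block {b!r} not present in table")
    paired = wide[[block_x, block_y]].dropna()
    if len(paired) < 3:
        raise ValidationError("block_correlation requires >= 3 subjects")
    x = paired[block_x].to_numpy(dtype=float)
    y = paired[block_y].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in a block; correlation undefined")
    return float(stats.pearsonr(x, y)[0])


def epoch_profile(
    trajectory: pd.DataFrame,
    groups: Optional[Mapping] = None,
    sign_col: str = "r1",
    goal_col: str = "r4",
    ddof: int = 0,
) -> pd.DataFrame:
    """Group x response-type x block x epoch summary of z-scored measures.

    ``groups`` maps subject id -> group label (e.g. phenotype "ST"/"GT");
    omitted, all subjects form one group "all".  Within each (group,
    response type) the raw per-record values are z-transformed pooling
    across all block x epoch cells, then averaged per cell.  Returns a
    tidy frame with columns group, response, block, epoch, mean, sem.

    With within-trial salience decay active, the sign measure peaks in
    early epochs and the goal measure in late epochs; with decay 1 the
    epoch profiles are flat.
    """
    if trajectory.empty:
        raise ValidationError("empty trajectory")
    if trajectory["epoch"].nunique() < 2:
        raise ValidationError("epoch_profile requires >= 2 epochs")
    df = trajectory[["subject", "block", "epoch", sign_col, goal_col]].copy()
    if groups is None:
        df["group"] = "all"
    else:
        df["group"] = df["subject"].map(dict(groups))
        if df["group"].isna().any():
            missing = sorted(df.loc[df["group"].isna(), "subject"].unique())
            raise ValidationError(f"subjects without a group label: {missing}")
    long = df.melt(
        id_vars=["group", "subject", "block", "epoch"],
        value_vars=[sign_col, goal_col],
        var_name="response",
        value_name="value",
    )
    long["response"] = long["response"].map({sign_col: "sign", goal_col: "goal"})

    out = []
    for (group, response), sub in long.groupby(["group", "response"], sort=False):
        if sub.empty:
            raise ValidationError(f"empty group {group!r}")
        z = z_transform(sub["value"].to_numpy(), ddof=ddof)
        sub = sub.assign(z=z)
        cell = (
            sub.groupby(["block", "epoch"], sort=True)["z"]
            .agg(mean="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else np.nan)
            .reset_index()
        )
        cell.insert(0, "response", response)
        cell.insert(0, "group", group)
        out.append(cell)
    return pd.concat(out, ignore_index=True)
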
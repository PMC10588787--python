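"""Remission-trajectory taxonomy of analyte z-score profiles.

After correcting each analyte for age and sex, the three group means of its
z-scored residuals trace a healthy -> remission -> active trajectory.
Biomarker candidates fall into three behaviours: *non-normalising* markers
stay near the active level during remission, *normalising* markers return
close to the healthy level, and *exceptional* markers break the monotone
pattern entirely — either the healthy mean lies strictly between the other
two, or the active mean lies strictly between healthy and remission (a
marker more deregulated in remission than in flare).

"Close to" is operationalized as a fraction delta (default 1/3) of the
healthy <-> active span; profiles near neither end and not exceptional are
reported as *intermediate* rather than forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .containers import GROUPS, AnalyteMatrix, SampleMeta, TriomicsError, warn

DEFAULT_DELTA = 1.0 / 3.0

CLASS_NORMALISING = "normalising"
CLASS_NON_NORMALISING = "non_normalising"
CLASS_EXCEPTIONAL = "exceptional"
CLASS_INTERMEDIATE = "intermediate"
CLASS_NO_SIGNAL = "no_signal"

SUBTYPE_HEALTHY_BETWEEN = "healthy_between"
SUBTYPE_ACTIVE_BETWEEN = "active_between"


@dataclass(frozen=True)
class TrajectoryProfile:
    analyte: str
    block: str
    z_healthy: float
    z_remission: float
    z_active: float
    trajectory_class: str
    subtype: Optional[str]
    delta: float


def corrected_group_zscores(
    matrix: AnalyteMatrix, meta: SampleMeta
) -> pd.DataFrame:
    """Confounder-corrected group-mean z-scores per analyte.

    Each analyte's log2 values are residualized on age and sex (least
    squares with intercept), the residuals are z-scored across all samples
    (sample sd), and the group means of those z-scores are returned as a
    DataFrame with columns z_healthy, z_remission, z_active.
    """
    matrix.require_complete("trajectory z-scores require imputed data")
    meta.check_alignment(matrix)
    Y = matrix.values.to_numpy(dtype=float)
    age = meta.age.to_numpy()
    X = np.column_stack([np.ones_like(age), age - age.mean(), meta.sex.to_numpy()])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=1)
    scale = np.abs(Y).max(axis=0)
    flat = sd <= 1e-10 * np.maximum(scale, 1.0)
    if flat.any():
        warn(f"{int(flat.sum())} analyte(s) with zero residual variance: z set to 0")
    sd = np.where(flat, 1.0, sd)
    z = resid / sd[None, :]
    z[:, flat] = 0.0
    out = {}
    groups = meta.group.to_numpy()
    for g in GROUPS:
        out[f"z_{g}"] = z[groups == g].mean(axis=0)
    return pd.DataFrame(out, index=matrix.analyte_ids)


def classify_trajectory(
    z_h: float, z_r: float, z_a: float, delta: float = DEFAULT_DELTA
) -> Tuple[str, Optional[str]]:
    """Assign one analyte's trajectory class from its three group z-means.

    Rule, applied in order:
      1. no healthy <-> active separation -> ``no_signal``;
      2. remission within delta * |z_a - z_h| of healthy -> ``normalising``;
         of active -> ``non_normalising`` (the closer end wins if delta
         admits both);
      3. otherwise, healthy strictly between remission and active ->
         ``exceptional`` (healthy_between); active strictly between healthy
         and remission -> ``exceptional`` (active_between);
      4. otherwise ``intermediate``.

    The delta-closeness classes are tested before betweenness so that a
    marker sitting essentially at the healthy (or active) level is never
    tipped into ``exceptional`` by sampling noise on which side of that
    level its remission mean falls.
    """
    if delta < 0:
        raise TriomicsError("delta must be non-negative")
    span = abs(z_a - z_h)
    if span == 0:
        return CLASS_NO_SIGNAL, None
    d_h = abs(z_r - z_h)
    d_a = abs(z_r - z_a)
    near_h = d_h <= delta * span
    near_a = d_a <= delta * span
    if near_h and (not near_a or d_h <= d_a):
        return CLASS_NORMALISING, None
    if near_a:
        return CLASS_NON_NORMALISING, None
    if min(z_r, z_a) < z_h < max(z_r, z_a):
        return CLASS_EXCEPTIONAL, SUBTYPE_HEALTHY_BETWEEN
    if min(z_h, z_r) < z_a < max(z_h, z_r):
        return CLASS_EXCEPTIONAL, SUBTYPE_ACTIVE_BETWEEN
    return CLASS_INTERMEDIATE, None


def classify_block(
    matrix: AnalyteMatrix,
    meta: SampleMeta,
    delta: float = DEFAULT_DELTA,
) -> pd.DataFrame:
    """Trajectory table for one block: z-means, class and sub-type."""
    zs = corrected_group_zscores(matrix, meta)
    rows = []
    for analyte, row in zs.iterrows():
        cls, subtype = classify_trajectory(
            row["z_healthy"], row["z_remission"], row["z_active"], delta=delta
        )
        rows.append(
            {
                "analyte": analyte,
                "block": matrix.block_label,
                "z_healthy": row["z_healthy"],
                "z_remission": row["z_remission"],
                "z_active": row["z_active"],
                "trajectory_class": cls,
                "subtype": subtype if subtype else "",
                "delta": delta,
            }
        )
    return pd.DataFrame(rows)
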
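"""Block-wise filtering, transformation and imputation rules.

Three omics blocks arrive with different gaps. Protein intensities carry
technically missing values: analytes are first filtered by a minimum number
of valid values in at least one group, then the remaining holes are filled
from a down-shifted Gaussian (Perseus-style: mean shifted down by 1.8
standard deviations, width 0.3 standard deviations, both per analyte).
Eicosanoid intensities are left-censored at the detection limit: censored
cells are set to the analyte's minimum observed value divided by sqrt(2),
then the whole block is log2-transformed. Metabolite values below the kit's
quantification window are handled by the same min/sqrt(2) rule for
consistency.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .containers import (
    GROUPS,
    SCALE_LOG2,
    SCALE_RAW,
    AnalyteMatrix,
    SampleMeta,
    TriomicsError,
    warn,
)

DOWNSHIFT_SD = 1.8
DOWNSHIFT_WIDTH = 0.3


def filter_by_valid_values(
    matrix: AnalyteMatrix, meta: SampleMeta, min_valid: int
) -> AnalyteMatrix:
    """Keep analytes with >= ``min_valid`` observed values in at least one group.

    Plasma blocks use ``min_valid=3``, tissue proteomics ``min_valid=5``.
    Retained analyte order is preserved; the operation is idempotent.
    """
    if min_valid < 1:
        raise TriomicsError("min_valid must be >= 1")
    meta.check_alignment(matrix)
    observed = matrix.observed_mask
    best = pd.Series(0, index=matrix.analyte_ids)
    for group in GROUPS:
        members = meta.group_members(group)
        if len(members) == 0:
            continue
        best = np.maximum(best, observed.loc[members].sum(axis=0))
    keep = matrix.analyte_ids[best >= min_valid]
    if len(keep) == 0:
        warn(
            f"filter_by_valid_values(min_valid={min_valid}) removed every "
            f"analyte of block {matrix.block_label!r}"
        )
    return matrix.select_analytes(keep)


def impute_gaussian_downshift(
    matrix: AnalyteMatrix,
    shift: float = DOWNSHIFT_SD,
    width: float = DOWNSHIFT_WIDTH,
    seed: int = 0,
) -> AnalyteMatrix:
    """Fill missing cells from Normal(mu_c - shift*sd_c, (width*sd_c)^2).

    mu_c and sd_c are the mean and sample standard deviation of the observed
    values of analyte c (the Perseus per-column convention). An analyte with
    fewer than two observed values has no defined sd; the whole-matrix sd of
    observed values is used instead. Deterministic given ``seed``.
    """
    if matrix.scale != SCALE_LOG2:
        raise TriomicsError("down-shift imputation expects log2 intensities")
    out = matrix.copy()
    vals = out.values.to_numpy(dtype=float)
    holes = ~out.observed_mask.to_numpy()
    if not holes.any():
        return out
    rng = np.random.default_rng(seed)
    observed = np.where(holes, np.nan, vals)
    global_sd = float(np.nanstd(observed, ddof=1))
    global_mean = float(np.nanmean(observed))
    n_obs = (~np.isnan(observed)).sum(axis=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(observed, axis=0)
        sd = np.nanstd(observed, axis=0, ddof=1)
    fallback = n_obs < 2
    if fallback.any():
        warn(
            f"{int(fallback.sum())} analyte(s) with < 2 observed values: "
            "using the whole-matrix sd (and mean where needed) for imputation"
        )
        sd = np.where(fallback, global_sd, sd)
        mu = np.where(n_obs < 1, global_mean, mu)
    draw = rng.standard_normal(vals.shape) * (width * sd)[None, :] + (
        mu - shift * sd
    )[None, :]
    vals[holes] = draw[holes]
    out.values = pd.DataFrame(vals, index=out.sample_ids, columns=out.analyte_ids)
    shaped = pd.DataFrame(holes, index=out.sample_ids, columns=out.analyte_ids)
    out.imputed_mask = out.imputed_mask | shaped
    out.missing_mask = out.missing_mask & ~shaped
    out.below_lod_mask = out.below_lod_mask & ~shaped
    return out


def impute_lod_min_over_sqrt2(matrix: AnalyteMatrix) -> AnalyteMatrix:
    """Impute below-LOD cells with min_observed/sqrt(2), then log2-transform.

    Operates on the raw scale. An analyte with no observed value at all
    cannot be imputed and is dropped with a warning. Observed values are
    untouched before the final log2 transform.
    """
    if matrix.scale != SCALE_RAW:
        raise TriomicsError("min/sqrt(2) imputation expects raw-scale intensities")
    out = matrix.copy()
    vals = out.values.to_numpy(dtype=float)
    observed = out.observed_mask.to_numpy()
    n_obs = observed.sum(axis=0)
    dead = n_obs == 0
    if dead.any():
        dropped = list(out.analyte_ids[dead])
        warn(
            f"dropping {len(dropped)} analyte(s) with no observed value: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
        out = out.select_analytes(out.analyte_ids[~dead])
        vals = out.values.to_numpy(dtype=float)
        observed = out.observed_mask.to_numpy()
    if (vals[observed] <= 0).any():
        raise TriomicsError("raw-scale intensities must be positive")
    col_min = np.where(observed, vals, np.inf).min(axis=0)
    lod = out.below_lod_mask.to_numpy()
    fill = np.broadcast_to(col_min / np.sqrt(2.0), vals.shape)
    vals = np.where(lod, fill, vals)
    # any remaining technically-missing cells stay NaN through the log2
    out.values = pd.DataFrame(
        np.log2(vals), index=out.sample_ids, columns=out.analyte_ids
    )
    out.imputed_mask = out.imputed_mask | out.below_lod_mask
    out.below_lod_mask = out.below_lod_mask & False
    return replace(out, scale=SCALE_LOG2)


def zscore_by_analyte(matrix: AnalyteMatrix) -> AnalyteMatrix:
    """Standardize each analyte to mean 0, sd 1 (sample sd) across samples.

    Constant analytes are set to all-zero with a warning. Idempotent up to
    floating-point error.
    """
    matrix.require_complete("z-scoring requires imputation first")
    out = matrix.copy()
    vals = out.values.to_numpy(dtype=float)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        warn(f"{int(flat.sum())} zero-variance analyte(s) z-scored to 0")
    sd = np.where(flat, 1.0, sd)
    z = (vals - mu[None, :]) / sd[None, :]
    z[:, flat] = 0.0
    out.values = pd.DataFrame(z, index=out.sample_ids, columns=out.analyte_ids)
    return out
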
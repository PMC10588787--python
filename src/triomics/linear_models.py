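"""Per-analyte differential analysis: moderated contrasts, t-tests, PCA.

Stage 1 of the integration method fits one linear model per analyte with
group indicators plus age and sex, shrinks the residual variances toward a
common prior with an empirical-Bayes scheme, and tests three pairwise
contrasts (healthy vs active, healthy vs remission, remission vs active) at
a Benjamini–Hochberg FDR of 5%.

The variance shrinkage follows the classical moment-matching construction:
the residual variances s_g^2 (df d) are modelled as scaled F around a prior
s_0^2 with d_0 prior df; (d_0, s_0^2) are estimated from the first two
moments of log s_g^2 via a trigamma inversion, and the posterior variance is

    s~_g^2 = (d_0 s_0^2 + d s_g^2) / (d_0 + d)

giving a moderated t with d_0 + d degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import GROUPS, AnalyteMatrix, SampleMeta, TriomicsError, warn

DEFAULT_Q = 0.05
CONTRAST_NAMES = ("healthy_vs_active", "healthy_vs_remission", "remission_vs_active")


@dataclass(frozen=True)
class ContrastSpec:
    """A pairwise group comparison, coded as group-coefficient differences."""

    name: str
    coefficients: Tuple[float, float, float]  # over (healthy, remission, active)

    def __post_init__(self) -> None:
        if abs(sum(self.coefficients)) > 1e-12:
            raise TriomicsError("contrast coefficients must sum to zero")

    @staticmethod
    def from_name(name: str) -> "ContrastSpec":
        try:
            a, b = name.split("_vs_")
            ia, ib = GROUPS.index(a), GROUPS.index(b)
        except ValueError:
            raise TriomicsError(f"malformed contrast name {name!r}") from None
        coef = [0.0, 0.0, 0.0]
        # estimate = mean(b) - mean(a): positive means "up in the later state"
        coef[ib], coef[ia] = 1.0, -1.0
        return ContrastSpec(name, tuple(coef))


def default_contrasts() -> List[ContrastSpec]:
    return [ContrastSpec.from_name(n) for n in CONTRAST_NAMES]


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes prior: d0 prior df (may be inf), s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise TriomicsError("prior df must be >= 0")
        if not (self.s0_sq > 0) and np.isfinite(self.d0) and self.d0 > 0:
            raise TriomicsError("prior variance must be positive")


@dataclass
class ContrastResult:
    """Tidy per-(analyte, contrast) statistics table.

    Columns: analyte, block, contrast, estimate, t, df, p, p_adj,
    significant. ``prior`` records the fitted moderation prior (None for
    plain t-tests).
    """

    table: pd.DataFrame
    q: float = DEFAULT_Q
    prior: Optional[ModerationPrior] = None

    def for_contrast(self, contrast: str) -> pd.DataFrame:
        sub = self.table[self.table["contrast"] == contrast]
        if sub.empty:
            raise TriomicsError(f"no results for contrast {contrast!r}")
        return sub.set_index("analyte")

    def significant_analytes(self, contrast: str) -> List[str]:
        sub = self.for_contrast(contrast)
        return list(sub.index[sub["significant"]])

    @property
    def contrasts(self) -> List[str]:
        return list(dict.fromkeys(self.table["contrast"]))


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise TriomicsError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> ModerationPrior:
    """Moment-match a scaled-F prior to the observed residual variances.

    Works on z = log(s^2): E[z] and Var[z] have closed forms in terms of
    digamma/trigamma functions of d/2 and d0/2, which are inverted here.
    A non-positive excess variance of z means the variances are at least as
    concentrated as sampling alone predicts, giving d0 = inf (complete
    shrinkage to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 4:
        warn("fewer than 4 usable analytes: no moderation (d0 = 0)")
        med = float(np.median(s2[ok])) if ok.any() else 1.0
        return ModerationPrior(d0=0.0, s0_sq=med)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    excess = float(np.var(e, ddof=1) - special.polygamma(1, df / 2.0))
    if excess <= 0:
        return ModerationPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def _design(meta: SampleMeta) -> Tuple[np.ndarray, List[str]]:
    """Group indicators (no intercept) plus centred age and sex.

    Only groups actually present contribute a column, so the same design
    builder serves both the joint three-group fit and pairwise subsets.
    """
    g = meta.group.to_numpy()
    present = [grp for grp in GROUPS if (g == grp).any()]
    cols = [np.asarray(g == grp, dtype=float) for grp in present]
    age = meta.age.to_numpy()
    cols.append(age - age.mean())
    cols.append(meta.sex.to_numpy())
    X = np.column_stack(cols)
    names = present + ["age", "sex"]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by dropping one at a time
        collinear = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise TriomicsError(f"rank-deficient design; collinear columns: {collinear}")
    return X, names


def fit_moderated_contrasts(
    matrix: AnalyteMatrix,
    meta: SampleMeta,
    contrasts: Optional[Sequence[ContrastSpec]] = None,
    q: float = DEFAULT_Q,
    prior: Optional[ModerationPrior] = None,
    groups_subset: bool = False,
) -> ContrastResult:
    """Fit per-analyte linear models and test moderated contrasts.

    ``prior=None`` estimates (d0, s0^2) from the data; passing an explicit
    :class:`ModerationPrior` overrides it (d0=0 reproduces ordinary t
    statistics, d0=inf full shrinkage). ``groups_subset=True`` refits each
    contrast on the two involved groups only instead of the joint
    three-group fit.
    """
    matrix.require_complete("fit models after imputation")
    meta.check_alignment(matrix)
    if contrasts is None:
        contrasts = default_contrasts()
    for g in GROUPS:
        if len(meta.group_members(g)) < 2:
            raise TriomicsError(f"group {g!r} has fewer than 2 samples")

    if groups_subset:
        frames, priors = [], []
        for spec in contrasts:
            keep_groups = {g for g, c in zip(GROUPS, spec.coefficients) if c != 0}
            keep = meta.table.index[meta.group.isin(keep_groups)]
            sub_meta = SampleMeta(meta.table.loc[keep])
            sub = matrix.copy()
            sub.values = sub.values.loc[keep]
            sub.missing_mask = sub.missing_mask.loc[keep]
            sub.below_lod_mask = sub.below_lod_mask.loc[keep]
            sub.imputed_mask = sub.imputed_mask.loc[keep]
            res = _fit_joint(sub, sub_meta, [spec], q, prior)
            frames.append(res.table)
            priors.append(res.prior)
        return ContrastResult(
            pd.concat(frames, ignore_index=True), q=q, prior=priors[0]
        )
    return _fit_joint(matrix, meta, list(contrasts), q, prior)


def _fit_joint(
    matrix: AnalyteMatrix,
    meta: SampleMeta,
    contrasts: List[ContrastSpec],
    q: float,
    prior: Optional[ModerationPrior],
) -> ContrastResult:
    X, names = _design(meta)
    group_cols = [nm for nm in names if nm in GROUPS]
    n, k = X.shape
    Y = matrix.values.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Y  # k x p
    resid = Y - X @ B
    df = n - k
    if df < 1:
        raise TriomicsError("no residual degrees of freedom")
    s2 = (resid**2).sum(axis=0) / df

    if prior is None:
        if matrix.n_analytes < 4:
            warn("fewer than 4 analytes: prior estimation skipped, d0 = 0")
            prior = ModerationPrior(d0=0.0, s0_sq=float(np.median(s2)))
        else:
            prior = estimate_prior(s2, df)
    d0, s0_sq = prior.d0, prior.s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    rows = []
    for spec in contrasts:
        c = np.zeros(k)
        for gi, grp in enumerate(group_cols):
            c[gi] = spec.coefficients[GROUPS.index(grp)]
        wanted = {g for g, w in zip(GROUPS, spec.coefficients) if w != 0}
        if not wanted <= set(group_cols):
            raise TriomicsError(
                f"contrast {spec.name!r} involves groups absent from the data"
            )
        est = c @ B
        v = float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / np.sqrt(s2_post * v)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p_adj = adjust_bh(p)
        rows.append(
            pd.DataFrame(
                {
                    "analyte": matrix.analyte_ids,
                    "block": matrix.block_label,
                    "contrast": spec.name,
                    "estimate": est,
                    "t": t,
                    "df": df_total,
                    "p": p,
                    "p_adj": p_adj,
                    "significant": p_adj <= q,
                }
            )
        )
    return ContrastResult(pd.concat(rows, ignore_index=True), q=q, prior=prior)


def adjust_bh(raw_p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise TriomicsError("BH adjustment received NaN p-values")
    if (p < 0).any() or (p > 1).any():
        raise TriomicsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_sided_ttests(
    matrix: AnalyteMatrix,
    meta: SampleMeta,
    group_a: str,
    group_b: str,
    q: float = DEFAULT_Q,
) -> ContrastResult:
    """Welch two-sample t-test per analyte (group_b minus group_a)."""
    matrix.require_complete()
    meta.check_alignment(matrix)
    ia, ib = meta.group_members(group_a), meta.group_members(group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise TriomicsError("each group needs at least 2 samples for a t-test")
    A = matrix.values.loc[ia].to_numpy(dtype=float)
    Bv = matrix.values.loc[ib].to_numpy(dtype=float)
    res = stats.ttest_ind(Bv, A, axis=0, equal_var=False)
    est = Bv.mean(axis=0) - A.mean(axis=0)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    t = np.where(np.isnan(res.statistic), 0.0, res.statistic)
    p_adj = adjust_bh(p)
    table = pd.DataFrame(
        {
            "analyte": matrix.analyte_ids,
            "block": matrix.block_label,
            "contrast": f"{group_a}_vs_{group_b}",
            "estimate": est,
            "t": t,
            "df": res.df if hasattr(res, "df") else np.nan,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj <= q,
        }
    )
    return ContrastResult(table, q=q, prior=None)


def pca_samples(
    matrix: AnalyteMatrix, n_components: int, scale: bool = True
) -> Tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Sample-space PCA of one block.

    Analytes are centred and (by default) scaled to unit sample sd. Returns
    (scores, loadings, variance-explained fractions). Loadings are
    orthonormal; the sign convention makes each component's
    largest-magnitude loading positive.
    """
    matrix.require_complete("PCA requires a complete matrix")
    n, p = matrix.values.shape
    if not (1 <= n_components <= min(n, p)):
        raise TriomicsError(
            f"n_components must lie in [1, {min(n, p)}], got {n_components}"
        )
    X = matrix.values.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = float((S**2).sum())
    var_frac = S**2 / total_var if total_var > 0 else np.zeros_like(S)
    # deterministic sign: largest-|loading| entry positive per component
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = pd.DataFrame(
        (U * S)[:, :n_components],
        index=matrix.sample_ids,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    loadings = pd.DataFrame(
        Vt[:n_components].T,
        index=matrix.analyte_ids,
        columns=scores.columns,
    )
    return scores, loadings, var_frac[:n_components]
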
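"""Sub-network association tests, K selection, and PC summarization.

Each candidate sub-network is scored against each contrast with a signed
Stouffer statistic built from the member analytes' raw p-values and
regulation directions,

    S = (1 / sqrt(m)) * sum_j sign(estimate_j) * Phi^{-1}(1 - p_j / 2),

and calibrated by resampling m analytes from the block's analyte universe
(two-sided permutation p). Within each (K, contrast) stratum the
permutation p-values are BH-adjusted at q = 0.05. The penalty multiplier K
is then fixed at the value yielding the largest number of significant
(sub-network, contrast) pairs, ties broken toward the sparser (smaller K)
solution. Each chosen sub-network is finally summarized by its first
principal component, or the first two when PC1 explains less than 75% of
the member variance (strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnalyteMatrix, TriomicsError, warn
from .ggm import KSweepResult, SubNetwork
from .linear_models import ContrastResult, adjust_bh, pca_samples
from .preprocess import zscore_by_analyte

PC1_THRESHOLD = 0.75
DEFAULT_N_PERM = 10_000


@dataclass
class SetAssociation:
    subnetwork: SubNetwork
    contrast: str
    statistic: float
    p: float
    p_adj: float = np.nan
    significant: bool = False


@dataclass
class SubNetworkSummary:
    subnetwork: SubNetwork
    scores: pd.DataFrame  # samples x (1 or 2) components
    loadings: pd.DataFrame
    pc1_variance_fraction: float

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _signed_z(p: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    eps = np.finfo(float).tiny
    if (p <= 0).any():
        warn("p-values of 0 clipped to the machine-epsilon floor")
    p = np.clip(p, eps, 1.0)
    return np.sign(estimate) * stats.norm.isf(p / 2.0)


def test_subnetwork(
    subnet: SubNetwork,
    analyte_stats: ContrastResult,
    contrast: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> SetAssociation:
    """Signed-Stouffer set statistic with an analyte-resampling null.

    The null resamples member sets of the same size from all analytes of the
    sub-network's block that have a statistic for the contrast, so the
    permutation p answers: is this set more coherently regulated than a
    random set of analytes from the same block?
    """
    stats_table = analyte_stats.for_contrast(contrast)
    stats_table = stats_table[stats_table["block"] == subnet.block_label]
    missing = [m for m in subnet.members if m not in stats_table.index]
    if missing:
        raise TriomicsError(
            f"sub-network members without contrast statistics: {missing[:5]}"
        )
    m = subnet.size
    if m < 2:
        raise TriomicsError("set test needs at least 2 members")
    z_all = _signed_z(
        stats_table["p"].to_numpy(), stats_table["estimate"].to_numpy()
    )
    member_pos = stats_table.index.get_indexer(list(subnet.members))
    s_obs = float(z_all[member_pos].sum() / np.sqrt(m))

    n_universe = len(stats_table)
    if n_universe <= m:
        raise TriomicsError("analyte universe no larger than the sub-network")
    rng = np.random.default_rng(seed)
    # m smallest of random keys per row = a uniform m-subset, vectorized
    keys = rng.random((n_perm, n_universe))
    idx = np.argpartition(keys, m, axis=1)[:, :m]
    s_perm = z_all[idx].sum(axis=1) / np.sqrt(m)
    p = float((1 + np.sum(np.abs(s_perm) >= abs(s_obs))) / (n_perm + 1))
    return SetAssociation(subnetwork=subnet, contrast=contrast, statistic=s_obs, p=p)


def associate_subnetworks(
    sweep: KSweepResult,
    analyte_stats: Dict[str, ContrastResult],
    contrasts: Sequence[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    q: float = 0.05,
) -> Dict[float, List[SetAssociation]]:
    """Test every sub-network at every K against every contrast.

    ``analyte_stats`` maps block label to that block's stage-1 results.
    BH adjustment is applied within each (K, contrast) stratum.
    """
    rng = np.random.default_rng(seed)
    out: Dict[float, List[SetAssociation]] = {}
    for K in sweep.grid:
        assocs: List[SetAssociation] = []
        for contrast in contrasts:
            batch = []
            for subnet in sweep.subnetworks[K]:
                child = int(rng.integers(0, 2**31 - 1))
                batch.append(
                    test_subnetwork(
                        subnet,
                        analyte_stats[subnet.block_label],
                        contrast,
                        n_perm=n_perm,
                        seed=child,
                    )
                )
            if batch:
                p_adj = adjust_bh(np.array([a.p for a in batch]))
                for a, adj in zip(batch, p_adj):
                    a.p_adj = float(adj)
                    a.significant = bool(adj <= q)
            assocs.extend(batch)
        out[K] = assocs
    return out


@dataclass
class ChosenK:
    """Outcome of the K sweep; ``K`` is None when nothing was significant."""

    K: Optional[float]
    significant: List[SetAssociation]
    counts: pd.DataFrame  # K x count of significant (sub-network, contrast) pairs

    @property
    def is_sentinel(self) -> bool:
        return self.K is None

    def chosen_subnetworks(self) -> List[SubNetwork]:
        seen: Dict[str, SubNetwork] = {}
        for a in self.significant:
            seen.setdefault(a.subnetwork.id, a.subnetwork)
        return list(seen.values())


def choose_K(
    sweep: KSweepResult, associations: Dict[float, List[SetAssociation]]
) -> ChosenK:
    """Pick the K with the most significant (sub-network, contrast) pairs.

    Ties break toward smaller K. With no significant pair at any K a
    sentinel is returned and the pipeline proceeds with single analytes
    only.
    """
    missing = [K for K in sweep.grid if K not in associations]
    if missing:
        raise TriomicsError(f"associations missing for K values: {missing}")
    counts = pd.DataFrame(
        {
            "K": list(sweep.grid),
            "n_significant": [
                sum(a.significant for a in associations[K]) for K in sweep.grid
            ],
        }
    )
    if counts["n_significant"].max() == 0:
        return ChosenK(K=None, significant=[], counts=counts)
    best = counts.loc[counts["n_significant"].idxmax(), "K"]  # idxmax: first max
    chosen = float(best)
    return ChosenK(
        K=chosen,
        significant=[a for a in associations[chosen] if a.significant],
        counts=counts,
    )


def summarize_pcs(
    matrix: AnalyteMatrix, subnet: SubNetwork, threshold: float = PC1_THRESHOLD
) -> SubNetworkSummary:
    """PC summary of a sub-network's member analytes (standardized).

    Returns PC1 alone when its variance fraction is >= ``threshold``
    (strictly below 75% adds PC2).
    """
    missing = [m for m in subnet.members if m not in matrix.analyte_ids]
    if missing:
        raise TriomicsError(f"sub-network members absent from matrix: {missing[:5]}")
    sub = zscore_by_analyte(matrix.select_analytes(subnet.members))
    n_comp = min(2, sub.n_samples, sub.n_analytes)
    scores, loadings, var_frac = pca_samples(sub, n_comp, scale=False)
    pc1_frac = float(var_frac[0])
    # strictly-below rule; fractions within floating-point distance of the
    # threshold count as "at" it and keep a single component
    keep = 1 if pc1_frac >= threshold - 1e-9 or n_comp == 1 else 2
    return SubNetworkSummary(
        subnetwork=subnet,
        scores=scores.iloc[:, :keep],
        loadings=loadings.iloc[:, :keep],
        pc1_variance_fraction=pc1_frac,
    )


def association_table(associations: Dict[float, List[SetAssociation]]) -> pd.DataFrame:
    rows = [
        {
            "K": K,
            "subnetwork": a.subnetwork.id,
            "block": a.subnetwork.block_label,
            "size": a.subnetwork.size,
            "contrast": a.contrast,
            "statistic": a.statistic,
            "p": a.p,
            "p_adj": a.p_adj,
            "significant": a.significant,
        }
        for K, assocs in associations.items()
        for a in assocs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "K",
            "subnetwork",
            "block",
            "size",
            "contrast",
            "statistic",
            "p",
            "p_adj",
            "significant",
        ],
    )
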
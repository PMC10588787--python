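"""Synthetic three-block omics studies with known ground truth.

The generator emulates the structure of a three-group (healthy / remission /
active) plasma multiomics study: three analyte blocks with planted
sub-network correlation structure, additive group mean shifts per contrast,
age and sex confounding, left-censoring at a detection limit for the
eicosanoid block, and missing-completely-at-random values for the protein
block. Everything planted is recorded in a :class:`GroundTruth` so each
downstream stage can be tested for recovery without any external data.

Correlation structure of a planted sub-network uses a single shared latent
factor per set: for loading rho in (0, 1] each member is

    x_j = rho * f + sqrt(1 - rho^2) * eps_j

with f and eps_j standard normal, so the expected pairwise Pearson
correlation within the set is rho^2 and the conditional-independence graph
over the set is a clique. All signals are additive on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import (
    BLOCKS,
    GROUPS,
    SCALE_RAW,
    AnalyteMatrix,
    SampleMeta,
    TriomicsError,
)

TRAJECTORY_CLASSES = ("normalising", "non_normalising", "exceptional")

# (block, index-set, loading)
PlantedBlock = Tuple[str, Tuple[int, ...], float]
# (block, index-set, contrast-name, log2 shift applied to the second group)
PlantedEffect = Tuple[str, Tuple[int, ...], str, float]

CONTRASTS = ("healthy_vs_active", "healthy_vs_remission", "remission_vs_active")

AGE_RANGE = (25.0, 65.0)  # matches the cohort's span without its imbalance
BASELINE_RANGE = (12.0, 20.0)  # log2 intensity baselines, plasma-like


def _contrast_groups(contrast: str) -> Tuple[str, str]:
    try:
        a, b = contrast.split("_vs_")
    except ValueError:
        raise TriomicsError(f"malformed contrast name {contrast!r}") from None
    if a not in GROUPS or b not in GROUPS:
        raise TriomicsError(f"unknown groups in contrast {contrast!r}")
    return a, b


@dataclass
class SimulationConfig:
    """Declarative description of one synthetic study.

    ``effects`` shifts the mean of the *second* group named in the contrast
    (e.g. ``healthy_vs_active`` shifts the active group) by the given amount
    in log2 units. ``trajectory_profiles`` maps (block, analyte index) to an
    intended trajectory class; the corresponding group means are planted so
    the class is recoverable. Confounder slopes act on centred age (per
    year) and on the 0/1 sex indicator.
    """

    n_per_group: int = 12
    block_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"protein": 60, "eicosanoid": 24, "metabolite": 90}
    )
    planted_blocks: Sequence[PlantedBlock] = ()
    effects: Sequence[PlantedEffect] = ()
    trajectory_profiles: Mapping[Tuple[str, int], str] = field(default_factory=dict)
    # planted healthy->active span in residual SDs; 2.5 keeps the delta=1/3
    # class boundaries ~2 group-mean standard errors away at n=12 per group
    trajectory_magnitude: float = 2.5
    age_effect: Mapping[Tuple[str, int], float] = field(default_factory=dict)
    sex_effect: Mapping[Tuple[str, int], float] = field(default_factory=dict)
    lod_quantile: float = 0.0
    missing_rate: float = 0.0
    noise_sd: float = 1.0
    mnar_missingness: bool = False  # optional intensity-dependent mode
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise TriomicsError("n_per_group must be >= 3")
        if not (0.0 <= self.lod_quantile < 1.0):
            raise TriomicsError("lod_quantile must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise TriomicsError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise TriomicsError("noise_sd must be positive")
        for block in self.block_sizes:
            if block not in BLOCKS:
                raise TriomicsError(f"unknown block {block!r}")
        claimed: Dict[str, set] = {b: set() for b in self.block_sizes}
        for block, idx, loading in self.planted_blocks:
            idx = tuple(idx)
            size = self.block_sizes.get(block)
            if size is None:
                raise TriomicsError(f"planted block refers to unknown block {block!r}")
            if not idx or min(idx) < 0 or max(idx) >= size:
                raise TriomicsError(f"planted index set out of range for {block!r}")
            if not (0.0 < loading <= 1.0):
                raise TriomicsError("latent-factor loading must lie in (0, 1]")
            if claimed[block] & set(idx):
                raise TriomicsError(
                    f"planted blocks overlap within block {block!r}"
                )
            claimed[block] |= set(idx)
        for block, idx, contrast, _shift in self.effects:
            _contrast_groups(contrast)
            size = self.block_sizes.get(block)
            if size is None:
                raise TriomicsError(f"effect refers to unknown block {block!r}")
            idx = tuple(idx)
            if idx and (min(idx) < 0 or max(idx) >= size):
                raise TriomicsError(f"effect index set out of range for {block!r}")
        for (block, j), cls in self.trajectory_profiles.items():
            if block not in self.block_sizes or not 0 <= j < self.block_sizes[block]:
                raise TriomicsError(f"trajectory profile out of range: {(block, j)}")
            if cls not in TRAJECTORY_CLASSES:
                raise TriomicsError(f"unknown trajectory class {cls!r}")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic study, for recovery checks."""

    true_effect_sets: Dict[str, List[Tuple[str, str]]]  # contrast -> (block, analyte id)
    true_partition: Dict[str, List[List[str]]]  # block -> planted member id sets
    true_trajectory: Dict[Tuple[str, str], str]  # (block, analyte id) -> class

    def to_jsonable(self) -> dict:
        return {
            "true_effect_sets": {
                c: [list(pair) for pair in pairs]
                for c, pairs in self.true_effect_sets.items()
            },
            "true_partition": self.true_partition,
            "true_trajectory": {
                f"{b}::{a}": cls for (b, a), cls in self.true_trajectory.items()
            },
        }


@dataclass
class SyntheticStudy:
    blocks: Dict[str, AnalyteMatrix]
    meta: SampleMeta
    truth: GroundTruth


def _trajectory_group_means(cls: str, span: float) -> Dict[str, float]:
    """Group mean shifts realising one trajectory class.

    The healthy group is the reference (0). ``span`` is the planted
    healthy -> active distance in log2 units.
    """
    if cls == "normalising":
        return {"healthy": 0.0, "remission": 0.0, "active": span}
    if cls == "non_normalising":
        return {"healthy": 0.0, "remission": span, "active": span}
    # exceptional: healthy strictly between remission and active
    return {"healthy": 0.0, "remission": -span, "active": span}


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Simulate one three-block study; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = 3 * config.n_per_group
    groups = np.repeat(list(GROUPS), config.n_per_group)
    sample_ids = pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id")
    age = rng.uniform(*AGE_RANGE, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    meta = SampleMeta(
        pd.DataFrame({"group": groups, "age": age, "sex": sex}, index=sample_ids)
    )
    age_centred = age - age.mean()

    truth = GroundTruth(
        true_effect_sets={c: [] for c in CONTRASTS},
        true_partition={},
        true_trajectory={},
    )

    blocks: Dict[str, AnalyteMatrix] = {}
    for block in ("protein", "eicosanoid", "metabolite"):
        if block not in config.block_sizes:
            continue
        p = config.block_sizes[block]
        ids = pd.Index([f"{block[:4]}_{j:04d}" for j in range(p)], name="analyte_id")

        # residual structure: latent factor cliques, otherwise independent
        x = rng.standard_normal((n, p))
        planted_here = [pb for pb in config.planted_blocks if pb[0] == block]
        partition: List[List[str]] = []
        for _, idx, loading in planted_here:
            f = rng.standard_normal(n)
            for j in idx:
                x[:, j] = loading * f + np.sqrt(1.0 - loading**2) * x[:, j]
            partition.append([ids[j] for j in sorted(idx)])
        truth.true_partition[block] = partition
        x *= config.noise_sd

        # per-analyte log2 baselines keep the raw scale positive
        x += rng.uniform(*BASELINE_RANGE, size=p)

        # planted contrast effects (additive on log2)
        group_shift = np.zeros((3, p))
        g_index = {g: k for k, g in enumerate(GROUPS)}
        for eff_block, idx, contrast, shift in config.effects:
            if eff_block != block or shift == 0:
                continue
            _, target = _contrast_groups(contrast)
            for j in idx:
                group_shift[g_index[target], j] += shift
                pair = (block, ids[j])
                if pair not in truth.true_effect_sets[contrast]:
                    truth.true_effect_sets[contrast].append(pair)

        span = config.trajectory_magnitude * config.noise_sd
        for (tb, j), cls in config.trajectory_profiles.items():
            if tb != block:
                continue
            means = _trajectory_group_means(cls, span)
            for g, m in means.items():
                group_shift[g_index[g], j] += m
            truth.true_trajectory[(block, ids[j])] = cls

        x += group_shift[[g_index[g] for g in groups], :]

        # confounders on centred age / 0-1 sex
        for (cb, j), slope in config.age_effect.items():
            if cb == block:
                x[:, j] += slope * age_centred
        for (cb, j), slope in config.sex_effect.items():
            if cb == block:
                x[:, j] += slope * sex

        values = pd.DataFrame(x, index=sample_ids, columns=ids)
        matrix = AnalyteMatrix(values=values, block_label=block)

        if block == "eicosanoid" and config.lod_quantile > 0:
            raw = AnalyteMatrix(
                values=np.exp2(values), block_label=block, scale=SCALE_RAW
            )
            matrix = censor_below_lod(raw, config.lod_quantile)
        elif block == "protein" and config.missing_rate > 0:
            seed = int(rng.integers(0, 2**31 - 1))
            matrix = apply_missingness(
                matrix, config.missing_rate, seed, mnar=config.mnar_missingness
            )

        blocks[block] = matrix

    return SyntheticStudy(blocks=blocks, meta=meta, truth=truth)


def censor_below_lod(matrix: AnalyteMatrix, lod_quantile: float) -> AnalyteMatrix:
    """Flag values below each analyte's empirical ``lod_quantile`` as censored.

    Values strictly below the per-analyte quantile are removed and flagged in
    the below-LOD mask; ties with the quantile itself are never censored, so
    an all-equal analyte is left untouched.
    """
    if not (0.0 <= lod_quantile < 1.0):
        raise TriomicsError("lod_quantile must lie in [0, 1)")
    if matrix.scale != SCALE_RAW:
        raise TriomicsError("censoring operates on the raw (pre-log) scale")
    out = matrix.copy()
    vals = out.values.to_numpy(dtype=float)
    lod = np.nanquantile(vals, lod_quantile, axis=0)
    below = vals < lod[None, :]
    vals[below] = np.nan
    out.values = pd.DataFrame(vals, index=out.sample_ids, columns=out.analyte_ids)
    out.below_lod_mask = out.below_lod_mask | pd.DataFrame(
        below, index=out.sample_ids, columns=out.analyte_ids
    )
    return out


def apply_missingness(
    matrix: AnalyteMatrix, rate: float, seed: int, mnar: bool = False
) -> AnalyteMatrix:
    """Mask cells at random; ``mnar=True`` biases masking toward low values.

    In the MNAR mode the per-cell masking probability is scaled by the
    within-analyte rank (low intensities more likely missing) while keeping
    the expected overall rate at ``rate``.
    """
    if not (0.0 <= rate < 1.0):
        raise TriomicsError("rate must lie in [0, 1)")
    out = matrix.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    vals = out.values.to_numpy(dtype=float)
    if mnar:
        order = np.argsort(np.argsort(vals, axis=0), axis=0)  # ranks 0..n-1
        weight = 2.0 * (1.0 - (order + 0.5) / vals.shape[0])
        prob = np.clip(rate * weight, 0.0, 1.0)
    else:
        prob = np.full(vals.shape, rate)
    mask = rng.random(vals.shape) < prob
    mask &= out.observed_mask.to_numpy()
    vals[mask] = np.nan
    out.values = pd.DataFrame(vals, index=out.sample_ids, columns=out.analyte_ids)
    out.missing_mask = out.missing_mask | pd.DataFrame(
        mask, index=out.sample_ids, columns=out.analyte_ids
    )
    return out
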
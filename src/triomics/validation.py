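"""Self-validation experiments exercising the pipeline on planted studies.

These routines generate synthetic studies under the package's reference
conditions, run the relevant stage(s), and return scalar quality metrics:
oracle-agreement errors, empirical FDR under the null, planted-structure
recovery rates. They are shared between the test suite and the
reproduction script so both measure exactly the same quantities.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .ggm import DEFAULT_K_GRID, sweep_K
from .linear_models import adjust_bh, fit_moderated_contrasts
from .integration import VariableSet, partial_correlations
from .set_analysis import associate_subnetworks, choose_K
from .synthetic import SimulationConfig, generate_study
from .trajectory import classify_block

CONTRASTS = ("healthy_vs_active", "healthy_vs_remission", "remission_vs_active")


def reference_simulation_config(seed: int) -> SimulationConfig:
    """The package's reference demo study at the cohort's scale.

    12 samples per group; one protein module and one metabolite module with
    graded healthy-vs-active shifts of 1.2-2.4 log2 units (acute-phase
    plasma markers and platelet-released eicosanoids shift 2- to 5-fold in
    flares), two strongly remission-shifted metabolites, three upregulated
    eicosanoids, three planted trajectory profiles, 10% missing protein
    values and 10% eicosanoid censoring.
    """
    return SimulationConfig(
        n_per_group=12,
        planted_blocks=[
            ("protein", tuple(range(5)), 0.9),
            ("metabolite", tuple(range(6)), 0.85),
        ],
        effects=[
            ("protein", (j,), "healthy_vs_active", s)
            for j, s in zip(range(5), (2.4, 1.8, 1.8, 1.2, 1.2))
        ]
        + [
            ("metabolite", (j,), "healthy_vs_active", s)
            for j, s in zip(range(6), (2.0, 1.5, 1.5, 1.0, 1.0, 1.0))
        ]
        + [
            ("eicosanoid", (0, 1, 2), "healthy_vs_active", 1.5),
            ("metabolite", (10, 11), "healthy_vs_remission", 1.5),
        ],
        trajectory_profiles={
            ("metabolite", 20): "normalising",
            ("metabolite", 21): "non_normalising",
            ("metabolite", 22): "exceptional",
        },
        lod_quantile=0.1,
        missing_rate=0.1,
        seed=seed,
    )


def _varset(data: pd.DataFrame) -> VariableSet:
    prov = pd.DataFrame(
        {"column": data.columns, "kind": "analyte", "block": "metabolite"}
    ).set_index("column")
    return VariableSet(data=data, contrast="healthy_vs_active", provenance=prov)


def partial_correlation_oracle_error(
    seed: int, n_instances: int = 50, n: int = 40, k: int = 8
) -> float:
    """Max |inverse-correlation partial R - residual-regression oracle|.

    The oracle regresses each pair's two variables on all remaining columns
    and correlates the residuals — an independent route to the same
    quantity.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        raw = rng.standard_normal((n, k))
        raw[:, 0] += 0.4 * raw[:, 1]
        data = pd.DataFrame(raw, columns=[f"x{i}" for i in range(k)])
        fast = partial_correlations(_varset(data), ridge=0).matrix.to_numpy()
        oracle = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                others = [c for c in range(k) if c not in (i, j)]
                Z = np.column_stack([np.ones(n), raw[:, others]])
                ri = raw[:, i] - Z @ np.linalg.lstsq(Z, raw[:, i], rcond=None)[0]
                rj = raw[:, j] - Z @ np.linalg.lstsq(Z, raw[:, j], rcond=None)[0]
                oracle[i, j] = oracle[j, i] = np.corrcoef(ri, rj)[0, 1]
        worst = max(worst, float(np.abs(fast - oracle).max()))
    return worst


def bh_oracle_error(seed: int, n_vectors: int = 1000) -> float:
    """Max |adjust_bh - by-definition step-up| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(rng.integers(1, 60))
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        worst = max(worst, float(np.abs(adjust_bh(p) - adj).max()))
    return worst


def fold_change_recovery(
    seed: int, shift: float = 2.0, n_planted: int = 50, n_analytes: int = 300
) -> float:
    """Mean estimated log2 fold-change over independently planted analytes.

    n = 12 per group, unit residual SD; the planted shift is applied to the
    active group for the healthy-vs-active contrast.
    """
    cfg = SimulationConfig(
        n_per_group=12,
        block_sizes={"metabolite": n_analytes},
        effects=[
            ("metabolite", tuple(range(n_planted)), "healthy_vs_active", shift)
        ],
        seed=seed,
    )
    study = generate_study(cfg)
    res = fit_moderated_contrasts(study.blocks["metabolite"], study.meta)
    sub = res.for_contrast("healthy_vs_active")
    planted = [a for _, a in study.truth.true_effect_sets["healthy_vs_active"]]
    return float(sub.loc[planted, "estimate"].mean())


def null_fdr(
    seed: int,
    n_sims: int = 50,
    n_per_group: int = 12,
    n_analytes: int = 500,
    q: float = 0.05,
) -> float:
    """Mean fraction of analytes flagged at FDR q on age/sex-only studies."""
    rng = np.random.default_rng(seed)
    fractions = []
    for _ in range(n_sims):
        s = int(rng.integers(0, 2**31 - 1))
        cfg = SimulationConfig(
            n_per_group=n_per_group,
            block_sizes={"metabolite": n_analytes},
            age_effect={("metabolite", j): 0.02 for j in range(0, n_analytes, 5)},
            sex_effect={("metabolite", j): 0.5 for j in range(0, n_analytes, 7)},
            seed=s,
        )
        study = generate_study(cfg)
        res = fit_moderated_contrasts(study.blocks["metabolite"], study.meta, q=q)
        flagged = res.table["significant"].to_numpy()
        fractions.append(flagged.reshape(3, -1).mean(axis=1).mean())
    return float(np.mean(fractions))


# graded within-module contrast shifts (log2 units at n=100/group): the
# realistic heterogeneous-regulation condition under which set-level power
# is high for whole modules and low for module fragments
MODULE_SHIFT_GRADE = (0.45, 0.226, 0.226, 0.113, 0.113)


def _recovery_config(seed: int) -> Tuple[SimulationConfig, List[Tuple[int, ...]]]:
    sets = [tuple(range(0, 5)), tuple(range(5, 10)), tuple(range(10, 15))]
    effects = []
    for members, contrast in zip(sets, CONTRASTS):
        for j, shift in zip(members, MODULE_SHIFT_GRADE):
            effects.append(("protein", (j,), contrast, shift))
    cfg = SimulationConfig(
        n_per_group=100,
        block_sizes={"protein": 60},
        planted_blocks=[("protein", s, 0.9) for s in sets],
        effects=effects,
        seed=seed,
    )
    return cfg, sets


def graph_recovery_ari(seed: int, n_perm: int = 1000) -> float:
    """Planted-partition ARI of the chosen-K components for one study.

    Three 5-analyte modules (loading 0.9) among 60 analytes, n = 300; the
    full K sweep (1 to 6, step 0.5) plus set-analysis K selection is run,
    and the chosen graph's components are compared with the planted sets
    over the planted analytes (unassigned analytes count as singletons).
    """
    cfg, _sets = _recovery_config(seed)
    study = generate_study(cfg)
    matrix = study.blocks["protein"]
    stats = {"protein": fit_moderated_contrasts(matrix, study.meta)}
    sweep = sweep_K({"protein": matrix}, grid=DEFAULT_K_GRID)
    assoc = associate_subnetworks(
        sweep, stats, CONTRASTS, n_perm=n_perm, seed=seed + 1
    )
    chosen = choose_K(sweep, assoc)
    subs = sweep.subnetworks[chosen.K] if chosen.K is not None else []
    membership = {a: i for i, sn in enumerate(subs) for a in sn.members}
    truth_sets = study.truth.true_partition["protein"]
    truth_map = {a: i for i, s in enumerate(truth_sets) for a in s}
    planted = [a for s in truth_sets for a in s]
    labels_true = [truth_map[a] for a in planted]
    labels_pred = [membership.get(a, 1000 + i) for i, a in enumerate(planted)]
    return float(adjusted_rand_score(labels_true, labels_pred))


def graph_recovery_rate(
    seed: int, n_seeds: int = 20, ari_threshold: float = 0.9
) -> Tuple[int, List[float]]:
    """How many of ``n_seeds`` studies reach the ARI threshold."""
    rng = np.random.default_rng(seed)
    aris = [graph_recovery_ari(int(rng.integers(0, 2**31 - 1))) for _ in range(n_seeds)]
    return sum(a >= ari_threshold for a in aris), aris


def trajectory_recovery_rate(
    seed: int, n_seeds: int = 20, n_per_class: int = 10
) -> float:
    """Fraction of planted trajectory profiles assigned their intended class."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_seeds):
        profiles = {}
        for j in range(n_per_class):
            profiles[("metabolite", j)] = "normalising"
            profiles[("metabolite", n_per_class + j)] = "non_normalising"
            profiles[("metabolite", 2 * n_per_class + j)] = "exceptional"
        cfg = SimulationConfig(
            n_per_group=12,
            block_sizes={"metabolite": 60},
            trajectory_profiles=profiles,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        study = generate_study(cfg)
        table = classify_block(study.blocks["metabolite"], study.meta)
        table = table.set_index("analyte")
        for (_block, analyte), intended in study.truth.true_trajectory.items():
            total += 1
            hits += table.loc[analyte, "trajectory_class"] == intended
    return hits / total
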
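"""End-to-end orchestration of the multiomics integration analysis.

Stages, in order, all driven by one :class:`PipelineConfig`:

1. preprocess — valid-value filtering plus Gaussian down-shift imputation
   for proteins; min/sqrt(2) below-LOD imputation and log2 transform for
   eicosanoids (and metabolites when censored);
2. stage 1 — moderated contrasts with age/sex adjustment, BH at q;
3. stage 2 — GGM neighborhood selection over the K grid, sub-network set
   analysis, K selection, PC summarization (75% rule);
4. stages 3–4 — variable pooling, full-order partial correlations, and the
   |R| > threshold integration network per contrast;
5. trajectory — confounder-corrected group z-scores and the
   normalising / non-normalising / exceptional taxonomy.

Every stage is a pure function of (inputs, config, seed): one global seed
fans out into per-stage child seeds through ``numpy.random.SeedSequence``,
so identical config + seed reproduces bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    SCALE_LOG2,
    SCALE_RAW,
    AnalyteMatrix,
    SampleMeta,
    TriomicsError,
)
from .ggm import DEFAULT_K_GRID, FAMILY_AND, KSweepResult, sweep_K
from .integration import (
    EDGE_THRESHOLD,
    IntegrationNetwork,
    build_network,
    build_variable_set,
    partial_correlations,
)
from .io import read_matrix, read_meta, write_json, write_table
from .linear_models import ContrastResult, default_contrasts, fit_moderated_contrasts
from .preprocess import (
    filter_by_valid_values,
    impute_gaussian_downshift,
    impute_lod_min_over_sqrt2,
)
from .set_analysis import (
    PC1_THRESHOLD,
    ChosenK,
    SubNetworkSummary,
    associate_subnetworks,
    association_table,
    choose_K,
    summarize_pcs,
)
from .trajectory import DEFAULT_DELTA, classify_block


@dataclass
class PipelineConfig:
    """Every tunable constant of the analysis, with the study defaults."""

    block_paths: Dict[str, str] = field(default_factory=dict)
    meta_path: str = ""
    min_valid: Dict[str, int] = field(
        default_factory=lambda: {"protein": 3, "eicosanoid": 3, "metabolite": 3}
    )
    downshift_shift: float = 1.8
    downshift_width: float = 0.3
    k_grid: Tuple[float, ...] = DEFAULT_K_GRID
    ggm_family: str = FAMILY_AND
    q: float = 0.05
    pc1_threshold: float = PC1_THRESHOLD
    edge_threshold: float = EDGE_THRESHOLD
    delta: float = DEFAULT_DELTA
    n_perm: int = 10_000
    seed: int = 0
    outdir: str = "results/pipeline"

    def validate(self) -> None:
        for name, value in (
            ("q", self.q),
            ("pc1_threshold", self.pc1_threshold),
            ("delta", self.delta),
        ):
            if not (0 < value < 1):
                raise TriomicsError(f"{name} must lie in (0, 1), got {value}")
        if self.edge_threshold < 0:
            raise TriomicsError("edge_threshold must be >= 0")
        if self.n_perm < 100:
            raise TriomicsError("n_perm must be >= 100")
        if not self.k_grid:
            raise TriomicsError("k_grid must be non-empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_grid"] = [float(k) for k in self.k_grid]
        return d

    @staticmethod
    def from_yaml(path: Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(payload) - known
        if unknown:
            raise TriomicsError(f"unknown config keys: {sorted(unknown)}")
        if "k_grid" in payload:
            payload["k_grid"] = tuple(float(k) for k in payload["k_grid"])
        cfg = PipelineConfig(**payload)
        cfg.validate()
        return cfg

    def to_yaml(self, path: Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class RunReport:
    config: dict
    version: str
    seed: int
    n_samples: int
    n_analytes_raw: Dict[str, int]
    n_analytes_filtered: Dict[str, int]
    n_significant: Dict[str, Dict[str, int]]  # contrast -> block -> count
    chosen_k: Optional[float]
    n_subnetworks: int
    n_significant_subnetworks: int
    network_nodes: Dict[str, int]
    network_edges: Dict[str, int]
    trajectory_counts: Dict[str, int]

    def to_jsonable(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    report: RunReport
    preprocessed: Dict[str, AnalyteMatrix]
    contrast_results: Dict[str, ContrastResult]
    sweep: KSweepResult
    chosen: ChosenK
    summaries: List[SubNetworkSummary]
    networks: Dict[str, IntegrationNetwork]
    trajectories: pd.DataFrame
    associations: pd.DataFrame


def _child_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def load_inputs(
    config: PipelineConfig,
) -> Tuple[Dict[str, AnalyteMatrix], SampleMeta]:
    blocks: Dict[str, AnalyteMatrix] = {}
    for block, path in config.block_paths.items():
        scale = SCALE_RAW if block == "eicosanoid" else SCALE_LOG2
        blocks[block] = read_matrix(path, block_label=block, scale=scale)
    meta = read_meta(config.meta_path)
    return blocks, meta


def preprocess_blocks(
    blocks: Dict[str, AnalyteMatrix],
    meta: SampleMeta,
    config: PipelineConfig,
    seed: int,
) -> Dict[str, AnalyteMatrix]:
    """Apply the block-specific imputation policy; outputs are complete log2."""
    out: Dict[str, AnalyteMatrix] = {}
    for block, matrix in blocks.items():
        if matrix.scale == SCALE_RAW or matrix.below_lod_mask.to_numpy().any():
            matrix = impute_lod_min_over_sqrt2(matrix)
        matrix = filter_by_valid_values(
            matrix, meta, config.min_valid.get(block, 3)
        )
        if not matrix.observed_mask.to_numpy().all():
            matrix = impute_gaussian_downshift(
                matrix,
                shift=config.downshift_shift,
                width=config.downshift_width,
                seed=seed,
            )
        matrix.require_complete(f"preprocessing left holes in block {block!r}")
        out[block] = matrix
    return out


def run_study(
    blocks: Dict[str, AnalyteMatrix],
    meta: SampleMeta,
    config: PipelineConfig,
    outdir: Optional[Path] = None,
) -> PipelineResult:
    """Run the full analysis in memory; optionally write all tables."""
    config.validate()
    seeds = _child_seeds(config.seed, 4)
    contrasts = default_contrasts()
    contrast_names = [c.name for c in contrasts]

    n_raw = {b: m.n_analytes for b, m in blocks.items()}
    pre = preprocess_blocks(blocks, meta, config, seeds[0])

    results: Dict[str, ContrastResult] = {
        block: fit_moderated_contrasts(m, meta, contrasts, q=config.q)
        for block, m in pre.items()
    }

    sweep = sweep_K(pre, grid=config.k_grid, family=config.ggm_family)
    associations = associate_subnetworks(
        sweep,
        results,
        contrast_names,
        n_perm=config.n_perm,
        seed=seeds[1],
        q=config.q,
    )
    chosen = choose_K(sweep, associations)
    summaries = [
        summarize_pcs(pre[s.block_label], s, threshold=config.pc1_threshold)
        for s in chosen.chosen_subnetworks()
    ]

    networks: Dict[str, IntegrationNetwork] = {}
    for contrast in contrast_names:
        varset = build_variable_set(
            _pooled_results(results), summaries, pre, meta, contrast
        )
        if varset.n_variables >= 3:
            pcm = partial_correlations(varset)
        else:
            # nothing significant: a node-only network over the covariates
            from .integration import PartialCorrelationMatrix

            pcm = PartialCorrelationMatrix(
                matrix=pd.DataFrame(
                    np.eye(varset.n_variables),
                    index=varset.data.columns,
                    columns=varset.data.columns,
                )
            )
        attrs = _node_attributes(varset, results, summaries, contrast)
        networks[contrast] = build_network(
            pcm, attrs, contrast, threshold=config.edge_threshold
        )

    trajectories = pd.concat(
        [classify_block(m, meta, delta=config.delta) for m in pre.values()],
        ignore_index=True,
    )

    n_significant = {
        contrast: {
            block: int(len(res.significant_analytes(contrast)))
            for block, res in results.items()
        }
        for contrast in contrast_names
    }
    report = RunReport(
        config=config.to_dict(),
        version=__version__,
        seed=config.seed,
        n_samples=meta.table.shape[0],
        n_analytes_raw=n_raw,
        n_analytes_filtered={b: m.n_analytes for b, m in pre.items()},
        n_significant=n_significant,
        chosen_k=chosen.K,
        n_subnetworks=len(chosen.chosen_subnetworks()),
        n_significant_subnetworks=len(chosen.significant),
        network_nodes={c: n.graph.number_of_nodes() for c, n in networks.items()},
        network_edges={c: n.n_edges for c, n in networks.items()},
        trajectory_counts=trajectories["trajectory_class"]
        .value_counts()
        .to_dict(),
    )

    result = PipelineResult(
        report=report,
        preprocessed=pre,
        contrast_results=results,
        sweep=sweep,
        chosen=chosen,
        summaries=summaries,
        networks=networks,
        trajectories=trajectories,
        associations=association_table(associations),
    )
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def _pooled_results(results: Dict[str, ContrastResult]) -> ContrastResult:
    table = pd.concat([r.table for r in results.values()], ignore_index=True)
    any_result = next(iter(results.values()))
    return ContrastResult(table, q=any_result.q)


def _node_attributes(
    varset, results: Dict[str, ContrastResult], summaries, contrast: str
) -> pd.DataFrame:
    pooled = _pooled_results(results).for_contrast(contrast)
    rows = []
    for column in varset.data.columns:
        prov = varset.provenance.loc[column]
        row = {"node": column, "kind": prov["kind"], "block": prov["block"]}
        if prov["kind"] == "analyte":
            row["log2fc"] = float(pooled.loc[column, "estimate"])
            row["members"] = column
        elif prov["kind"] == "subnetwork_pc":
            sn_id = column.rsplit("|", 1)[0]
            summary = next(s for s in summaries if s.subnetwork.id == sn_id)
            members = summary.subnetwork.members
            row["members"] = "+".join(members)
            fc = [
                float(pooled.loc[m, "estimate"])
                for m in members
                if m in pooled.index
            ]
            row["log2fc"] = float(np.mean(fc)) if fc else np.nan
            row["member_log2fc"] = ";".join(f"{v:.4f}" for v in fc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("node")


def run(config: PipelineConfig) -> RunReport:
    """File-based entry point: read inputs, run all stages, write outputs."""
    config.validate()
    if not config.block_paths:
        raise TriomicsError("config.block_paths is empty")
    blocks, meta = load_inputs(config)
    result = run_study(blocks, meta, config, outdir=Path(config.outdir))
    return result.report


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for block, res in result.contrast_results.items():
        for contrast in res.contrasts:
            write_table(
                res.for_contrast(contrast).reset_index(),
                outdir / f"contrasts_{block}_{contrast}.tsv",
            )
    write_table(result.associations, outdir / "subnetwork_associations.tsv")
    write_table(result.chosen.counts, outdir / "k_selection.tsv")
    write_table(result.trajectories, outdir / "trajectories.tsv")
    for summary in result.summaries:
        scores = summary.scores.copy()
        scores.insert(0, "sample_id", scores.index)
        write_table(
            scores,
            outdir / f"subnetwork_scores_{summary.subnetwork.id.replace(':', '_')}.tsv",
        )
    for contrast, network in result.networks.items():
        write_table(network.node_table(), outdir / f"network_nodes_{contrast}.tsv")
        write_table(network.edge_table(), outdir / f"network_edges_{contrast}.tsv")
        network.write_graphml(outdir / f"network_{contrast}.graphml")
    write_json(result.report.to_jsonable(), outdir / "report.json")
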
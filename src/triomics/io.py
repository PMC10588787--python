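"""Delimited-text persistence for matrices, metadata and ground truth.

Analyte matrices are written with analytes in rows and samples in columns
(first column = analyte id), tab-separated UTF-8 with a header row; missing
values are empty fields. Masks travel as parallel 0/1 tables next to the
value table (``<stem>.missing.tsv`` / ``<stem>.lod.tsv``) and are only
written when non-empty.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import pandas as pd

from .containers import SCALE_LOG2, AnalyteMatrix, SampleMeta, TriomicsError
from .synthetic import GroundTruth, SyntheticStudy

SEP = "\t"


def write_matrix(matrix: AnalyteMatrix, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = matrix.values.T
    table.index.name = "analyte_id"
    table.to_csv(path, sep=SEP, na_rep="")
    for mask, suffix in (
        (matrix.missing_mask, ".missing.tsv"),
        (matrix.below_lod_mask, ".lod.tsv"),
    ):
        side = path.with_suffix(suffix)
        if mask.to_numpy().any():
            out = mask.T.astype(int)
            out.index.name = "analyte_id"
            out.to_csv(side, sep=SEP)
        elif side.exists():
            side.unlink()


def read_matrix(
    path: Path, block_label: str, scale: str = SCALE_LOG2
) -> AnalyteMatrix:
    path = Path(path)
    if not path.exists():
        raise TriomicsError(f"matrix file not found: {path}")
    values = pd.read_csv(path, sep=SEP, index_col=0).T
    values.index.name = "sample_id"
    values.columns.name = "analyte_id"
    masks = {}
    for key, suffix in (("missing", ".missing.tsv"), ("lod", ".lod.tsv")):
        side = path.with_suffix(suffix)
        if side.exists():
            mask = pd.read_csv(side, sep=SEP, index_col=0).T.astype(bool)
            mask.index.name = "sample_id"
            mask.columns.name = "analyte_id"
            masks[key] = mask
    return AnalyteMatrix(
        values=values,
        block_label=block_label,
        scale=scale,
        missing_mask=masks.get("missing"),
        below_lod_mask=masks.get("lod"),
    )


def write_meta(meta: SampleMeta, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=SEP)


def read_meta(path: Path) -> SampleMeta:
    path = Path(path)
    if not path.exists():
        raise TriomicsError(f"metadata file not found: {path}")
    return SampleMeta(pd.read_csv(path, sep=SEP, index_col=0))


def write_truth(truth: GroundTruth, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth.to_jsonable(), indent=2))


def write_study(study: SyntheticStudy, outdir: Path) -> Dict[str, Path]:
    """Write a synthetic study the way the pipeline expects to read it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for block, matrix in study.blocks.items():
        p = outdir / f"{block}.tsv"
        write_matrix(matrix, p)
        paths[block] = p
    meta_path = outdir / "samples.tsv"
    write_meta(study.meta, meta_path)
    paths["meta"] = meta_path
    truth_path = outdir / "truth.json"
    write_truth(study.truth, truth_path)
    paths["truth"] = truth_path
    return paths


def write_table(table: pd.DataFrame, path: Path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=SEP, index=index, na_rep="")


def write_json(payload: dict, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
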
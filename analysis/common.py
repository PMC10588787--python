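"""Shared study definition for the numbered analysis drivers.

All drivers operate on the same synthetic reference study: three omics
blocks (60 proteins with 10% missing values, 24 eicosanoids censored at
the 10% detection-limit quantile, 90 metabolites), 12 samples per group,
one planted protein module and one metabolite module with graded
healthy-vs-active shifts, two remission-specific metabolites, and three
planted trajectory profiles.
"""

from pathlib import Path

from triomics import PipelineConfig, generate_study
from triomics.io import read_matrix, read_meta, write_study
from triomics.validation import reference_simulation_config

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
OUT_DIR = ROOT / "results"

SEED = 2024


def simulation_config():
    return reference_simulation_config(SEED)


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(seed=SEED, n_perm=2000, outdir=str(OUT_DIR / "pipeline"))


def load_or_simulate():
    """Read the reference study from results/data, simulating it if absent."""
    meta_path = DATA_DIR / "samples.tsv"
    if not meta_path.exists():
        write_study(generate_study(simulation_config()), DATA_DIR)
    blocks = {
        "protein": read_matrix(DATA_DIR / "protein.tsv", "protein"),
        "eicosanoid": read_matrix(
            DATA_DIR / "eicosanoid.tsv", "eicosanoid", scale="raw"
        ),
        "metabolite": read_matrix(DATA_DIR / "metabolite.tsv", "metabolite"),
    }
    return blocks, read_meta(meta_path)
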
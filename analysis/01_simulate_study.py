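"""Generate the synthetic reference study and write it to results/data.

Produces the three block tables (analytes x samples), the sample metadata,
and the ground-truth JSON recording every planted module, effect and
trajectory profile.
"""

from common import DATA_DIR, simulation_config

from triomics import generate_study
from triomics.io import write_study


def main() -> None:
    study = generate_study(simulation_config())
    paths = write_study(study, DATA_DIR)
    print(f"wrote {len(paths)} files to {DATA_DIR}")
    for block, matrix in study.blocks.items():
        n_missing = int(matrix.missing_mask.sum().sum())
        n_lod = int(matrix.below_lod_mask.sum().sum())
        print(
            f"  {block}: {matrix.n_samples} samples x {matrix.n_analytes} "
            f"analytes ({matrix.scale} scale, {n_missing} missing, "
            f"{n_lod} below LOD)"
        )
    truth = study.truth
    print(
        f"planted: {sum(len(v) for v in truth.true_partition.values())} "
        f"modules, {len(truth.true_trajectory)} trajectory profiles"
    )


if __name__ == "__main__":
    main()
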
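"""Trajectory taxonomy: which analytes normalise during remission?

Computes age/sex-corrected group-mean z-scores per analyte and classifies
the healthy -> remission -> active profile as normalising (back to healthy
levels), non-normalising (stuck at active levels), exceptional (healthy or
active strictly in between), or intermediate.
"""

from common import OUT_DIR, load_or_simulate, pipeline_config

from triomics import classify_block
from triomics.io import write_table
from triomics.pipeline import _child_seeds, preprocess_blocks

import pandas as pd


def main() -> None:
    blocks, meta = load_or_simulate()
    cfg = pipeline_config()
    pre = preprocess_blocks(blocks, meta, cfg, _child_seeds(cfg.seed, 4)[0])
    tables = [classify_block(m, meta, delta=cfg.delta) for m in pre.values()]
    table = pd.concat(tables, ignore_index=True)
    write_table(table, OUT_DIR / "trajectories.tsv")
    counts = table["trajectory_class"].value_counts()
    print(f"classified {len(table)} analytes (delta = {cfg.delta:.3f}):")
    for cls, n in counts.items():
        print(f"  {cls}: {n}")
    strongest = table.assign(span=(table.z_active - table.z_healthy).abs())
    top = strongest.nlargest(5, "span")
    print("largest healthy<->active spans:")
    for _, row in top.iterrows():
        print(
            f"  {row['analyte']} ({row['block']}): "
            f"z_h={row['z_healthy']:+.2f} z_r={row['z_remission']:+.2f} "
            f"z_a={row['z_active']:+.2f} -> {row['trajectory_class']}"
        )


if __name__ == "__main__":
    main()
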
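"""Stage 1: moderated contrasts with age/sex adjustment, BH at 5% FDR.

Fits one linear model per analyte (group indicators + centred age + sex),
shrinks residual variances with the empirical-Bayes prior, and tests the
three pairwise contrasts. Writes one tidy table per block and contrast.
"""

from common import OUT_DIR, load_or_simulate, pipeline_config

from triomics import fit_moderated_contrasts
from triomics.io import write_table
from triomics.pipeline import _child_seeds, preprocess_blocks


def main() -> None:
    blocks, meta = load_or_simulate()
    cfg = pipeline_config()
    pre = preprocess_blocks(blocks, meta, cfg, _child_seeds(cfg.seed, 4)[0])
    outdir = OUT_DIR / "contrasts"
    for block, matrix in pre.items():
        res = fit_moderated_contrasts(matrix, meta, q=cfg.q)
        prior = res.prior
        print(
            f"{block}: prior df d0 = {prior.d0:.2f}, prior variance "
            f"s0^2 = {prior.s0_sq:.3f}"
        )
        for contrast in res.contrasts:
            table = res.for_contrast(contrast).reset_index()
            write_table(table, outdir / f"{block}_{contrast}.tsv")
            sig = table[table["significant"]]
            print(
                f"  {contrast}: {len(sig)} significant analytes"
                + (
                    f" (top: {sig.nsmallest(3, 'p_adj')['analyte'].tolist()})"
                    if len(sig)
                    else ""
                )
            )
    print(f"contrast tables in {outdir}")


if __name__ == "__main__":
    main()
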
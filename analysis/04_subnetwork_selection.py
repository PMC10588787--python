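"""Stage 2: GGM sub-network discovery, K selection and PC summarization.

Sweeps the neighborhood-selection penalty multiplier K from 1 to 6 in
half steps per block, tests every connected component against every
contrast with the signed-Stouffer permutation test, picks the K with the
most significant (sub-network, contrast) pairs, and summarizes each chosen
sub-network by PC1 (or PC1+PC2 when PC1 explains < 75% of the variance).
"""

from common import OUT_DIR, load_or_simulate, pipeline_config

from triomics import choose_K, fit_moderated_contrasts, summarize_pcs, sweep_K
from triomics.io import write_table
from triomics.pipeline import _child_seeds, preprocess_blocks
from triomics.set_analysis import associate_subnetworks, association_table


def main() -> None:
    blocks, meta = load_or_simulate()
    cfg = pipeline_config()
    seeds = _child_seeds(cfg.seed, 4)
    pre = preprocess_blocks(blocks, meta, cfg, seeds[0])
    stats = {b: fit_moderated_contrasts(m, meta, q=cfg.q) for b, m in pre.items()}

    sweep = sweep_K(pre, grid=cfg.k_grid, family=cfg.ggm_family)
    contrasts = next(iter(stats.values())).contrasts
    assoc = associate_subnetworks(
        sweep, stats, contrasts, n_perm=cfg.n_perm, seed=seeds[1], q=cfg.q
    )
    chosen = choose_K(sweep, assoc)

    outdir = OUT_DIR / "subnetworks"
    write_table(association_table(assoc), outdir / "associations.tsv")
    write_table(chosen.counts, outdir / "k_selection.tsv")
    print(chosen.counts.to_string(index=False))
    if chosen.is_sentinel:
        print("no significant sub-network at any K; single analytes only")
        return
    print(f"chosen K = {chosen.K} with {len(chosen.significant)} significant pairs")
    for subnet in chosen.chosen_subnetworks():
        summary = summarize_pcs(pre[subnet.block_label], subnet, cfg.pc1_threshold)
        print(
            f"  {subnet.id}: {subnet.size} members, PC1 explains "
            f"{summary.pc1_variance_fraction:.0%} -> "
            f"{summary.n_components} component(s)"
        )
        scores = summary.scores.copy()
        scores.insert(0, "sample_id", scores.index)
        write_table(scores, outdir / f"scores_{subnet.id.replace(':', '_')}.tsv")


if __name__ == "__main__":
    main()
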
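"""Stages 3-4: cross-omics partial-correlation networks per contrast.

Pools significant single analytes, chosen sub-network PC scores, age and
sex; computes full-order partial correlations; writes the |R| > 0.6
network (nodes, edges, GraphML) for each contrast. This driver simply
runs the orchestrated pipeline, which executes stages 1-2 on the way.
"""

from common import load_or_simulate, pipeline_config

from triomics import run_study


def main() -> None:
    blocks, meta = load_or_simulate()
    cfg = pipeline_config()
    result = run_study(blocks, meta, cfg, outdir=cfg.outdir)
    for contrast, network in result.networks.items():
        nodes = network.graph.number_of_nodes()
        kinds = [d["kind"] for _, d in network.graph.nodes(data=True)]
        print(
            f"{contrast}: {nodes} nodes "
            f"({kinds.count('analyte')} analytes, "
            f"{kinds.count('subnetwork_pc')} sub-network PCs, "
            f"{kinds.count('covariate')} covariates), "
            f"{network.n_edges} edges with |R| > {network.threshold}"
        )
    print(f"networks and report written to {cfg.outdir}")


if __name__ == "__main__":
    main()
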
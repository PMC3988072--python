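"""Build the PPI network and prioritize hub genes.

Reads the edge list from results/inputs/, applies the 0.7 confidence
filter, computes degree and betweenness for every node, fits the
power-law degree distribution, selects hubs with the dual strict cutoff
(degree > 50 or BC > 0.05), and extracts the hub backbone network.
"""

import argparse
from pathlib import Path

from hubnet import io
from hubnet.graph import build_graph, fit_power_law
from hubnet.prioritize import (
    compute_node_stats,
    extract_backbone,
    hub_edge_fraction,
    select_hubs,
)


def main(in_dir: str = "results/inputs", out_dir: str = "results") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    g = build_graph(io.read_edge_tsv(Path(in_dir) / "edges.tsv"), 0.7)
    stats = compute_node_stats(g)
    io.write_stats_tsv(stats, out / "node_stats.tsv")
    io.write_graphml(g, out / "network.graphml")

    fit = fit_power_law({s.node: s.degree for s in stats})
    print(
        f"network: {g.number_of_nodes()} nodes / {g.number_of_edges()} edges; "
        f"degree distribution ~ {fit.coefficient_a:.1f} * d^{fit.exponent_b:.2f}, "
        f"r^2 = {fit.r_squared:.3f}"
    )

    sel = select_hubs(stats)
    print(f"hubs (degree > {sel.degree_cut} or BC > {sel.bc_cut}): "
          f"{', '.join(sel.hubs)}")

    backbone = extract_backbone(g, sel.hubs)
    io.write_sif(backbone, out / "backbone.sif")
    io.write_graphml(backbone, out / "backbone.graphml")
    frac = hub_edge_fraction(backbone, sel.hubs)
    print(
        f"backbone: {backbone.number_of_nodes()} nodes / "
        f"{backbone.number_of_edges()} edges; "
        f"{100 * frac:.0f}% of its edges touch a hub"
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="in_dir", default="results/inputs")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    main(args.in_dir, args.out)
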
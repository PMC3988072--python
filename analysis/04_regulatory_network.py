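"""Rank transcription factors in the hub-gene regulatory network.

Filters the promoter-scan evidence table to TF/target pairs with more
than one binding site, forms the bipartite TF->target network, and
ranks TFs by how many of the hub genes they regulate.
"""

import argparse
from pathlib import Path

import pandas as pd

from hubnet import io
from hubnet.regnet import (
    build_regulatory_network,
    filter_evidence,
    rank_tf_connectivity,
    unique_tf_union,
)


def main(in_dir: str = "results/inputs", out_dir: str = "results") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = io.read_tf_table_tsv(Path(in_dir) / "tf_evidence.tsv")
    tf_sets = filter_evidence(records, min_sites=2)
    for target in sorted(tf_sets):
        print(f"{target}: {len(tf_sets[target])} TFs with >1 binding site")
    union = unique_tf_union(tf_sets)
    print(f"{len(union)} unique TFs after redundancy removal")

    net = build_regulatory_network(tf_sets)
    io.write_sif(net, out / "regulatory.sif", relation="reg")
    top = rank_tf_connectivity(net, top_n=3)
    pd.DataFrame(top, columns=["tf", "connectivity"]).to_csv(
        out / "top_tfs.tsv", sep="\t", index=False
    )
    print("core regulators:",
          ", ".join(f"{tf} ({c} targets)" for tf, c in top))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="in_dir", default="results/inputs")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    main(args.in_dir, args.out)
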
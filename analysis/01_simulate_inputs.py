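"""Generate the synthetic study inputs.

Produces the four input files the downstream analyses consume — a
scale-free PPI edge list with five planted hubs, the two seed-gene
source lists, the promoter-scan TF evidence table, and the case/control
qPCR Ct table — under results/inputs/.
"""

import argparse
from pathlib import Path

from hubnet import io
from hubnet.simulate import (
    CtSimConfig,
    NetworkSimConfig,
    simulate_ct,
    simulate_gene_lists,
    simulate_ppi,
    simulate_tf_table,
)


def main(seed: int = 17, out_dir: str = "results/inputs") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    g, hubs = simulate_ppi(NetworkSimConfig(seed=seed))
    io.write_edge_tsv(g, out / "edges.tsv")
    print(
        f"network: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges; "
        f"planted hubs: {', '.join(hubs)}"
    )

    tm, curated = simulate_gene_lists(seed=seed)
    io.write_gene_list_tsv([*tm, *curated], out / "gene_lists.tsv")
    print(f"gene lists: {len(tm)} text-mining records, {len(curated)} curated")

    records = simulate_tf_table(seed=seed)
    io.write_tf_table_tsv(records, out / "tf_evidence.tsv")
    print(f"TF evidence: {len(records)} records")

    ct = simulate_ct(CtSimConfig(seed=seed))
    ct.to_csv(out / "ct.csv", index=False)
    print(f"qPCR: {ct['sample_id'].nunique()} samples, {len(ct)} wells")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", default="results/inputs")
    args = ap.parse_args()
    main(args.seed, args.out)
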
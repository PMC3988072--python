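"""Comparative-Ct expression analysis of the case/control cohort.

Reduces the qPCR Ct table to relative expression (2^-ddCt, GUSB
reference, pooled-control calibrator), compares cases vs controls per
gene (means +/- SEM on the fold-change scale, t-test on the log scale),
and computes the between-gene Pearson correlation matrix.
"""

import argparse
from pathlib import Path

from hubnet import io
from hubnet.expression import (
    correlation_matrix,
    expression_table,
    group_comparison_table,
)


def main(in_dir: str = "results/inputs", out_dir: str = "results") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ct = io.read_ct_csv(Path(in_dir) / "ct.csv")
    expr = expression_table(ct)
    expr.to_csv(out / "relative_expression.tsv", sep="\t", index=False)

    comp = group_comparison_table(expr)
    comp.to_csv(out / "group_comparison.tsv", sep="\t", index=False)
    print("case vs control relative expression (mean +/- SEM):")
    for r in comp.itertuples(index=False):
        star = "*" if r.p < 0.05 else " "
        print(
            f"  {r.gene:6s} {r.mean_case:5.2f}+/-{r.sem_case:.2f} vs "
            f"{r.mean_ctrl:5.2f}+/-{r.sem_ctrl:.2f}  p={r.p:.3g}{star}"
        )

    wide = expr.pivot_table(index="sample_id", columns="gene", values="rel_expr")
    r_mat, p_mat = correlation_matrix(wide)
    r_mat.to_csv(out / "correlation_matrix.tsv", sep="\t")
    off_diag = r_mat.where(~(r_mat == 1.0)).stack()
    print(
        f"between-gene Pearson r range: {off_diag.min():.2f} to "
        f"{off_diag.max():.2f}"
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="in_dir", default="results/inputs")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    main(args.in_dir, args.out)
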
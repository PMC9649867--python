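"""Relative expression of the operon genes under UV-B, 2^(-dCt) normalized
to the geometric mean of the PPC and RNPB reference genes.

Consumes results/inputs/ct_table.tsv (run 01 first), writes
results/qpcr/expression.tsv. Expected outcome: fold inductions of 3.5
(PHR), 2 (bifunctional PHR-like) and 3 (intergenic amplicon) at 15 min of
UV-B, returning to control level at 30 min.
"""

from pathlib import Path

from phrkit import qpcr

IN = Path("results/inputs")
OUT = Path("results/qpcr")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = qpcr.read_ct_table(IN / "ct_table.tsv")
    table = qpcr.expression_table(records, ("PPC", "RNPB"), "control")
    table.to_csv(OUT / "expression.tsv", sep="\t", index=False)
    for row in table.itertuples():
        if row.condition != "control":
            print(f"{row.gene:16s} {row.condition:10s} "
                  f"fold vs control: {row.fold_change_vs_control:.2f}")


if __name__ == "__main__":
    main()
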
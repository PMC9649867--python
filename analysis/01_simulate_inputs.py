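"""Generate every synthetic input for the downstream analyses.

Emits, under results/inputs/:
  - a 149-sequence protein family (55 planted bifunctional homologs + 94
    decoys violating at least one functional-residue rule) plus the
    synthetic PhrSph98-style reference, as FASTA and an ungapped MSA;
  - a BLAST-tabular hit file for the family (E-values/identities drawn in
    the published passing range);
  - the two-gene operon sequence with planted overlap junction, SD motif,
    promoter boxes and TF sites, plus its truth table;
  - primer pairs bracketing a 233-nt intergenic amplicon;
  - a Ct table with planted UV-B induction folds 3.5 / 2 / 3 at 15 min.

Run from the repository root: python analysis/01_simulate_inputs.py [seed]
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from phrkit import homology, synthetic
from phrkit.operon import revcomp

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    reference = synthetic.synthetic_phrsph98_reference()
    family = synthetic.FamilyDesign(reference=reference, n_true=55, n_decoy=94,
                                    substitution_rate=0.05, seed=SEED)
    records, labels = synthetic.gen_protein_family(family)
    homology.write_fasta([reference] + records, OUT / "family.fasta")
    homology.write_fasta([reference] + records, OUT / "family_msa.fasta")
    pd.DataFrame(sorted(labels.items()), columns=["sequence", "is_homolog"]).to_csv(
        OUT / "family_truth.tsv", sep="\t", index=False)

    # hit table in the published passing range: identity 31-90%, E <= 1e-63
    rows = [[reference.id, r.id, float(rng.uniform(31.0, 90.0)), len(r.sequence),
             5, 0, 1, len(r.sequence), 1, len(r.sequence),
             float(10.0 ** rng.uniform(-180.0, -63.0)), 500.0] for r in records]
    pd.DataFrame(rows).to_csv(OUT / "blast_hits.tsv", sep="\t",
                              index=False, header=False)

    operon = synthetic.OperonDesign(seed=SEED)
    seq, truth = synthetic.gen_operon_sequence(operon)
    (OUT / "operon.fasta").write_text(f">synthetic_operon\n{seq}\n")
    truth.to_frame().to_csv(OUT / "operon_truth.tsv", sep="\t", index=False)

    g1 = truth.genes[0]
    start = g1.end - 100
    pd.DataFrame([{"name": "intergenic",
                   "forward": seq[start - 1:start + 19],
                   "reverse": revcomp(seq[start + 233 - 21:start + 233 - 1])}]
                 ).to_csv(OUT / "primers.tsv", sep="\t", index=False)

    ct = synthetic.CtDesign(
        genes=("PHR", "CPD64_PHR_like", "intergenic", "PPC", "RNPB"),
        reference_genes=("PPC", "RNPB"),
        conditions=("control", "uvb_15min", "uvb_30min"),
        control_condition="control",
        true_fold_changes={("PHR", "uvb_15min"): 3.5,
                           ("CPD64_PHR_like", "uvb_15min"): 2.0,
                           ("intergenic", "uvb_15min"): 3.0},
        baseline_ct={"PHR": 24.0, "CPD64_PHR_like": 26.0, "intergenic": 27.0,
                     "PPC": 20.0, "RNPB": 21.0},
        noise_sd=0.0, replicates=3, seed=SEED)
    pd.DataFrame([r.__dict__ for r in synthetic.gen_ct_table(ct)]).to_csv(
        OUT / "ct_table.tsv", sep="\t", index=False)

    print(f"simulated {len(records)} proteins ({sum(labels.values())} planted homologs), "
          f"{len(seq)} nt operon, {3 * 5 * 3} Ct measurements -> {OUT}")


if __name__ == "__main__":
    main()
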
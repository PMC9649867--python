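"""Synthetic data with planted ground truth for every pipeline stage.

Everything here is synthetic and desk-scale: a reference protein with the
twelve functional residues planted at their PhrSph98-numbered positions, a
protein family with a controlled number of rule-conserving homologs and
rule-violating decoys, a two-gene operon sequence with planted overlap
junction / Shine-Dalgarno / promoter / TF-site features, Ct tables with
planted fold changes, and trees with planted activity-state histories.

The divergence model for protein families is deliberately minimal —
i.i.d. per-site substitution from a uniform residue pool outside the ruled
positions, no indels, no rate variation — which is sufficient to exercise a
rule screen but is not a realistic evolutionary simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import parsimony
from .conservation import AMINO_ACIDS, default_phrsph98_rules
from .operon import (START_CODONS, STOP_CODONS, OverlapRecord, SdHit, TfHit,
                     find_orfs, find_sd_motifs, revcomp)
from .records import CtRecord, GeneFeature, ProteinRecord, ResidueRule

__all__ = [
    "FamilyDesign", "OperonDesign", "CtDesign", "TreeDesign", "OperonAnnotation",
    "synthetic_phrsph98_reference", "gen_protein_family", "gen_operon_sequence",
    "gen_ct_table", "gen_tree_with_states", "load_design",
]

AROMATIC = set("FWY")
_REFERENCE_SEED = 987001  # fixed: the reference protein is a constant of the package


def synthetic_phrsph98_reference(length: int = 460,
                                 rules: list[ResidueRule] | None = None) -> ProteinRecord:
    """A synthetic stand-in for the PhrSph98 reference protein.

    A random amino-acid sequence (fixed internal seed, so it is a package
    constant) with each ruled residue planted at its PhrSph98-numbered
    position. Used wherever the real sequence would be, since analyses here
    depend only on the ruled positions and overall length.
    """
    rules = rules if rules is not None else default_phrsph98_rules()
    top = max(r.ref_position for r in rules)
    if length < top:
        raise ValueError(f"length {length} shorter than highest ruled position {top}")
    rng = np.random.default_rng(_REFERENCE_SEED)
    seq = list(rng.choice(list(AMINO_ACIDS), size=length))
    for rule in rules:
        seq[rule.ref_position - 1] = rule.label[0]  # canonical residue, e.g. Y389 -> Y
    return ProteinRecord("PhrSph98_synthetic", "".join(seq))


@dataclass(frozen=True)
class FamilyDesign:
    """Design for a protein family with planted homologs and decoys."""

    reference: ProteinRecord
    rules: tuple = ()
    n_true: int = 10
    n_decoy: int = 10
    substitution_rate: float = 0.05
    decoy_violations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true < 0 or self.n_decoy < 0:
            raise ValueError("n_true and n_decoy must be >= 0")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0, 1]")
        rules = self.rules or default_phrsph98_rules()
        object.__setattr__(self, "rules", tuple(rules))
        for rule in self.rules:
            if rule.ref_position > len(self.reference.sequence):
                raise ValueError(
                    f"rule {rule.label}: position {rule.ref_position} beyond "
                    f"reference length {len(self.reference.sequence)}")
        if not 1 <= self.decoy_violations <= len(self.rules):
            raise ValueError("decoy_violations must be between 1 and the number of rules")


def gen_protein_family(design: FamilyDesign) -> tuple[list[ProteinRecord], dict[str, bool]]:
    """Emit n_true rule-conserving homologs and n_decoy rule-violating decoys.

    Homologs keep the reference residue at every ruled position and mutate
    other sites i.i.d. at ``substitution_rate``. Each decoy additionally
    replaces at least ``decoy_violations`` ruled positions with a
    non-allowed, non-aromatic residue (mirroring the Thr/Leu replacements
    seen in non-homolog clades). Same seed, same output.
    """
    rng = np.random.default_rng(design.seed)
    ref = design.reference.sequence
    ruled = {r.ref_position - 1: r for r in design.rules}
    aa = list(AMINO_ACIDS)
    records: list[ProteinRecord] = []
    labels: dict[str, bool] = {}

    def mutate_background(seq: list[str]) -> list[str]:
        for i in range(len(seq)):
            if i in ruled:
                continue
            if rng.random() < design.substitution_rate:
                choices = [x for x in aa if x != seq[i]]
                seq[i] = choices[rng.integers(len(choices))]
        return seq

    for k in range(design.n_true):
        seq = mutate_background(list(ref))
        rec = ProteinRecord(f"homolog_{k + 1:03d}", "".join(seq))
        records.append(rec)
        labels[rec.id] = True

    for k in range(design.n_decoy):
        seq = mutate_background(list(ref))
        n_viol = int(rng.integers(design.decoy_violations, len(design.rules) + 1))
        positions = rng.choice(sorted(ruled), size=n_viol, replace=False)
        for p in positions:
            rule = ruled[int(p)]
            bad = sorted(set(AMINO_ACIDS) - set(rule.allowed) - AROMATIC)
            seq[int(p)] = bad[rng.integers(len(bad))]
        rec = ProteinRecord(f"decoy_{k + 1:03d}", "".join(seq))
        records.append(rec)
        labels[rec.id] = False

    return records, labels


@dataclass
class OperonAnnotation:
    """Planted ground truth, 1-based inclusive forward-strand coordinates."""

    genes: list[GeneFeature]
    overlap: OverlapRecord
    sd: SdHit
    minus35: tuple[str, int, int]  # string, start, end
    minus10: tuple[str, int, int]
    tf_sites: list[TfHit]
    strand: str
    length: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature": g.id, "kind": "CDS", "start": g.start, "end": g.end,
                 "strand": g.strand, "detail": ""} for g in self.genes]
        rows.append({"feature": "overlap", "kind": "overlap",
                     "start": 0, "end": 0, "strand": self.strand,
                     "detail": f"{self.overlap.overlap_length}nt:{self.overlap.junction_sequence}"})
        rows.append({"feature": "SD", "kind": "SD", "start": 0, "end": self.sd.motif_end,
                     "strand": self.strand, "detail": f"{self.sd.motif}:spacer{self.sd.spacer}"})
        for name, s, e in (("minus35",) + self.minus35[1:], ("minus10",) + self.minus10[1:]):
            rows.append({"feature": name, "kind": "promoter_box", "start": s, "end": e,
                         "strand": self.strand, "detail": ""})
        for t in self.tf_sites:
            rows.append({"feature": t.name, "kind": "tf_site", "start": t.start,
                         "end": t.end, "strand": t.strand, "detail": t.matched})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class OperonDesign:
    """Design for a two-gene operon with a stop/start overlap junction."""

    gene_lengths: tuple[int, int] = (240, 231)
    overlap_junction: str = "ATGTCAGTTGA"
    sd_motif: str = "AGGAG"
    sd_spacer: int = 7
    minus10: str = "TGCTATACA"
    minus35: str = "TTGAAG"
    box_spacing: int = 14
    tf_sites: tuple = (("CRP", "TCACAATT"), ("IHF", "ACAGACAA"))
    strand: str = "+"
    pad: int = 40
    promoter_gap: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        j = self.overlap_junction.upper()
        if j[:3] not in START_CODONS or j[-3:] not in STOP_CODONS:
            raise ValueError(
                "overlap junction must begin with a start codon (downstream gene) "
                "and end with a stop codon (upstream gene)")
        if len(j) % 3 == 0:
            raise ValueError("junction length a multiple of 3: the two frames would coincide")
        for L in self.gene_lengths:
            if L % 3 != 0:
                raise ValueError("gene lengths must be multiples of 3")
        if self.sd_spacer < 0:
            raise ValueError("sd_spacer must be >= 0")
        L1, L2 = self.gene_lengths
        need = len(j) + len(self.sd_motif) + self.sd_spacer + 6
        if L1 < need or L2 < len(j) + 6:
            raise ValueError("gene lengths too short for the planted junction/SD layout")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


_SAFE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in STOP_CODONS]


def _random_nt(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


def _codons_ok(gene: str) -> bool:
    body = [gene[i:i + 3] for i in range(0, len(gene) - 3, 3)]
    return all(c not in STOP_CODONS for c in body) and gene[-3:] in STOP_CODONS


def gen_operon_sequence(design: OperonDesign) -> tuple[str, OperonAnnotation]:
    """Build the operon sequence and its planted-truth annotation.

    Forward-strand layout: pad, CRP site, pad, IHF site, pad, -35 box,
    spacer, -10 box, gap, gene1 (ATG ... SD ... spacer ... junction),
    gene2 tail, pad. The junction is shared: it ends gene1 (upstream stop)
    and starts gene2 (downstream ATG) in a different frame. For strand "-"
    the whole sequence is reverse complemented and truth coordinates are
    mirrored onto the forward strand of the returned string.
    """
    rng = np.random.default_rng(design.seed)
    junction = design.overlap_junction.upper()
    L1, L2 = design.gene_lengths

    def build_gene1() -> str:
        head_len = L1 - len(junction) - design.sd_spacer - len(design.sd_motif) - 3
        for _ in range(1000):
            head = "".join(rng.choice(_SAFE_CODONS) for _ in range(head_len // 3 + 1))[:head_len]
            gene = ("ATG" + head + design.sd_motif
                    + _random_nt(rng, design.sd_spacer) + junction)
            if _codons_ok(gene):
                return gene
        raise RuntimeError("could not lay out gene1 without a premature stop")

    def build_gene2_tail() -> str:
        tail_len = L2 - len(junction)
        lead = (3 - len(junction) % 3) % 3  # completes the junction's split codon
        for _ in range(1000):
            tail = (_random_nt(rng, lead)
                    + "".join(rng.choice(_SAFE_CODONS)
                              for _ in range((tail_len - lead) // 3 - 1))
                    + "TAA")
            if _codons_ok(junction + tail):
                return tail
        raise RuntimeError("could not lay out gene2 without a premature stop")

    for _attempt in range(200):
        gene1 = build_gene1()
        tail2 = build_gene2_tail()

        parts: list[tuple[str, str]] = [("pad", _random_nt(rng, design.pad))]
        for name, site in design.tf_sites:
            parts.append((f"tf:{name}", site.upper()))
            parts.append(("pad", _random_nt(rng, 10)))
        parts.append(("minus35", design.minus35.upper()))
        parts.append(("pad", _random_nt(rng, design.box_spacing)))
        parts.append(("minus10", design.minus10.upper()))
        # the gap ends with an in-frame stop so no upstream start extends gene1
        parts.append(("pad", _random_nt(rng, max(0, design.promoter_gap - 3)) + "TAA"))
        parts.append(("gene1", gene1))
        parts.append(("gene2_tail", tail2))
        parts.append(("pad", _random_nt(rng, design.pad)))

        seq = ""
        coords: dict[str, tuple[int, int]] = {}
        tf_truth: list[TfHit] = []
        for name, chunk in parts:
            start = len(seq) + 1
            seq += chunk
            end = len(seq)
            if name.startswith("tf:"):
                tf_truth.append(TfHit(name[3:], start, end, "+", 0, chunk))
            elif name != "pad":
                coords[name] = (start, end)

        g1s, g1e = coords["gene1"]
        g2s = g1e - len(junction) + 1           # gene2 starts at the junction ATG
        g2e = coords["gene2_tail"][1]
        gene_feats = [
            GeneFeature("phr_upstream", g1s, g1e, "+", (g1s - 1) % 3),
            GeneFeature("cpd64_phr_like", g2s, g2e, "+", (g2s - 1) % 3),
        ]
        # accept only assemblies whose plus-strand ORF scan recovers exactly
        # the two planted genes and whose leading gene has no accidental SD
        found = {(f.start, f.end) for f in find_orfs(seq, 90, both_strands=False)}
        if found != {(g1s, g1e), (g2s, g2e)}:
            continue
        if any(h.target_gene == "phr_upstream"
               for h in find_sd_motifs(seq, gene_feats)):
            continue
        break
    else:
        raise RuntimeError("could not assemble a clean operon sequence in 200 attempts")
    overlap = OverlapRecord("phr_upstream", "cpd64_phr_like", len(junction), junction, True)
    sd_end = g2s - 1 - design.sd_spacer
    sd = SdHit("cpd64_phr_like", design.sd_motif.upper(), sd_end, design.sd_spacer)
    truth = OperonAnnotation(
        genes=gene_feats, overlap=overlap, sd=sd,
        minus35=(design.minus35.upper(),) + coords["minus35"],
        minus10=(design.minus10.upper(),) + coords["minus10"],
        tf_sites=tf_truth, strand="+", length=len(seq))

    if design.strand == "-":
        n = len(seq)
        seq = revcomp(seq)

        def flip(start: int, end: int) -> tuple[int, int]:
            return n - end + 1, n - start + 1

        truth.genes = [GeneFeature(g.id, *flip(g.start, g.end), "-",
                                   (n - g.end) % 3) for g in truth.genes]
        truth.sd = SdHit(sd.target_gene, sd.motif, n - sd.motif_end + 1, sd.spacer)
        truth.minus35 = (truth.minus35[0],) + flip(*truth.minus35[1:])
        truth.minus10 = (truth.minus10[0],) + flip(*truth.minus10[1:])
        truth.tf_sites = [TfHit(t.name, *flip(t.start, t.end), "-", 0, t.matched)
                          for t in truth.tf_sites]
        truth.strand = "-"

    return seq, truth


@dataclass(frozen=True)
class CtDesign:
    """Design for a qPCR Ct table with planted fold changes."""

    genes: tuple
    reference_genes: tuple
    conditions: tuple
    control_condition: str
    true_fold_changes: dict = field(default_factory=dict)  # (gene, condition) -> ratio
    baseline_ct: dict = field(default_factory=dict)        # gene -> Ct at control
    noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(self.reference_genes) - set(self.genes)
        if missing:
            raise ValueError(f"reference genes absent from gene list: {sorted(missing)}")
        if self.control_condition not in self.conditions:
            raise ValueError(f"control condition {self.control_condition!r} not in conditions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for (gene, cond), fold in self.true_fold_changes.items():
            if fold <= 0:
                raise ValueError(f"fold change for {gene}/{cond} must be > 0")
            if gene in self.reference_genes and fold != 1:
                raise ValueError(f"reference gene {gene} must have fold change 1")

    def fold(self, gene: str, condition: str) -> float:
        if condition == self.control_condition:
            return 1.0
        return float(self.true_fold_changes.get((gene, condition), 1.0))


def gen_ct_table(design: CtDesign) -> list[CtRecord]:
    """Ct records with planted folds: Ct = baseline - log2(fold) + noise.

    At noise_sd=0 the downstream 2^(-dCt) fold changes equal the designed
    ratios exactly; the same seed reproduces the table byte for byte.
    """
    rng = np.random.default_rng(design.seed)
    records = []
    for gene in design.genes:
        base = float(design.baseline_ct.get(gene, 20.0))
        for cond in design.conditions:
            shift = -np.log2(design.fold(gene, cond))
            for rep in range(1, design.replicates + 1):
                noise = rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0
                records.append(CtRecord(gene, cond, rep, base + shift + noise))
    return records


@dataclass(frozen=True)
class TreeDesign:
    """A topology plus tip activity states and the planted change events."""

    topology: str
    tip_states: dict
    planted_events: tuple = ()

    def __post_init__(self) -> None:
        if not self.topology.strip():
            raise ValueError("empty topology")


def gen_tree_with_states(design: TreeDesign):
    """Parse the planted topology and verify event-count consistency.

    Rejects unknown tips and designs whose planted event count disagrees
    with the Fitch minimum on the planted topology.
    """
    tree = parsimony.parse_newick(design.topology)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(design.tip_states) - tips
    if unknown:
        raise ValueError(f"states given for unknown tips: {sorted(unknown)}")
    missing = tips - set(design.tip_states)
    if missing:
        raise ValueError(f"tips without a state: {sorted(missing)}")
    score = parsimony.fitch_count(tree, design.tip_states)
    if score != len(design.planted_events):
        raise ValueError(
            f"planted events ({len(design.planted_events)}) inconsistent with "
            f"parsimony minimum ({score}) on the planted topology")
    return tree, dict(design.tip_states)


_DESIGN_KINDS = {"family": FamilyDesign, "operon": OperonDesign,
                 "ct": CtDesign, "tree": TreeDesign}


def load_design(path):
    """Load a design from a YAML config with a ``kind`` key
    (family | operon | ct | tree); remaining keys are the design fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    kind = data.pop("kind", None)
    if kind not in _DESIGN_KINDS:
        raise ValueError(f"config must set kind to one of {sorted(_DESIGN_KINDS)}")
    if kind == "family":
        ref = data.pop("reference", None)
        data["reference"] = (synthetic_phrsph98_reference() if ref is None
                             else ProteinRecord("reference", ref))
    for key in ("gene_lengths", "tf_sites", "genes", "reference_genes",
                "conditions", "planted_events"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(tuple(x) if isinstance(x, list) else x for x in data[key])
    if "true_fold_changes" in data:
        data["true_fold_changes"] = {tuple(k.split("/")): v
                                     for k, v in data["true_fold_changes"].items()}
    return _DESIGN_KINDS[kind](**data)
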
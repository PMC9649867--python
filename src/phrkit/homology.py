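"""Homology-screen operations over BLAST tabular output and protein sets.

The screen keeps hits with E-value strictly below 1e-3 and percent identity
strictly above 30, then discards partial sequences (low aligned coverage of
the reference) and collapses redundant ones (>85% identity) by greedy
incremental clustering in descending length order, the same scheme CD-HIT
uses (without its word-filter heuristics, so bit-identical clusters are not
promised).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .records import ProteinRecord

__all__ = [
    "BlastHit",
    "IdentityParams",
    "Cluster",
    "read_blast_tabular",
    "filter_blast_hits",
    "pairwise_identity",
    "reference_coverage",
    "remove_partial",
    "cluster_redundant",
    "read_fasta",
    "write_fasta",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    query_coverage: float | None = None
    subject_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.subject_id}: negative E-value {self.evalue}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"{self.subject_id}: identity {self.percent_identity} outside [0, 100]")


@dataclass(frozen=True)
class IdentityParams:
    """Global-alignment parameters for percent-identity computation.

    ``denominator`` chooses what identities are divided by:
    "aligned_columns" (columns where neither sequence is gapped, default),
    "shorter_sequence", or "alignment_length_with_gaps".
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    denominator: str = "aligned_columns"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.denominator not in ("aligned_columns", "shorter_sequence",
                                    "alignment_length_with_gaps"):
            raise ValueError(f"unknown denominator convention {self.denominator!r}")


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)  # member -> % id to representative


def read_fasta(path) -> list[ProteinRecord]:
    return [ProteinRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                  "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def read_blast_tabular(path) -> list[BlastHit]:
    """Read BLAST outfmt-6-style TSV; extra columns beyond the 12 standard are ignored."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    if df.shape[1] < 12:
        raise ValueError(f"expected >= 12 BLAST tabular columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = BLAST6_COLUMNS
    hits = []
    for lineno, row in enumerate(df.itertuples(), start=1):
        try:
            hits.append(BlastHit(str(row.qseqid), str(row.sseqid), float(row.pident),
                                 int(row.length), float(row.evalue)))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


def filter_blast_hits(hits, evalue_max: float = 1e-3, identity_min: float = 30.0) -> list[BlastHit]:
    """Keep hits with evalue strictly below ``evalue_max`` AND identity strictly
    above ``identity_min``; input order preserved. Idempotent."""
    return [h for h in hits if h.evalue < evalue_max and h.percent_identity > identity_min]


def _aligner(params: IdentityParams) -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "global"
    aln.substitution_matrix = substitution_matrices.load(params.matrix)
    aln.open_gap_score = -params.gap_open
    aln.extend_gap_score = -params.gap_extend
    return aln


def _check_protein(seq: str, which: str) -> None:
    if not seq:
        raise ValueError(f"sequence {which} is empty")
    for i, ch in enumerate(seq):
        if ch not in AA_ALPHABET:
            raise ValueError(f"sequence {which}: illegal character {ch!r} at position {i + 1}")


def pairwise_identity(a: str, b: str, params: IdentityParams | None = None) -> float:
    """Percent identity from one optimal global alignment of ``a`` and ``b``.

    The pair is ordered canonically before aligning so the result is exactly
    symmetric even when co-optimal alignments with different identity counts
    exist.
    """
    params = params or IdentityParams()
    a, b = a.upper(), b.upper()
    _check_protein(a, "a")
    _check_protein(b, "b")
    x, y = sorted((a, b))
    alignment = _aligner(params).align(x, y)[0]
    sx, sy = str(alignment[0]), str(alignment[1])
    matches = sum(1 for p, q in zip(sx, sy) if p == q and p != "-")
    aligned_cols = sum(1 for p, q in zip(sx, sy) if p != "-" and q != "-")
    if params.denominator == "aligned_columns":
        denom = aligned_cols
    elif params.denominator == "shorter_sequence":
        denom = min(len(a), len(b))
    else:
        denom = len(sx)
    return 100.0 * matches / denom if denom else 0.0


def reference_coverage(record: ProteinRecord, reference: ProteinRecord,
                       params: IdentityParams | None = None) -> float:
    """Fraction of reference residues aligned to a residue of ``record``."""
    params = params or IdentityParams()
    alignment = _aligner(params).align(reference.sequence, record.sequence)[0]
    covered = sum(int(e) - int(s) for s, e in alignment.aligned[0])
    return covered / len(reference.sequence)


def remove_partial(records, reference: ProteinRecord, min_coverage: float = 0.7,
                   params: IdentityParams | None = None) -> list[ProteinRecord]:
    """Discard records whose aligned coverage of the reference is below
    ``min_coverage``; empty input yields empty output."""
    return [r for r in records if reference_coverage(r, reference, params) >= min_coverage]


def cluster_redundant(records, threshold: float = 0.85,
                      params: IdentityParams | None = None) -> list[Cluster]:
    """Greedy incremental clustering at a fractional identity threshold.

    Records are visited in descending length order (ties by input order);
    each joins the first existing cluster whose representative it matches at
    strictly more than ``threshold`` identity, otherwise it founds a new
    cluster with itself as representative.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    params = params or IdentityParams()
    order = sorted(range(len(records)), key=lambda i: (-len(records[i].sequence), i))
    clusters: list[Cluster] = []
    reps: list[ProteinRecord] = []
    for i in order:
        rec = records[i]
        placed = False
        for cl, rep in zip(clusters, reps):
            ident = pairwise_identity(rec.sequence, rep.sequence, params)
            if ident > threshold * 100.0:
                cl.member_ids.append(rec.id)
                cl.identities[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec.id, [rec.id], {rec.id: 100.0}))
            reps.append(rec)
    return clusters


def write_cluster_report(clusters, path) -> None:
    rows = [{"representative": c.representative_id, "member": m,
             "percent_identity": c.identities[m]}
            for c in clusters for m in c.member_ids]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
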
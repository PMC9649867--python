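"""Annotation of a compact two-gene bacterial operon.

Covers ORF scanning, stop/start overlap junction detection (translational
coupling), intragenic Shine-Dalgarno motifs, sigma-70 -10/-35 promoter box
scanning by consensus match count, transcription-factor site search (CRP,
IHF), distance-based operon grouping and in-silico PCR.

All coordinates are 1-based inclusive on the forward strand; minus-strand
features carry strand "-".
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .records import GeneFeature

__all__ = [
    "START_CODONS", "STOP_CODONS",
    "OverlapRecord", "SdHit", "PromoterHit", "TfHit", "PrimerPair", "AmpliconHit",
    "find_orfs", "detect_overlaps", "find_sd_motifs", "scan_promoter",
    "scan_tf_sites", "predict_operons", "in_silico_pcr", "features_to_gff3",
]

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
NT = set("ACGTN")

DEFAULT_SD_MOTIFS = ("AGGAGG", "AGGAG", "GGAG")
DEFAULT_TF_SITES = {"CRP": "TCACAATT", "IHF": "ACAGACAA"}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _check_nt(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in NT:
            raise ValueError(f"illegal nucleotide {ch!r} at position {i + 1}")


@dataclass(frozen=True)
class OverlapRecord:
    upstream_id: str
    downstream_id: str
    overlap_length: int
    junction_sequence: str
    frames_differ: bool


@dataclass(frozen=True)
class SdHit:
    target_gene: str
    motif: str
    motif_end: int   # forward-strand coordinate of the motif's 3' base (gene strand)
    spacer: int      # nt between motif end and the base before the start codon


@dataclass(frozen=True)
class PromoterHit:
    minus35: str
    minus35_start: int
    minus10: str
    minus10_start: int
    spacing: int
    score: int


@dataclass(frozen=True)
class TfHit:
    name: str
    start: int
    end: int
    strand: str
    mismatches: int
    matched: str


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str   # 5'->3' on the plus strand of the template region
    reverse: str   # 5'->3' on the opposite strand


@dataclass(frozen=True)
class AmpliconHit:
    primer_name: str
    start: int
    end: int
    forward_mismatches: int
    reverse_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_orfs(seq: str, min_len_nt: int = 90, start_codons=("ATG",),
              both_strands: bool = True) -> list[GeneFeature]:
    """All complete ORFs (start codon through in-frame stop, inclusive).

    For each stop codon only the longest upstream ORF (first start after the
    previous in-frame stop) is reported. Starts default to ATG; pass
    ``START_CODONS`` to admit the alternative bacterial starts GTG/TTG.
    Minus-strand ORFs are reported in forward coordinates with strand "-".
    ``frame`` is 0/1/2 relative to the sequence start on the ORF's own strand.
    """
    seq = seq.upper()
    _check_nt(seq)
    feats: list[GeneFeature] = []

    def scan(s: str, strand: str) -> None:
        n = len(s)
        for frame in range(3):
            start_at: int | None = None
            for i in range(frame, n - 2, 3):
                codon = s[i:i + 3]
                if start_at is None and codon in start_codons:
                    start_at = i
                elif codon in STOP_CODONS:
                    if start_at is not None:
                        length = i + 3 - start_at
                        if length >= min_len_nt:
                            if strand == "+":
                                fstart, fend = start_at + 1, i + 3
                            else:
                                fstart, fend = n - (i + 3) + 1, n - start_at
                            feats.append(GeneFeature(
                                f"orf_{strand}{frame}_{fstart}", fstart, fend,
                                strand, frame))
                    start_at = None

    scan(seq, "+")
    if both_strands:
        scan(revcomp(seq), "-")
    feats.sort(key=lambda f: (f.start, f.end))
    return feats


def _frame_on_strand(feature: GeneFeature, seqlen: int) -> int:
    """Reading frame from the feature's own 5' end, on its strand."""
    if feature.strand == "+":
        return (feature.start - 1) % 3
    return (seqlen - feature.end) % 3


def detect_overlaps(features: list[GeneFeature], seq: str) -> list[OverlapRecord]:
    """Overlap records for consecutive same-strand features sorted 5'->3'.

    A pair overlapping by k nt yields a record with the k-nt junction
    substring (forward-strand orientation of the pair for "+", reverse
    complemented for "-") and whether the two reading frames differ.
    Opposite-strand overlaps are excluded.
    """
    seq = seq.upper()
    recs = []
    ordered = sorted(features, key=lambda f: f.start)
    for up, dn in zip(ordered, ordered[1:]):
        if up.strand != dn.strand:
            continue
        ov = up.end - dn.start + 1
        if ov <= 0:
            continue
        junction = seq[dn.start - 1:up.end]
        if up.strand == "-":
            junction = revcomp(junction)
            upstream, downstream = dn, up  # 5'->3' order on the minus strand
        else:
            upstream, downstream = up, dn
        recs.append(OverlapRecord(
            upstream.id, downstream.id, ov, junction,
            _frame_on_strand(up, len(seq)) != _frame_on_strand(dn, len(seq))))
    return recs


def find_sd_motifs(seq: str, features: list[GeneFeature],
                   motifs=DEFAULT_SD_MOTIFS, window=(4, 13)) -> list[SdHit]:
    """Shine-Dalgarno motif hits upstream of each feature's start codon.

    The spacer is the number of nt strictly between the motif's 3' base and
    the first base of the start codon; hits with spacer inside ``window``
    (inclusive) are reported. At equal motif end position the longest motif
    wins. Works in gene-strand space, so intragenic SDs (inside an upstream
    overlapping gene) are found naturally.
    """
    seq = seq.upper()
    lo, hi = window
    hits = []
    motifs = sorted(motifs, key=len, reverse=True)
    for feat in features:
        if feat.strand == "+":
            start_pos = feat.start - 1           # 0-based first base of start codon
            region_end = start_pos - 1 - lo      # 0-based last allowed motif base
            s = seq
        else:
            s = revcomp(seq)
            start_pos = len(seq) - feat.end
            region_end = start_pos - 1 - lo
        best_at: dict[int, str] = {}
        for motif in motifs:
            for spacer in range(lo, hi + 1):
                end0 = start_pos - 1 - spacer            # motif 3' base, 0-based
                beg0 = end0 - len(motif) + 1
                if beg0 < 0:
                    continue
                if s[beg0:end0 + 1] == motif and end0 not in best_at:
                    best_at[end0] = motif
        for end0, motif in sorted(best_at.items()):
            spacer = start_pos - 1 - end0
            fwd_end = end0 + 1 if feat.strand == "+" else len(seq) - end0
            hits.append(SdHit(feat.id, motif, fwd_end, spacer))
    return hits


def _consensus_score(site: str, consensus: str) -> int:
    return sum(1 for a, b in zip(site, consensus) if a == b)


def scan_promoter(seq: str, upstream_window: tuple[int, int],
                  consensus_minus10: str = "TATAAT", consensus_minus35: str = "TTGACA",
                  spacing: tuple[int, int] = (15, 19), min_score: int = 8) -> list[PromoterHit]:
    """Enumerate -35/-10 box pairs in a window, scored by consensus matches.

    ``upstream_window`` is 1-based inclusive on the forward strand; the score
    is the number of positions matching each consensus, summed over both
    boxes (mismatches score 0). Pairs whose box spacing falls inside
    ``spacing`` and whose score is >= ``min_score`` are returned sorted by
    descending score then position.
    """
    seq = seq.upper()
    w0, w1 = upstream_window
    if not (1 <= w0 <= w1 <= len(seq)):
        raise ValueError(f"window {upstream_window} outside sequence of length {len(seq)}")
    region = seq[w0 - 1:w1]
    hits = []
    l35, l10 = len(consensus_minus35), len(consensus_minus10)
    for i in range(len(region) - l35 + 1):
        site35 = region[i:i + l35]
        s35 = _consensus_score(site35, consensus_minus35)
        for gap in range(spacing[0], spacing[1] + 1):
            j = i + l35 + gap
            if j + l10 > len(region):
                continue
            site10 = region[j:j + l10]
            score = s35 + _consensus_score(site10, consensus_minus10)
            if score >= min_score:
                hits.append(PromoterHit(site35, w0 + i, site10, w0 + j, gap, score))
    hits.sort(key=lambda h: (-h.score, h.minus35_start, h.minus10_start))
    return hits


def scan_tf_sites(seq: str, sites: dict = None, max_mismatch: int = 0) -> list[TfHit]:
    """Find transcription-factor binding sites on both strands, allowing up
    to ``max_mismatch`` mismatches."""
    seq = seq.upper()
    sites = sites if sites is not None else DEFAULT_TF_SITES
    hits = []
    for name, site in sites.items():
        L = len(site)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - L + 1):
                word = s[i:i + L]
                mm = sum(1 for a, b in zip(word, site) if a != b)
                if mm <= max_mismatch:
                    if strand == "+":
                        start = i + 1
                    else:
                        start = len(seq) - (i + L) + 1
                    hits.append(TfHit(name, start, start + L - 1, strand, mm, word))
    hits.sort(key=lambda h: (h.start, h.name, h.strand))
    return hits


def predict_operons(features: list[GeneFeature], max_gap: int = 50,
                    require_same_strand: bool = True) -> list[list[GeneFeature]]:
    """Group consecutive same-strand genes with intergenic gap <= ``max_gap``
    (overlapping genes have negative gap); only groups of >= 2 are reported.

    With ``require_same_strand`` each strand is chained independently, so a
    gene on the opposite strand lying between two co-directional genes does
    not break their operon; convergent/divergent pairs are never grouped.
    """
    groups: list[list[GeneFeature]] = []
    strands = ("+", "-") if require_same_strand else ("any",)
    for strand in strands:
        pool = [f for f in features if strand in ("any", f.strand)]
        pool.sort(key=lambda f: (f.start, f.end))
        current: list[GeneFeature] = []
        for feat in pool:
            if current and feat.start - current[-1].end - 1 <= max_gap:
                current.append(feat)
                continue
            if len(current) >= 2:
                groups.append(current)
            current = [feat]
        if len(current) >= 2:
            groups.append(current)
    groups.sort(key=lambda g: g[0].start)
    return groups


def _find_with_mismatches(hay: str, needle: str, max_mm: int) -> list[tuple[int, int]]:
    out = []
    L = len(needle)
    for i in range(len(hay) - L + 1):
        mm = sum(1 for a, b in zip(hay[i:i + L], needle) if a != b)
        if mm <= max_mm:
            out.append((i, mm))
    return out


def in_silico_pcr(seq: str, primers: PrimerPair, max_mismatch: int = 0,
                  max_product: int = 5000) -> list[AmpliconHit]:
    """Predict PCR products on the plus strand of ``seq``.

    The forward primer anneals to the plus strand as given; the reverse
    primer (5'->3' on the opposite strand) anneals where its reverse
    complement occurs downstream. The amplicon runs from the forward
    primer's 5' end through the reverse primer's 5' end inclusive, so both
    primer footprints count toward the product length. All products up to
    ``max_product`` nt are reported.
    """
    seq = seq.upper()
    fwd = primers.forward.upper()
    rev_rc = revcomp(primers.reverse.upper())
    hits = []
    fwd_sites = _find_with_mismatches(seq, fwd, max_mismatch)
    rev_sites = _find_with_mismatches(seq, rev_rc, max_mismatch)
    for fpos, fmm in fwd_sites:
        for rpos, rmm in rev_sites:
            start = fpos + 1
            end = rpos + len(rev_rc)       # reverse primer 5' end on plus strand
            if end <= fpos + len(fwd):
                continue
            length = end - start + 1
            if length <= max_product:
                hits.append(AmpliconHit(primers.name, start, end, fmm, rmm))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def features_to_gff3(features: list[GeneFeature], seqid: str = "sequence") -> str:
    lines = ["##gff-version 3"]
    for f in sorted(features, key=lambda x: x.start):
        lines.append("\t".join([
            seqid, "phrkit", f.kind, str(f.start), str(f.end), ".",
            f.strand, str(f.frame), f"ID={f.id}"]))
    return "\n".join(lines) + "\n"
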
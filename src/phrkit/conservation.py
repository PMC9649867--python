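"""Functional-residue conservation screening over a multiple sequence alignment.

A candidate bifunctional CPD/(6-4) photolyase must conserve, at the columns
homologous to the PhrSph98 reference positions, every residue implicated in
the electron-transfer chain to FAD (Y389-W369-W390-F376-W381), FAD binding
(N412, D413), DNA-lesion binding (W314, A430, M388) and lesion stabilization
(E310, N384). A sequence conserving all twelve is classified a true
bifunctional homolog; failing any one rule excludes it.

Also provides sequence-logo column information content (Shannon) and a
BMGE-like entropy/gap column trimmer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO

from .records import Msa, ResidueRule

__all__ = [
    "default_phrsph98_rules",
    "map_reference_positions",
    "apply_residue_rules",
    "classify_homologs",
    "column_information",
    "trim_alignment",
    "read_alignment",
    "ConservationReport",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_BITS = math.log2(20)

_ROLE_ET = "electron_transfer"
_ROLE_FAD = "fad_binding"
_ROLE_BIND = "lesion_binding"
_ROLE_STAB = "lesion_stabilization"


def default_phrsph98_rules() -> list[ResidueRule]:
    """The twelve conservation rules, positions in PhrSph98 numbering.

    F376 admits the aromatic substitutions Trp and Tyr observed within the
    homolog clades; A430 admits the Trp replacement seen in class II CPD
    photolyases (M. mazei W421); the remaining positions are strict.
    """
    def rule(label, pos, allowed, role):
        return ResidueRule(label, pos, frozenset(allowed), role)

    return [
        rule("W369", 369, "W", _ROLE_ET),
        rule("W390", 390, "W", _ROLE_ET),
        rule("Y389", 389, "Y", _ROLE_ET),
        rule("F376", 376, "FWY", _ROLE_ET),
        rule("W381", 381, "W", _ROLE_ET),
        rule("N412", 412, "N", _ROLE_FAD),
        rule("D413", 413, "D", _ROLE_FAD),
        rule("W314", 314, "W", _ROLE_BIND),
        rule("A430", 430, "AW", _ROLE_BIND),
        rule("M388", 388, "M", _ROLE_BIND),
        rule("E310", 310, "E", _ROLE_STAB),
        rule("N384", 384, "N", _ROLE_STAB),
    ]


def read_alignment(path) -> Msa:
    aln = AlignIO.read(str(path), "fasta")
    return Msa([r.id for r in aln], [str(r.seq).upper() for r in aln])


def map_reference_positions(msa: Msa, ref_id: str, positions) -> list[int]:
    """Map 1-based ungapped reference positions to 1-based alignment columns.

    Column c maps to position p when the reference's ungapped prefix through
    column c has length exactly p; the returned mapping is strictly
    increasing for increasing positions.
    """
    ref_row = msa.row(ref_id)
    ungapped_len = sum(1 for ch in ref_row if ch != "-")
    pos_to_col: dict[int, int] = {}
    p = 0
    for c, ch in enumerate(ref_row, start=1):
        if ch != "-":
            p += 1
            pos_to_col[p] = c
    cols = []
    for pos in positions:
        if not 1 <= pos <= ungapped_len:
            raise ValueError(f"position {pos} beyond reference length {ungapped_len}")
        cols.append(pos_to_col[pos])
    return cols


@dataclass
class ConservationReport:
    """Per-sequence, per-rule observations and pass/fail outcomes."""

    rules: list[ResidueRule]
    observed: dict[str, dict[str, str]] = field(default_factory=dict)  # seq -> label -> residue
    passed: dict[str, dict[str, bool]] = field(default_factory=dict)
    column_frequencies: pd.DataFrame | None = None

    def all_pass(self, seq_id: str) -> bool:
        return all(self.passed[seq_id].values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sequence": sid, "rule": r.label, "observed": self.observed[sid][r.label],
                 "pass": self.passed[sid][r.label]}
                for sid in self.observed for r in self.rules]
        return pd.DataFrame(rows)


def apply_residue_rules(msa: Msa, ref_id: str, rules: list[ResidueRule] | None = None) -> ConservationReport:
    """Evaluate every rule at its mapped column for every aligned sequence.

    A gap at a ruled column counts as failure: a deleted catalytic residue
    cannot function.
    """
    rules = rules if rules is not None else default_phrsph98_rules()
    cols = map_reference_positions(msa, ref_id, [r.ref_position for r in rules])
    report = ConservationReport(rules=rules)
    for sid, row in zip(msa.ids, msa.rows):
        obs, ok = {}, {}
        for rule, c in zip(rules, cols):
            residue = row[c - 1]
            obs[rule.label] = residue
            ok[rule.label] = residue in rule.allowed
        report.observed[sid] = obs
        report.passed[sid] = ok

    freq = []
    for c in cols:
        col = [r[c - 1] for r in msa.rows]
        for aa in sorted(set(col)):
            freq.append({"column": c, "residue": aa,
                         "frequency": col.count(aa) / len(col) if col else 0.0})
    report.column_frequencies = pd.DataFrame(freq)
    return report


def classify_homologs(report: ConservationReport, clades: dict[str, str] | None = None):
    """Label each sequence true_homolog iff it passes every rule.

    Returns (labels, counts) where counts tallies true homologs per clade
    when a sequence->clade mapping is supplied (total under key "all").
    """
    labels = {sid: ("true_homolog" if report.all_pass(sid) else "non_homolog")
              for sid in report.observed}
    counts: dict[str, int] = {"all": sum(1 for v in labels.values() if v == "true_homolog")}
    if clades:
        for sid, lab in labels.items():
            if lab == "true_homolog":
                cl = clades.get(sid, "unassigned")
                counts[cl] = counts.get(cl, 0) + 1
    return labels, counts


def column_information(msa: Msa, correct_small_sample: bool = False) -> list[float | None]:
    """Per-column information content in bits, WebLogo style.

    R = log2(20) - H with H the Shannon entropy of residue frequencies
    (gaps excluded from the counts). With ``correct_small_sample`` the
    approximate correction e_n = 19 / (2 ln2 n) is subtracted, clipped at 0.
    All-gap columns have undefined content, reported as None.
    """
    out: list[float | None] = []
    for j in range(msa.n_columns):
        col = [ch for ch in msa.column(j) if ch != "-"]
        n = len(col)
        if n == 0:
            out.append(None)
            continue
        counts = np.array([col.count(aa) for aa in sorted(set(col))], dtype=float)
        p = counts / n
        h = float(-(p * np.log2(p)).sum())
        r = MAX_BITS - h
        if correct_small_sample:
            r -= 19.0 / (2.0 * math.log(2) * n)
        out.append(max(0.0, min(MAX_BITS, r)))
    return out


def logo_table(msa: Msa, correct_small_sample: bool = False) -> pd.DataFrame:
    """Logo data: one row per (column, residue) with frequency and column bits."""
    bits = column_information(msa, correct_small_sample)
    rows = []
    for j in range(msa.n_columns):
        col = [ch for ch in msa.column(j) if ch != "-"]
        for aa in sorted(set(col)):
            rows.append({"column": j + 1, "residue": aa,
                         "frequency": col.count(aa) / len(col),
                         "bits": bits[j]})
    return pd.DataFrame(rows)


def _column_entropy_with_gaps(col: str) -> float:
    # gap counted as a 21st symbol, BMGE-like
    counts = np.array([col.count(s) for s in sorted(set(col))], dtype=float)
    p = counts / len(col)
    return float(-(p * np.log2(p)).sum())


def trim_alignment(msa: Msa, max_gap_fraction: float = 0.2, max_entropy: float = 2.0) -> Msa:
    """Keep exactly the columns with gap fraction <= ``max_gap_fraction`` and
    entropy (gaps as a 21st symbol) <= ``max_entropy``; raises if nothing
    survives."""
    keep = []
    for j in range(msa.n_columns):
        col = msa.column(j)
        gap_frac = col.count("-") / len(col)
        if gap_frac <= max_gap_fraction and _column_entropy_with_gaps(col) <= max_entropy:
            keep.append(j)
    if not keep:
        raise ValueError(
            f"no columns survive trimming (max_gap_fraction={max_gap_fraction}, "
            f"max_entropy={max_entropy})")
    return Msa(list(msa.ids), ["".join(row[j] for j in keep) for row in msa.rows])
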
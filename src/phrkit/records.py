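"""Shared lightweight record types used across the package.

Coordinates follow the GenBank convention throughout: 1-based, inclusive,
always expressed on the forward strand, with orientation carried by an
explicit ``strand`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence with an optional clade/taxonomy label."""

    id: str
    sequence: str
    clade: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueRule:
    """One functional-residue conservation rule.

    ``ref_position`` is a 1-based index into the *ungapped* reference
    sequence; ``allowed`` is the residue set counted as conserved at that
    position; ``role`` names the functional category the residue belongs to
    (electron transfer chain, FAD binding, lesion binding or lesion
    stabilization); ``label`` is the conventional residue label, e.g. "Y389".
    """

    label: str
    ref_position: int
    allowed: frozenset[str]
    role: str

    def __post_init__(self) -> None:
        if not self.allowed:
            raise ValueError(f"rule {self.label}: allowed residue set is empty")
        if self.ref_position < 1:
            raise ValueError(f"rule {self.label}: ref_position must be >= 1")


@dataclass(frozen=True)
class GeneFeature:
    """A strand-aware coordinate interval, 1-based inclusive, forward strand."""

    id: str
    start: int
    end: int
    strand: str = "+"
    frame: int = 0
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"{self.id}: invalid interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CtRecord:
    """One qPCR threshold-cycle measurement."""

    gene: str
    condition: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if not self.ct > 0 or self.ct != self.ct:  # NaN guard
            raise ValueError(f"{self.gene}/{self.condition}: Ct must be finite and > 0")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass
class Msa:
    """An ordered multiple sequence alignment over amino acids plus gap '-'.

    All gapped sequences must have equal length and each ungapped sequence
    must be non-empty.
    """

    ids: list[str] = field(default_factory=list)
    rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows:
            ncol = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise ValueError(f"{rid}: row length {len(row)} != {ncol}")
                if not row.replace("-", ""):
                    raise ValueError(f"{rid}: sequence is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)
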
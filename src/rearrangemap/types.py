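"""Core domain types shared across the rearrangement-mapping pipeline.

Coordinate convention: all breakpoint and element coordinates are 1-based
inclusive genomic positions.  A :class:`ReferenceLocus` carries an ``offset``
(the genomic coordinate of its first base) so that a sub-region of a
chromosome can be analysed in genomic coordinates throughout; conversion to
half-open 0-based (BED) happens only at I/O boundaries.

For a deletion junction, ``bp5`` is the last retained base before the join
and ``bp3`` the first retained base after it (the deleted interval is
``[bp5+1, bp3-1]``).  For a tandem-duplication junction the same two fields
are reused with ``bp3 <= bp5``: ``bp5`` is the last base of the duplicated
interval and ``bp3`` its first base, so the derived allele around the
junction reads ``...seq[..bp5] | inserted_seq | seq[bp3..]...`` in both
cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceLocus:
    """A reference sub-sequence anchored at a 1-based genomic offset."""

    name: str
    offset: int
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError("locus sequence must be non-empty")
        if self.offset < 1:
            raise ValueError("locus offset must be >= 1 (1-based genomic)")
        extra = set(self.sequence) - DNA_ALPHABET
        if extra:
            raise ValueError(f"non-DNA characters in locus sequence: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def start(self) -> int:
        return self.offset

    @property
    def end(self) -> int:
        """Genomic coordinate of the last base (1-based inclusive)."""
        return self.offset + len(self.sequence) - 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def local(self, pos: int) -> int:
        """0-based index into ``sequence`` for a genomic coordinate."""
        if not self.contains(pos):
            raise ValueError(
                f"coordinate {pos} outside locus {self.name} "
                f"[{self.start}, {self.end}]"
            )
        return pos - self.offset

    def base(self, pos: int) -> str:
        return self.sequence[self.local(pos)]

    def fetch(self, start: int, end: int) -> str:
        """Sub-sequence for a 1-based inclusive genomic interval."""
        if start > end:
            raise ValueError(f"fetch start {start} > end {end}")
        return self.sequence[self.local(start) : self.local(end) + 1]


REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA")


@dataclass(frozen=True)
class RepeatElement:
    """One interspersed repeat annotation (RepeatMasker-style)."""

    family: str
    start: int
    end: int
    strand: str
    class_: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"repeat start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"repeat strand must be + or -, got {self.strand!r}")
        if self.class_ not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.class_!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def family_group(self) -> str:
        """Superfamily used for homology-pairing decisions.

        All Alu subfamilies (AluY, AluSx, ...) collapse to ``Alu``; other
        families group by their repeat class.
        """
        if self.family.replace(" ", "").startswith("Alu"):
            return "Alu"
        return self.class_


@dataclass
class TruthRecord:
    """Ground truth for a planted rearrangement (simulation plumbing).

    Coordinates are leftmost-normalized, so parameter-recovery comparisons
    against pipeline output are exact string/integer comparisons.
    """

    event_type: str  # {"deletion", "duplication"}
    bp5: int
    bp3: int
    planted_microhomology: int = 0
    inserted_seq: str = ""
    mechanism_label: str = "NHEJ"  # {"NAHR", "NHEJ"}

    def __post_init__(self) -> None:
        if self.event_type not in ("deletion", "duplication"):
            raise ValueError(f"bad event_type {self.event_type!r}")
        if self.mechanism_label not in ("NAHR", "NHEJ"):
            raise ValueError(f"bad mechanism_label {self.mechanism_label!r}")
        if self.planted_microhomology < 0:
            raise ValueError("planted_microhomology must be >= 0")
        if self.event_type == "deletion" and not self.bp5 < self.bp3:
            raise ValueError("deletion requires bp5 < bp3")
        if self.planted_microhomology > 0 and self.inserted_seq:
            raise ValueError("microhomology and junction insertion are mutually exclusive")


@dataclass
class Junction:
    """A resolved rearrangement junction.

    ``microhomology_len`` counts the flank-shared bases that make the exact
    breakpoint ambiguous; ``ambiguity_interval`` is the inclusive range of
    equivalent ``bp5`` placements (leftmost-normalized coordinates are
    stored).  A non-empty untemplated insertion excludes microhomology.
    """

    bp5: int
    bp3: int
    microhomology_len: int = 0
    microhomology_seq: str = ""
    inserted_seq: str = ""
    ambiguity_interval: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.microhomology_len != len(self.microhomology_seq):
            raise ValueError("microhomology_len must equal len(microhomology_seq)")
        if self.inserted_seq and self.microhomology_len > 0:
            raise ValueError("inserted_seq and microhomology are mutually exclusive")


@dataclass
class RearrangementCall:
    """A fully annotated rearrangement event."""

    event_type: str
    start: int
    end: int
    size: int
    nomenclature_report_style: str = ""
    nomenclature_hgvs: str = ""
    mechanism: str = "unclassified"  # {"NAHR", "NHEJ", "unclassified"}
    repeat5: Optional[RepeatElement] = None
    repeat3: Optional[RepeatElement] = None
    junction: Optional[Junction] = None
    pathogenic_flag: bool = False
    pathogenic_rationale: str = ""

    def __post_init__(self) -> None:
        if self.size != self.end - self.start + 1:
            raise ValueError("size must equal end - start + 1")


@dataclass
class DosageProfile:
    """Normalized MLPA dosage ratios for one sample and one reaction.

    ``ratios`` maps probe name to ``(exon_label, normalized_ratio)``.
    """

    sample_id: str
    ratios: dict[str, tuple[str, float]]
    reaction_id: int

    def __post_init__(self) -> None:
        if self.reaction_id not in (1, 2):
            raise ValueError("reaction_id must be 1 or 2")
        for probe, (_exon, ratio) in self.ratios.items():
            if ratio < 0:
                raise ValueError(f"negative dosage ratio for probe {probe}")

    def exon_ratios(self) -> dict[str, float]:
        """Mean ratio per exon (probes of the same exon averaged)."""
        acc: dict[str, list[float]] = {}
        for _probe, (exon, ratio) in self.ratios.items():
            acc.setdefault(exon, []).append(ratio)
        return {exon: sum(v) / len(v) for exon, v in acc.items()}


@dataclass
class ExonCall:
    """Per-exon copy-number call from two independent MLPA reactions."""

    exon: str
    state: str  # {"deletion", "normal", "duplication"}
    ratio_r1: float
    ratio_r2: float
    confirmed: bool
    discordant: bool = False

    def __post_init__(self) -> None:
        if self.state not in ("deletion", "normal", "duplication"):
            raise ValueError(f"bad exon-call state {self.state!r}")
        if self.confirmed and self.state == "normal":
            raise ValueError("confirmed is reserved for non-normal states")


@dataclass
class CnvSegment:
    """A copy-number segment from array-CGH probe log2 ratios."""

    start: int
    end: int
    n_probes: int
    mean_log2: float
    state: str  # {"loss", "gain"}

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.state not in ("loss", "gain"):
            raise ValueError(f"bad segment state {self.state!r}")


@dataclass
class SplitSegment:
    """One aligned piece of a (possibly chimeric) read."""

    read_start: int  # 0-based, half-open in read coordinates
    read_end: int
    ref_start: int  # 1-based inclusive genomic
    ref_end: int
    strand: str
    mismatches: int


@dataclass
class SplitAlignment:
    """Alignment of one read, split into at most two reference segments.

    For a chimeric read, ``bp5``/``bp3``/``inserted_seq`` describe the
    leftmost-normalized junction implied by the two anchors;
    ``orientation`` is ``"del"`` when the suffix anchor lies downstream of
    the prefix anchor and ``"dup"`` when it lies upstream (tandem
    head-to-tail junction).
    """

    read_id: str
    seg1: Optional[SplitSegment]
    seg2: Optional[SplitSegment]
    is_chimeric: bool
    ambiguous: bool = False
    orientation: str = ""
    bp5: int = 0
    bp3: int = 0
    inserted_seq: str = ""


@dataclass
class BreakpointCluster:
    """A group of concordant chimeric reads supporting one junction."""

    region5: tuple[int, int]
    region3: tuple[int, int]
    support: int
    bp5: int
    bp3: int
    orientation: str
    inserted_seq: str = ""
    junction_consensus: str = ""
    read_ids: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class ContingencyResult:
    """One 2x2 association test result."""

    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        for row in self.table:
            for c in row:
                if c < 0:
                    raise ValueError("negative contingency count")
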
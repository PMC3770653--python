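"""Junction resolution, microhomology, mechanism classification, nomenclature.

The central quantity here is junction *microhomology*: sequence shared by
the two joined flanks that makes the exact breakpoint position ambiguous.
For a deletion joining ``...seq[..bp5]`` to ``seq[bp3..]...`` the derived
allele is unchanged by sliding the junction anywhere within the shared
stretch, so a single reported coordinate pair is a convention.  This module
computes the maximal such stretch (common flank suffix + common flank
prefix), reports the ambiguity interval, and normalizes every junction to
its *leftmost* equivalent placement so that simulator truth, read-derived
junctions and annotations are directly comparable.

Mechanism calls follow the repeat-recombination logic used for Alu-dense
disease loci: substantial junction microhomology inside two same-orientation
repeats of the same superfamily indicates nonallelic homologous
recombination (NAHR); little or no homology indicates nonhomologous
end-joining (NHEJ) regardless of whether a repeat happens to span one or
both breakpoints — repeat overlap alone is not a proxy for NAHR.
"""

from __future__ import annotations

import bisect
from typing import Optional, Sequence

from .types import (
    Junction,
    RearrangementCall,
    ReferenceLocus,
    RepeatElement,
)

MSH2_ENSEMBL_ID = "ENSG00000095002"


class UnresolvedBreakpointError(ValueError):
    """Raised when nomenclature is requested for an event without
    sequence-resolved breakpoints; use MLPA-style bounded notation
    (e.g. ``c.212-?_366+?del``) instead."""


# ---------------------------------------------------------------------------
# Microhomology and leftmost normalization


def compute_microhomology(
    locus: ReferenceLocus, bp5: int, bp3: int
) -> tuple[int, str, tuple[int, int]]:
    """Microhomology of the deletion junction joining bp5 to bp3.

    Parameters are 1-based genomic coordinates with ``bp5 < bp3``; ``bp5``
    is the last retained base before the join, ``bp3`` the first retained
    base after it.  Returns ``(length, sequence, ambiguity_interval)``
    where ``length`` is the maximal number of bases the junction can slide
    over while reconstructing the identical derived allele, ``sequence``
    is that shared stretch read from the reference at the
    leftmost-normalized position, and ``ambiguity_interval`` is the
    inclusive range of equivalent ``bp5`` placements.
    """
    if not (bp5 < bp3):
        raise ValueError(f"deletion junction requires bp5 < bp3, got {bp5}, {bp3}")
    for pos in (bp5, bp3):
        if not locus.contains(pos):
            raise ValueError(
                f"coordinate {pos} outside locus [{locus.start}, {locus.end}]"
            )
    seq = locus.sequence
    i5 = locus.local(bp5)  # 0-based index of bp5
    i3 = locus.local(bp3)

    # Common suffix of the two flanks ending just before each join point.
    s = 0
    while i5 - s >= 0 and i3 - 1 - s >= 0 and seq[i5 - s] == seq[i3 - 1 - s]:
        s += 1
    # Common prefix of the two flanks starting at each join point.
    p = 0
    n = len(seq)
    while i5 + 1 + p < n and i3 + p < n and seq[i5 + 1 + p] == seq[i3 + p]:
        p += 1

    length = s + p
    bp5_left = bp5 - s
    mh_seq = seq[locus.local(bp5_left) + 1 : locus.local(bp5_left) + 1 + length] if length else ""
    return length, mh_seq, (bp5_left, bp5_left + length)


def leftmost_normalize(
    locus: ReferenceLocus, bp5: int, bp3: int, inserted_seq: str = ""
) -> tuple[int, int, str]:
    """Canonical (leftmost, minimal-insertion) form of a deletion junction.

    Without an insertion the junction slides left through the flank-shared
    stretch.  With an untemplated insertion the representation is first
    reduced: insertion bases identical to the adjoining reference flank are
    reassigned to the flank (trailing bases matching the base before
    ``bp3`` move into the 3' flank, then leading bases matching the base
    after ``bp5`` move into the 5' flank), after which an emptied insertion
    falls back to plain leftmost sliding.  Idempotent by construction.
    """
    ins = inserted_seq
    # Reassign insertion bases that duplicate reference flank bases.
    while ins and locus.contains(bp3 - 1) and ins[-1] == locus.base(bp3 - 1):
        ins = ins[:-1]
        bp3 -= 1
    while ins and locus.contains(bp5 + 1) and ins[0] == locus.base(bp5 + 1):
        ins = ins[1:]
        bp5 += 1
    if ins:
        return bp5, bp3, ins
    if bp5 < bp3:
        _len, _seq, (bp5_left, _hi) = compute_microhomology(locus, bp5, bp3)
        shift = bp5 - bp5_left
        return bp5 - shift, bp3 - shift, ""
    return bp5, bp3, ""


def normalize_duplication_junction(
    locus: ReferenceLocus, bp5: int, bp3: int, inserted_seq: str = ""
) -> tuple[int, int, str]:
    """Leftmost form of a tandem-duplication junction (``bp3 <= bp5``).

    The junction joins the end of the duplicated interval (``bp5``) back to
    its start (``bp3``); sliding moves both coordinates together, exactly as
    for deletions, so the same flank-comparison applies with the roles of
    the sequences swapped around the join.
    """
    ins = inserted_seq
    while ins and locus.contains(bp3 - 1) and ins[-1] == locus.base(bp3 - 1):
        ins = ins[:-1]
        bp3 -= 1
    while ins and locus.contains(bp5 + 1) and ins[0] == locus.base(bp5 + 1):
        ins = ins[1:]
        bp5 += 1
    if ins:
        return bp5, bp3, ins
    s = 0
    while (
        locus.contains(bp5 - s)
        and locus.contains(bp3 - 1 - s)
        and locus.base(bp5 - s) == locus.base(bp3 - 1 - s)
    ):
        s += 1
    return bp5 - s, bp3 - s, ""


def resolve_junction(
    locus: ReferenceLocus,
    bp5: int,
    bp3: int,
    inserted_seq: str = "",
    event_type: str = "deletion",
) -> Junction:
    """Build a leftmost-normalized :class:`Junction` from raw coordinates."""
    if event_type == "deletion":
        bp5n, bp3n, ins = leftmost_normalize(locus, bp5, bp3, inserted_seq)
        if ins:
            return Junction(bp5n, bp3n, 0, "", ins, (bp5n, bp5n))
        length, seq, interval = compute_microhomology(locus, bp5n, bp3n)
        return Junction(bp5n, bp3n, length, seq, "", interval)
    if event_type == "duplication":
        bp5n, bp3n, ins = normalize_duplication_junction(locus, bp5, bp3, inserted_seq)
        if ins:
            return Junction(bp5n, bp3n, 0, "", ins, (bp5n, bp5n))
        # Homology between the interval end and the bases before its start.
        s = 0
        while (
            locus.contains(bp5n + 1 + s)
            and locus.contains(bp3n + s)
            and locus.base(bp5n + 1 + s) == locus.base(bp3n + s)
        ):
            s += 1
        k = 0
        while (
            locus.contains(bp5n - k)
            and locus.contains(bp3n - 1 - k)
            and locus.base(bp5n - k) == locus.base(bp3n - 1 - k)
        ):
            k += 1
        length = s + k
        mh = locus.fetch(bp3n - k, bp3n - k + length - 1) if length else ""
        return Junction(bp5n, bp3n, length, mh, "", (bp5n - k, bp5n - k + length))
    raise ValueError(f"bad event_type {event_type!r}")


# ---------------------------------------------------------------------------
# Sizes, repeat overlap, mechanism


def deletion_size(start: int, end: int) -> int:
    """Event size in bp for a 1-based inclusive interval."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return end - start + 1


def overlap_repeats(
    coordinate: int, repeat_track: Sequence[RepeatElement]
) -> Optional[RepeatElement]:
    """The repeat element containing ``coordinate`` (endpoints inclusive).

    The track must be sorted by start coordinate; with non-overlapping
    elements at most one can contain the position.
    """
    starts = [r.start for r in repeat_track]
    i = bisect.bisect_right(starts, coordinate)
    # Walk left over elements starting at or before the coordinate.
    for j in range(i - 1, -1, -1):
        r = repeat_track[j]
        if r.contains(coordinate):
            return r
        if coordinate - r.start > 10000:  # far past any plausible element
            break
    return None


def classify_mechanism(
    junction: Junction,
    repeat5: Optional[RepeatElement],
    repeat3: Optional[RepeatElement],
    min_homology: int = 10,
    short_homology_cap: int = 5,
) -> str:
    """NAHR / NHEJ / unclassified for a resolved junction.

    NAHR requires microhomology of at least ``min_homology`` bp *and* both
    breakpoints inside repeats of the same superfamily in the same
    orientation.  Junctions with under ``short_homology_cap`` bp of homology
    (including untemplated-insertion junctions) are NHEJ whatever the repeat
    context.  Intermediate homology, or long homology without a qualifying
    repeat pair, stays unclassified.
    """
    mh = junction.microhomology_len
    if (
        mh >= min_homology
        and repeat5 is not None
        and repeat3 is not None
        and repeat5.family_group == repeat3.family_group
        and repeat5.strand == repeat3.strand
    ):
        return "NAHR"
    if mh < short_homology_cap:
        return "NHEJ"
    return "unclassified"


# ---------------------------------------------------------------------------
# Nomenclature


def _abbrev_second(first: int, second: int) -> str:
    """Journal-style abbreviation of the second coordinate of a pair
    (``47694485_86`` for 47694485_47694486) when only the last two digits
    differ."""
    a, b = str(first), str(second)
    if len(a) == len(b) and a[:-2] == b[:-2]:
        return b[-2:]
    return b


def format_deletion(start: int, end: int) -> tuple[str, str]:
    size = deletion_size(start, end)
    report = f"g.{start}-{end}del{size}"
    hgvs = f"g.{start}del" if start == end else f"g.{start}_{end}del"
    return report, hgvs


def format_duplication(
    start: int, end: int, inserted_seq: str = "", gene_id: str = MSH2_ENSEMBL_ID
) -> tuple[str, str]:
    """Tandem head-to-tail duplication of ``[start, end]`` with an optional
    untemplated insertion preceding the second copy at the junction."""
    ins_pos5, ins_pos3 = end, end + 1
    abbrev = _abbrev_second(ins_pos5, ins_pos3)
    dup_ref = f"{gene_id}:g.{start}_{end}"
    if inserted_seq:
        report = (
            f"g.[{ins_pos5}_{abbrev}ins{inserted_seq};"
            f"{ins_pos5}_{abbrev}ins{dup_ref}]"
        )
        hgvs = f"g.[{start}_{end}dup;{ins_pos5}_{ins_pos3}ins{inserted_seq}]"
    else:
        report = f"g.[{ins_pos5}_{abbrev}ins{dup_ref}]"
        hgvs = f"g.{start}_{end}dup"
    return report, hgvs


def format_nomenclature(call: RearrangementCall) -> tuple[str, str]:
    """(clinical-report style, HGVS style) designations for a resolved call."""
    if call.start <= 0 or call.end <= 0:
        raise UnresolvedBreakpointError(
            "breakpoints not sequence-resolved; report an MLPA-bounded "
            "designation such as 'c.212-?_366+?del' instead"
        )
    if call.event_type == "deletion":
        return format_deletion(call.start, call.end)
    ins = call.junction.inserted_seq if call.junction else ""
    return format_duplication(call.start, call.end, ins)


def mlpa_bounded_notation(c_start: int, c_end: int) -> str:
    """Coding-coordinate bounded designation for an event delimited only at
    exon resolution (MLPA), e.g. ``c.212-?_366+?del``."""
    return f"c.{c_start}-?_{c_end}+?del"


def iscn_string(start: int, end: int, copies: int, band: str = "2p21") -> str:
    """ISCN-style array description, e.g. ``arr 2p21 (47705272-47705637)x3``."""
    return f"arr {band} ({start}-{end})×{copies}"


# ---------------------------------------------------------------------------
# Repeat content summaries


def repeat_content(
    repeat_track: Sequence[RepeatElement], locus: ReferenceLocus
) -> tuple[float, dict[str, int]]:
    """(masked fraction of the locus, element counts per repeat class).

    Overlapping elements are unioned so each base counts once.
    """
    counts = {"SINE": 0, "LINE": 0, "LTR": 0, "DNA": 0}
    intervals = []
    for r in repeat_track:
        if r.start < locus.start or r.end > locus.end:
            raise ValueError(f"repeat {r.family} [{r.start},{r.end}] outside locus")
        counts[r.class_] += 1
        intervals.append((r.start, r.end))
    intervals.sort()
    masked = 0
    cur_s, cur_e = None, None
    for s, e in intervals:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                masked += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        masked += cur_e - cur_s + 1
    return masked / len(locus), counts


# ---------------------------------------------------------------------------
# Full annotation of a junction into a call


def annotate_call(
    locus: ReferenceLocus,
    repeat_track: Sequence[RepeatElement],
    bp5: int,
    bp3: int,
    inserted_seq: str = "",
    event_type: str = "deletion",
    min_homology: int = 10,
    short_homology_cap: int = 5,
    exon_regions: Optional[Sequence[tuple[int, int]]] = None,
    co_occurring_pathogenic: bool = False,
) -> RearrangementCall:
    """Resolve, classify and name one rearrangement.

    For deletions the event interval is the deleted segment
    ``[bp5+1, bp3-1]``; for duplications it is the duplicated interval
    ``[bp3, bp5]``.  Pathogenicity flagging is rule-based metadata only: an
    event overlapping annotated exons is flagged (gene-disrupting), an
    intronic event is not, and an intronic event co-occurring with a
    pathogenic event on the same allele is annotated as such.
    """
    junction = resolve_junction(locus, bp5, bp3, inserted_seq, event_type)
    if event_type == "deletion":
        start, end = junction.bp5 + 1, junction.bp3 - 1
    else:
        start, end = junction.bp3, junction.bp5
    r5 = overlap_repeats(junction.bp5, repeat_track)
    r3 = overlap_repeats(junction.bp3, repeat_track)
    mechanism = classify_mechanism(junction, r5, r3, min_homology, short_homology_cap)

    pathogenic = False
    rationale = "no exon annotation supplied"
    if exon_regions is not None:
        hit = [
            i + 1
            for i, (es, ee) in enumerate(exon_regions)
            if not (end < es or start > ee)
        ]
        if hit:
            pathogenic = True
            kind = "truncating/in-frame disruption" if event_type == "deletion" else "copy-gain disruption"
            rationale = f"overlaps exon(s) {hit}: {kind}"
        elif co_occurring_pathogenic:
            pathogenic = False
            rationale = "intronic; co-occurs with a pathogenic event on the same allele"
        else:
            pathogenic = False
            rationale = "intronic; no coding sequence affected"

    call = RearrangementCall(
        event_type=event_type,
        start=start,
        end=end,
        size=end - start + 1,
        mechanism=mechanism,
        repeat5=r5,
        repeat3=r3,
        junction=junction,
        pathogenic_flag=pathogenic,
        pathogenic_rationale=rationale,
    )
    call.nomenclature_report_style, call.nomenclature_hgvs = format_nomenclature(call)
    return call
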
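"""Split-read breakpoint detection: chimeric reads, clustering, consensus.

A read spanning a rearrangement junction matches two discrete regions of
the reference — a *chimeric* read.  The mapper anchors each read twice by
seed-and-extend: the maximal near-exact extension of the read prefix and,
independently, of the read suffix.  When the two anchors are collinear the
read is an ordinary (non-chimeric) match; when they land on reference loci
separated by more than ``min_sv_distance`` the read evidences a deletion
junction, and when the suffix anchor maps *upstream* of the prefix anchor
the read spans a tandem head-to-tail duplication junction.  Reads that
accumulate at the same two discrete regions are clustered into breakpoint
calls, and a majority-vote consensus of the junction sequence is
reconstructed around the join.

Breakpoints inside junction microhomology are inherently ambiguous: every
split position within the flank-shared stretch writes the same read.  Each
chimeric read is therefore reduced to the canonical *leftmost* junction
(computed against the reference, exactly as the annotator and the
simulator's truth records are normalized), and each cluster reports the
modal junction of its members, which makes read-level calls, truth and
annotation directly comparable.

Alignment details: anchoring uses an X-drop rule over substitutions only
(match +1, mismatch -3, drop 9) for tolerance to scattered sequencing
errors; it serves solely to identify the two reference diagonals.  The
split position itself then comes from an exhaustive scan of every junction
placement on those diagonals, minimizing total mismatches, with an
untemplated-gap decomposition accepted only at strictly lower cost (then
minimal gap, then leftmost) — necessary because the sequence around an
NAHR junction is flanked by near-identical repeat copies, where any
heuristic that walks along match runs mis-places the boundary.  Indel
errors are out of scope.  Anchors with multiple equally good placements (e.g. wholly inside
one of two near-identical repeat copies) are rejected with an ambiguity
flag, never silently assigned.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .junction_annotator import leftmost_normalize, normalize_duplication_junction
from .types import (
    BreakpointCluster,
    ReferenceLocus,
    SplitAlignment,
    SplitSegment,
    revcomp,
)

_XDROP = 9
_MATCH, _MISMATCH = 1, -3


def _extend_right(read: str, ref: str, read_i: int, ref_i: int) -> tuple[int, int]:
    """X-drop extension rightwards from (read_i, ref_i) inclusive.

    Returns ``(read_end_exclusive, mismatches)`` at the maximal-score point.
    """
    score = best_score = best_len = best_mm = mm = 0
    n = min(len(read) - read_i, len(ref) - ref_i)
    for k in range(n):
        if read[read_i + k] == ref[ref_i + k]:
            score += _MATCH
        else:
            score += _MISMATCH
            mm += 1
        if score > best_score:
            best_score, best_len, best_mm = score, k + 1, mm
        elif best_score - score > _XDROP:
            break
    return read_i + best_len, best_mm


def _extend_left(read: str, ref: str, read_i: int, ref_i: int) -> tuple[int, int]:
    """X-drop extension leftwards from (read_i, ref_i) exclusive; returns
    ``(read_start_inclusive, mismatches)`` at the maximal-score point."""
    score = best_score = best_len = best_mm = mm = 0
    n = min(read_i, ref_i)
    for k in range(1, n + 1):
        if read[read_i - k] == ref[ref_i - k]:
            score += _MATCH
        else:
            score += _MISMATCH
            mm += 1
        if score > best_score:
            best_score, best_len, best_mm = score, k, mm
        elif best_score - score > _XDROP:
            break
    return read_i - best_len, best_mm


def _diag_mismatch_profiles(
    seq: str, ref: str, d1: int, d2: int, lo: int, hi: int
) -> tuple[list[int], list[int]]:
    """Cumulative mismatch counts of the read against the two diagonals.

    ``pre[x]`` counts mismatches of ``seq[:x]`` against the prefix diagonal
    ``d1``; ``suf[x]`` counts mismatches of ``seq[x:]`` against the suffix
    diagonal ``d2``.  Only split positions in ``[lo, hi]`` are ever used,
    but the profiles are computed over the full read for simplicity.
    """
    L = len(seq)
    pre = [0] * (L + 1)
    for i in range(L):
        r = d1 + i
        pre[i + 1] = pre[i] + (1 if not (0 <= r < len(ref)) or seq[i] != ref[r] else 0)
    suf = [0] * (L + 1)
    for i in range(L - 1, -1, -1):
        r = d2 + i
        suf[i] = suf[i + 1] + (1 if not (0 <= r < len(ref)) or seq[i] != ref[r] else 0)
    return pre, suf


_MAX_UNTEMPLATED = 50  # longest junction insertion considered


def _best_split(
    seq: str, ref: str, d1: int, d2: int, lo: int, hi: int
) -> Optional[tuple[int, int, int, list[int], list[int]]]:
    """Optimal decomposition of a chimeric read across two diagonals.

    Scans every split position ``x`` in ``[lo, hi]`` (read prefix against
    diagonal ``d1``, read suffix against ``d2``) and every untemplated-gap
    decomposition ``(x5, x3)`` with gap up to ``_MAX_UNTEMPLATED`` bases,
    scoring by total mismatches.  A gapped decomposition is preferred only
    at *strictly* lower cost, then minimal gap, then leftmost position, so
    an error-free read over a clean junction always yields the clean split
    and an error-free read over an insertion junction always yields the
    minimal true insertion.  Returns ``(x5, x3, cost)`` with the insertion
    being ``seq[x5:x3]`` (empty for a clean split), or ``None`` when the
    window is empty.  The two mismatch profiles are returned for reuse.
    """
    if hi < lo:
        return None
    pre, suf = _diag_mismatch_profiles(seq, ref, d1, d2, lo, hi)
    best = None  # (cost, gap, x5)
    for g in range(0, _MAX_UNTEMPLATED + 1):
        for x5 in range(lo, hi - g + 1):
            c = pre[x5] + suf[x5 + g]
            cand = (c, g, x5)
            if best is None or cand < best:
                best = cand
        if best is not None and best[0] == 0 and best[1] <= g:
            break  # cannot improve on a zero-cost decomposition
    if best is None:
        return None
    cost, g, x5 = best
    return x5, x5 + g, cost, pre, suf


def _find_all(ref: str, seed: str, limit: int = 50) -> list[int]:
    hits, start = [], ref.find(seed)
    while start != -1 and len(hits) <= limit:
        hits.append(start)
        start = ref.find(seed, start + 1)
    return hits


def _anchor(
    read: str, ref: str, from_start: bool, min_anchor: int
) -> tuple[Optional[tuple[int, int, int, int]], bool]:
    """Best anchored extension of the read prefix or suffix.

    Returns ``((read_start, read_end, diag, mismatches), ambiguous)`` with
    read coordinates half-open 0-based and ``diag`` the 0-based reference
    position of read position 0 on the anchor's diagonal.  Several seed
    offsets are tried so a sequencing error inside one seed does not lose
    the anchor.
    """
    L, k = len(read), min_anchor
    offsets = (0, k, 2 * k) if from_start else (L - k, L - 2 * k, L - 3 * k)
    candidates: dict[int, tuple[int, int, int, int, int]] = {}
    for off in offsets:
        if off < 0 or off + k > L:
            continue
        for hit in _find_all(ref, read[off : off + k]):
            diag = hit - off
            if diag in candidates:
                continue
            r_end, mm_r = _extend_right(read, ref, off, hit)
            r_start, mm_l = _extend_left(read, ref, off, hit)
            mm = mm_l + mm_r
            score = (r_end - r_start - mm) * _MATCH + mm * _MISMATCH
            candidates[diag] = (score, r_start, r_end, diag, mm)
    # Keep only placements that reach (nearly) the anchor's read end; a few
    # leading/trailing error bases are tolerated.
    valid = [
        c for c in candidates.values()
        if (c[1] <= 3 if from_start else c[2] >= L - 3) and c[2] - c[1] >= min_anchor
    ]
    if not valid:
        return None, False
    valid.sort(reverse=True)
    best = valid[0]
    if len(valid) > 1 and valid[1][0] == best[0]:
        return None, True
    _score, r_start, r_end, diag, mm = best
    return (r_start, r_end, diag, mm), False


def split_align(
    read: tuple[str, str] | str,
    locus: ReferenceLocus,
    min_anchor: int = 20,
    max_mismatch_rate: float = 0.05,
    min_sv_distance: int = 100,
) -> Optional[SplitAlignment]:
    """Align one read, splitting it across a junction when chimeric.

    ``read`` is ``(read_id, sequence)`` (or a bare sequence).  Both
    orientations are tried; reads fully contained in the reference are
    returned non-chimeric; reads with no adequate anchor return ``None``;
    anchors with equally good alternative placements come back with
    ``ambiguous=True`` and are never assigned.
    """
    read_id, seq = read if isinstance(read, tuple) else ("read", read)
    seq = seq.upper()
    if len(seq) < 2 * min_anchor:
        raise ValueError(f"read length {len(seq)} < 2*min_anchor ({2 * min_anchor})")

    best: Optional[SplitAlignment] = None
    best_cov = -1
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        aln = _split_align_oriented(
            read_id, oriented, strand, locus, min_anchor,
            max_mismatch_rate, min_sv_distance,
        )
        if aln is None:
            continue
        cov = sum(
            s.read_end - s.read_start for s in (aln.seg1, aln.seg2) if s is not None
        )
        if aln.ambiguous:
            cov = 0
        if cov > best_cov:
            best, best_cov = aln, cov
    return best


def _split_align_oriented(
    read_id: str,
    seq: str,
    strand: str,
    locus: ReferenceLocus,
    min_anchor: int,
    max_mismatch_rate: float,
    min_sv_distance: int,
) -> Optional[SplitAlignment]:
    ref = locus.sequence
    L = len(seq)
    pos = ref.find(seq)
    if pos != -1 and ref.find(seq, pos + 1) == -1:
        seg = SplitSegment(0, L, locus.offset + pos, locus.offset + pos + L - 1, strand, 0)
        return SplitAlignment(read_id, seg, None, is_chimeric=False)

    prefix, amb_p = _anchor(seq, ref, True, min_anchor)
    suffix, amb_s = _anchor(seq, ref, False, min_anchor)
    if prefix is None or suffix is None:
        if amb_p or amb_s:
            return SplitAlignment(read_id, None, None, is_chimeric=False, ambiguous=True)
        got = prefix if prefix is not None else suffix
        if got is None:
            return None
        r_start, r_end, diag, mm = got
        if mm > max_mismatch_rate * (r_end - r_start) + 1:
            return None
        seg = SplitSegment(r_start, r_end, locus.offset + diag + r_start,
                           locus.offset + diag + r_end - 1, strand, mm)
        return SplitAlignment(read_id, seg, None, is_chimeric=False)

    p_start, p_end, p_diag, p_mm = prefix
    s_start, s_end, s_diag, s_mm = suffix
    if p_diag == s_diag:
        mm = sum(1 for i in range(L) if 0 <= p_diag + i < len(ref) and seq[i] != ref[p_diag + i])
        if mm > max_mismatch_rate * L + 1:
            return None
        seg = SplitSegment(0, L, locus.offset + p_diag, locus.offset + p_diag + L - 1,
                           strand, mm)
        return SplitAlignment(read_id, seg, None, is_chimeric=False)

    # Optimal split over the two diagonals, keeping at least min_anchor
    # bases on each side of the junction.
    lo = max(min_anchor, 1 - p_diag)
    hi = min(L - min_anchor, len(ref) - s_diag - 1)
    found = _best_split(seq, ref, p_diag, s_diag, lo, hi)
    if found is None:
        return None
    x5, x3, _cost, pre, suf = found
    if pre[x5] > max_mismatch_rate * x5 + 1:
        return None
    if suf[x3] > max_mismatch_rate * (L - x3) + 1:
        return None
    bp5_raw = locus.offset + p_diag + x5 - 1
    bp3_raw = locus.offset + s_diag + x3
    ins_raw = seq[x5:x3]

    if not (locus.contains(bp5_raw) and locus.contains(bp3_raw)):
        return None
    if bp3_raw > bp5_raw:
        if bp3_raw - bp5_raw - 1 <= min_sv_distance:
            return None  # small gap: not called as a rearrangement
        orientation = "del"
        bp5, bp3, ins = leftmost_normalize(locus, bp5_raw, bp3_raw, ins_raw)
    else:
        if bp5_raw - bp3_raw + 1 <= min_sv_distance:
            return None
        orientation = "dup"
        bp5, bp3, ins = normalize_duplication_junction(locus, bp5_raw, bp3_raw, ins_raw)

    split5 = bp5 - (locus.offset + p_diag) + 1  # read index after last 5' base
    split3 = bp3 - (locus.offset + s_diag)
    seg1 = SplitSegment(p_start, max(p_start, split5),
                        locus.offset + p_diag + p_start, bp5, strand, p_mm)
    seg2 = SplitSegment(min(split3, s_end), s_end,
                        bp3, locus.offset + s_diag + s_end - 1, strand, s_mm)
    return SplitAlignment(
        read_id, seg1, seg2, is_chimeric=True, orientation=orientation,
        bp5=bp5, bp3=bp3, inserted_seq=ins,
    )


# ---------------------------------------------------------------------------
# Clustering


def cluster_chimeras(
    alignments: Sequence[SplitAlignment],
    tol: int = 10,
    min_support: int = 3,
    satellite_window: int = 150,
) -> list[BreakpointCluster]:
    """Single-linkage clustering of chimeric reads by junction coordinates.

    Two chimeric reads of the same orientation are linked when both their
    ``bp5`` and ``bp3`` differ by at most ``tol``; clusters with fewer
    than ``min_support`` reads are discarded.  Each cluster reports the
    modal leftmost ``(bp5, bp3, insertion)`` triple of its members.  Every
    read belongs to at most one cluster.

    Satellite absorption: a read carrying a sequencing error right at the
    junction can prefer a slightly displaced split (the minimal-mismatch
    decomposition excises the error as a spurious untemplated gap), so a
    junction accumulates a halo of near-miss placements around the exact
    one.  Groups of the same orientation whose median coordinates fall
    within ``satellite_window`` bp of a stronger group are therefore
    merged into it before support filtering — they are not two "discrete
    regions" but one junction seen twice — which makes ``satellite_window``
    the minimum resolvable distance between two same-orientation junctions.
    """
    chims = [a for a in alignments if a.is_chimeric and not a.ambiguous]
    clusters: list[BreakpointCluster] = []
    for orientation in ("del", "dup"):
        pts = sorted(
            (a for a in chims if a.orientation == orientation),
            key=lambda a: (a.bp5, a.bp3),
        )
        if not pts:
            continue
        parent = list(range(len(pts)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if pts[j].bp5 - pts[i].bp5 > tol:
                    break
                if abs(pts[j].bp3 - pts[i].bp3) <= tol:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
        groups: dict[int, list[SplitAlignment]] = {}
        for i, a in enumerate(pts):
            groups.setdefault(find(i), []).append(a)
        member_groups = sorted(groups.values(), key=len, reverse=True)
        kept: list[list[SplitAlignment]] = []
        for members in member_groups:
            rep5 = int(np.median([a.bp5 for a in members]))
            rep3 = int(np.median([a.bp3 for a in members]))
            host = next(
                (
                    k for k in kept
                    if abs(int(np.median([a.bp5 for a in k])) - rep5) <= satellite_window
                    and abs(int(np.median([a.bp3 for a in k])) - rep3) <= satellite_window
                ),
                None,
            )
            if host is not None:
                host.extend(members)
            else:
                kept.append(members)
        for members in kept:
            if len(members) < min_support:
                continue
            bp5, bp3, ins = Counter(
                (a.bp5, a.bp3, a.inserted_seq) for a in members
            ).most_common(1)[0][0]
            clusters.append(
                BreakpointCluster(
                    region5=(min(a.bp5 for a in members), max(a.bp5 for a in members)),
                    region3=(min(a.bp3 for a in members), max(a.bp3 for a in members)),
                    support=len(members),
                    bp5=bp5,
                    bp3=bp3,
                    orientation=orientation,
                    inserted_seq=ins,
                    read_ids=tuple(a.read_id for a in members),
                )
            )
    clusters.sort(key=lambda c: (c.bp5, c.bp3))
    return clusters


# ---------------------------------------------------------------------------
# Junction consensus


def reconstruct_junction(
    locus: ReferenceLocus,
    cluster: BreakpointCluster,
    alignments: Sequence[SplitAlignment],
    reads: Sequence[tuple[str, str]],
    flank: int = 150,
) -> str:
    """Majority-vote consensus of the junction sequence, ±``flank`` bp.

    The template is the reference 5' flank up to ``bp5``, the cluster's
    untemplated insertion, then the reference from ``bp3`` on.  Member
    reads vote column-wise at the offsets implied by their split
    alignments (anchored parts; insertion columns are voted by reads whose
    own gap length matches).  Uncovered columns fall back to the template.
    """
    read_seq = dict(reads)
    wanted = set(cluster.read_ids)
    members = [a for a in alignments if a.read_id in wanted and a.is_chimeric]
    bp5, bp3, ins = cluster.bp5, cluster.bp3, cluster.inserted_seq

    left = locus.fetch(max(locus.start, bp5 - flank + 1), bp5)
    right = locus.fetch(bp3, min(locus.end, bp3 + flank - 1))
    template = left + ins + right
    n_ins = len(ins)
    j0 = len(left)  # template index of the first insertion/right-flank base

    votes: list[Counter] = [Counter() for _ in range(len(template))]
    for aln in members:
        seq = read_seq.get(aln.read_id)
        if seq is None:
            continue
        if aln.seg1 is not None and aln.seg1.strand == "-":
            seq = revcomp(seq)
        s1, s2 = aln.seg1, aln.seg2
        if s1 is not None:
            diag = s1.ref_start - s1.read_start
            for p in range(s1.read_start, s1.read_end):
                t = (diag + p) - bp5 + j0 - 1
                if 0 <= t < j0:
                    votes[t][seq[p]] += 1
        if s2 is not None:
            diag = s2.ref_start - s2.read_start
            for p in range(s2.read_start, s2.read_end):
                t = (diag + p) - bp3 + j0 + n_ins
                if j0 + n_ins <= t < len(template):
                    votes[t][seq[p]] += 1
        if n_ins and len(aln.inserted_seq) == n_ins and s1 is not None:
            gap_start = s1.read_end
            for k in range(n_ins):
                p = gap_start + k
                if 0 <= p < len(seq):
                    votes[j0 + k][seq[p]] += 1

    return "".join(
        c.most_common(1)[0][0] if c else template[t] for t, c in enumerate(votes)
    )


# ---------------------------------------------------------------------------
# Reporting


def clusters_to_frame(clusters: Sequence[BreakpointCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orientation": c.orientation,
                "bp5": c.bp5,
                "bp3": c.bp3,
                "region5_start": c.region5[0],
                "region5_end": c.region5[1],
                "region3_start": c.region3[0],
                "region3_end": c.region3[1],
                "support": c.support,
                "inserted_seq": c.inserted_seq,
                "junction_consensus": c.junction_consensus,
            }
            for c in clusters
        ]
    )


def alignments_to_sam_text(
    alignments: Sequence[SplitAlignment], locus: ReferenceLocus
) -> str:
    """SAM-like text dump of split alignments (diagnostic output)."""
    lines = [f"@SQ\tSN:{locus.name}\tLN:{len(locus)}"]
    for a in alignments:
        if a.seg1 is None:
            continue
        for seg, tag in ((a.seg1, "P"), (a.seg2, "S")):
            if seg is None:
                continue
            flag = 0 if seg.strand == "+" else 16
            cigar = f"{seg.read_end - seg.read_start}M"
            lines.append(
                f"{a.read_id}\t{flag}\t{locus.name}\t{seg.ref_start}\t60\t{cigar}"
                f"\t*\t0\t0\t*\t*\tXT:A:{tag}\tXC:i:{int(a.is_chimeric)}"
            )
    return "\n".join(lines) + "\n"
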
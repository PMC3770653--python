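"""End-to-end convenience: reads -> split alignments -> clusters -> calls.

Thin orchestration over :mod:`breakpoint_mapper` and
:mod:`junction_annotator`; every step is available separately.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .breakpoint_mapper import cluster_chimeras, reconstruct_junction, split_align
from .junction_annotator import annotate_call
from .types import BreakpointCluster, RearrangementCall, ReferenceLocus, RepeatElement


def detect_rearrangements(
    locus: ReferenceLocus,
    repeat_track: Sequence[RepeatElement],
    reads: Sequence[tuple[str, str]],
    min_anchor: int = 20,
    tol: int = 10,
    min_support: int = 3,
    min_homology: int = 10,
    exon_regions: Optional[Sequence[tuple[int, int]]] = None,
    with_consensus: bool = True,
) -> tuple[list[RearrangementCall], list[BreakpointCluster]]:
    """Run the split-read pipeline and annotate every breakpoint cluster.

    Returns ``(calls, clusters)`` in genomic order; ``calls[i]`` annotates
    ``clusters[i]``.
    """
    alignments = [
        a for a in (split_align(r, locus, min_anchor=min_anchor) for r in reads)
        if a is not None
    ]
    clusters = cluster_chimeras(alignments, tol=tol, min_support=min_support)
    calls = []
    for cluster in clusters:
        if with_consensus:
            cluster.junction_consensus = reconstruct_junction(
                locus, cluster, alignments, reads
            )
        event_type = "deletion" if cluster.orientation == "del" else "duplication"
        calls.append(
            annotate_call(
                locus,
                repeat_track,
                cluster.bp5,
                cluster.bp3,
                cluster.inserted_seq,
                event_type,
                min_homology=min_homology,
                exon_regions=exon_regions,
            )
        )
    return calls, clusters
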
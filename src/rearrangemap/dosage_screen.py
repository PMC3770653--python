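"""Exon-dosage calling from MLPA peak tables and CNV segmentation from aCGH.

MLPA dosage quotients follow the standard two-step normalization: each
probe's peak area is divided by the sample's total area over the kit's
reference probes (intrasample normalization), then by the median of that
quantity across the batch (intersample normalization).  The batch median
makes the reference robust to one aberrant sample but collapses — a known
screening blind spot — when most of the batch carries the same aberration.
A sample is called aberrant for an exon when its dosage quotient falls
below ``low`` (deletion, expectation 0.5 at CN=1) or above ``high``
(duplication, expectation 1.5 at CN=3) and the call is reproduced in a
second independent reaction.

aCGH segmentation is a deliberately simple threshold-and-merge procedure:
probes whose |log2 ratio| exceeds ``z_threshold`` robust SDs of the flat
background are merged into consecutive same-sign runs, and runs shorter
than the applicable consecutive-probe minimum (10 inside densely covered
gene regions, 5 elsewhere) are discarded.
"""

from __future__ import annotations

import re
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import CnvSegment, DosageProfile, ExonCall

# ---------------------------------------------------------------------------
# MLPA normalization


def normalize_mlpa(
    sample_peaks: Mapping[str, float],
    batch_peaks: Mapping[str, Mapping[str, float]],
    probe_exon: Mapping[str, str],
    reference_probes: Optional[Sequence[str]] = None,
    sample_id: str = "sample",
    reaction_id: int = 1,
) -> DosageProfile:
    """Dosage quotients for one sample against its batch.

    ``batch_peaks`` maps sample id -> probe -> peak area for all samples of
    the same experiment (at least 3).  ``reference_probes`` names the kit's
    diploid normalization probes used for the intrasample total; when
    omitted, all probes are used (adequate for large probe sets, exact only
    when the aberrant fraction of total signal is negligible).
    """
    if len(batch_peaks) < 3:
        raise ValueError("batch must contain at least 3 samples")
    probes = list(sample_peaks)
    for sid, peaks in batch_peaks.items():
        if set(peaks) != set(probes):
            raise ValueError(f"sample {sid} does not share the batch probe set")
    norm_set = list(reference_probes) if reference_probes else probes

    def rel(peaks: Mapping[str, float]) -> dict[str, float]:
        total = sum(peaks[p] for p in norm_set)
        if total <= 0:
            raise ValueError("non-positive normalization total")
        return {p: peaks[p] / total for p in probes}

    sample_rel = rel(sample_peaks)
    batch_rel = {sid: rel(peaks) for sid, peaks in batch_peaks.items()}
    ratios: dict[str, tuple[str, float]] = {}
    for p in probes:
        ref = float(np.median([batch_rel[sid][p] for sid in batch_rel]))
        if ref <= 0:
            raise ValueError(f"probe {p} has zero area across the batch")
        ratios[p] = (probe_exon.get(p, p), sample_rel[p] / ref)
    return DosageProfile(sample_id=sample_id, ratios=ratios, reaction_id=reaction_id)


def normalize_mlpa_table(
    table: pd.DataFrame,
    sample_id: str,
    use_reference_probes: bool = True,
) -> tuple[DosageProfile, DosageProfile]:
    """Normalize both reactions of ``sample_id`` from a long-form peak table
    (columns sample_id, reaction, probe, exon, peak_area[, is_reference])."""
    if "is_reference" not in table.columns:
        table = table.assign(is_reference=False)
    profiles = []
    for reaction in (1, 2):
        sub = table[table["reaction"] == reaction]
        if sub.empty:
            raise ValueError(f"reaction {reaction} missing from the table")
        probe_exon = dict(zip(sub["probe"], sub["exon"]))
        batch = {
            sid: dict(zip(g["probe"], g["peak_area"]))
            for sid, g in sub.groupby("sample_id")
        }
        if sample_id not in batch:
            raise ValueError(f"sample {sample_id} not in table")
        refs = None
        if use_reference_probes:
            ref_probes = sub.loc[sub["is_reference"], "probe"].unique().tolist()
            refs = ref_probes or None
        profiles.append(
            normalize_mlpa(
                batch[sample_id], batch, probe_exon,
                reference_probes=refs, sample_id=sample_id, reaction_id=reaction,
            )
        )
    return profiles[0], profiles[1]


# ---------------------------------------------------------------------------
# Dosage calling


def _state(ratio: float, low: float, high: float) -> str:
    # Strict inequalities: exact boundary values call normal.
    if ratio < low:
        return "deletion"
    if ratio > high:
        return "duplication"
    return "normal"


def call_dosage(
    profile_r1: DosageProfile,
    profile_r2: DosageProfile,
    low: float = 0.7,
    high: float = 1.2,
    reference_exon_prefix: str = "ref",
) -> list[ExonCall]:
    """Per-exon calls requiring confirmation in both independent reactions.

    An exon is reported aberrant only when both reactions agree on the same
    non-normal state; a threshold straddle (aberrant in one reaction only)
    is reported normal with ``discordant=True``.  Exons missing from one
    reaction are reported unconfirmed with a warning.  Reference/control
    probes (exon labels starting with ``reference_exon_prefix``) are not
    called.
    """
    r1, r2 = profile_r1.exon_ratios(), profile_r2.exon_ratios()
    calls = []
    for exon in r1:
        if exon.startswith(reference_exon_prefix):
            continue
        if exon not in r2:
            warnings.warn(f"exon {exon} missing from reaction 2; call unconfirmed")
            s1 = _state(r1[exon], low, high)
            calls.append(
                ExonCall(exon, s1, r1[exon], float("nan"),
                         confirmed=False, discordant=True)
            )
            continue
        s1, s2 = _state(r1[exon], low, high), _state(r2[exon], low, high)
        if s1 == s2 and s1 != "normal":
            calls.append(ExonCall(exon, s1, r1[exon], r2[exon], confirmed=True))
        elif s1 == s2:
            calls.append(ExonCall(exon, "normal", r1[exon], r2[exon], confirmed=False))
        else:
            calls.append(
                ExonCall(exon, "normal", r1[exon], r2[exon],
                         confirmed=False, discordant=True)
            )
    return calls


def _exon_number(label: str) -> Optional[int]:
    m = re.fullmatch(r"E?(\d+)", label)
    return int(m.group(1)) if m else None


def segment_exon_calls(
    calls: Sequence[ExonCall],
    exon_order: Optional[Sequence[str]] = None,
) -> list[tuple[str, str, str, str]]:
    """Maximal runs of confirmed same-state exons.

    Returns ``(state, first_exon, last_exon, label)`` tuples in exon order;
    labels follow the clinical shorthand ``E7 del`` / ``E11-16 del``.
    Singleton runs are allowed.
    """
    by_exon = {c.exon: c for c in calls}
    order = list(exon_order) if exon_order is not None else [c.exon for c in calls]
    runs: list[tuple[str, str, str, str]] = []
    cur_state, cur_run = None, []

    def flush() -> None:
        nonlocal cur_state, cur_run
        if cur_state and cur_run:
            first, last = cur_run[0], cur_run[-1]
            short = {"deletion": "del", "duplication": "dup"}[cur_state]
            n1, n2 = _exon_number(first), _exon_number(last)
            if first == last:
                label = f"{first} {short}"
            elif n1 is not None and n2 is not None:
                label = f"E{n1}-{n2} {short}"
            else:
                label = f"{first}-{last} {short}"
            runs.append((cur_state, first, last, label))
        cur_state, cur_run = None, []

    for exon in order:
        call = by_exon.get(exon)
        state = call.state if call is not None and call.confirmed else "normal"
        if state == "normal":
            flush()
        elif state == cur_state:
            cur_run.append(exon)
        else:
            flush()
            cur_state, cur_run = state, [exon]
    flush()
    return runs


# ---------------------------------------------------------------------------
# aCGH segmentation


def segment_cgh(
    probes: pd.DataFrame,
    gene_regions: Sequence[tuple[int, int]] = (),
    z_threshold: float = 2.5,
    min_probes_gene: int = 10,
    min_probes_genome: int = 5,
    max_bridge: int = 1,
) -> list[CnvSegment]:
    """Threshold-and-merge CNV segmentation with consecutive-probe filters.

    ``probes`` needs columns ``position`` (sorted ascending) and
    ``log2_ratio``.  The flat-background scatter is estimated robustly
    (1.4826·MAD about the median); probes with |log2| above
    ``z_threshold``·SD are flagged and consecutive flagged probes of the
    same sign merged into runs, a run tolerating up to ``max_bridge``
    consecutive sub-threshold probes in its interior (a single noisy
    dropout must not split a real aberration).  Segments whose span
    overlaps a densely covered gene region must contain at least
    ``min_probes_gene`` probes; elsewhere ``min_probes_genome`` apply; the
    count includes bridged probes.  Segment coordinates are the first and
    last *flagged* probe positions.
    """
    pos = probes["position"].to_numpy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("probes must be sorted by coordinate")
    x = probes["log2_ratio"].to_numpy(dtype=float)
    med = np.median(x)
    sd = 1.4826 * np.median(np.abs(x - med))
    cut = max(z_threshold * sd, 1e-9)
    flagged = np.abs(x) > cut

    segments: list[CnvSegment] = []
    i, n = 0, len(x)
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        sign = np.sign(x[i])
        j = i
        while j + 1 < n:
            # next flagged same-sign probe within bridging distance?
            k = j + 1
            while k < n and k - j <= max_bridge + 1 and not (
                flagged[k] and np.sign(x[k]) == sign
            ):
                k += 1
            if k < n and k - j <= max_bridge + 1 and flagged[k] and np.sign(x[k]) == sign:
                j = k
            else:
                break
        n_probes = j - i + 1
        start, end = int(pos[i]), int(pos[j])
        in_gene = any(not (end < gs or start > ge) for gs, ge in gene_regions)
        minimum = min_probes_gene if in_gene else min_probes_genome
        if n_probes >= minimum:
            segments.append(
                CnvSegment(
                    start=start,
                    end=end,
                    n_probes=n_probes,
                    mean_log2=float(np.mean(x[i : j + 1])),
                    state="gain" if sign > 0 else "loss",
                )
            )
        i = j + 1
    return segments
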
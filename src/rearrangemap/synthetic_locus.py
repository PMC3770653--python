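"""Synthetic data: repeat-dense loci, rearranged alleles, reads, assay tables.

Every downstream stage of the pipeline (dosage screening, split-read
breakpoint mapping, junction annotation, cohort statistics) is exercised
against data generated here, with exact ground truth carried alongside:

* :func:`generate_reference` builds a random locus seeded with ~300 bp
  Alu-like elements (a fixed consensus, per-copy divergence, random strand)
  at exactly annotated positions, emulating the repeat density of
  rearrangement-prone disease loci.
* :func:`plant_nahr_deletion`, :func:`plant_nhej_deletion` and
  :func:`plant_tandem_duplication` derive a rearranged allele and a
  leftmost-normalized :class:`~rearrangemap.types.TruthRecord`.  NAHR
  junctions are placed inside a stretch forced identical between two
  same-orientation repeats (copy-paste before joining), so the planted
  microhomology is exact by construction; NHEJ junctions are blunt or carry
  a short untemplated insertion with flanks verified to share < 5 bp.
* :func:`simulate_reads` draws uniform-start reads with independent
  per-base substitution errors (no indels — a deliberate simplification
  relative to real pyrosequencing homopolymer errors).
* :func:`simulate_mlpa` / :func:`simulate_cgh` / :func:`simulate_cohort`
  produce the tabular inputs of the screening and statistics modules, with
  lognormal (MLPA) and Gaussian (aCGH) noise and Bernoulli tumor
  indicators respectively.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .junction_annotator import (
    compute_microhomology,
    leftmost_normalize,
    normalize_duplication_junction,
)
from .types import ReferenceLocus, RepeatElement, TruthRecord, revcomp

# A fixed ~300 bp Alu-like consensus (AluY-style SINE body plus A-tail),
# embedded as a constant so repeat planting needs no downloads.
ALU_CONSENSUS = (
    "GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGATCACGAGGT"
    "CAGGAGATCGAGACCATCCCGGCTAAAACGGTGAAACCCCGTCTCTACTAAAAATACAAAAAATTAGCC"
    "GGGCGTGGTGGCGGGCGCCTGTAGTCCCAGCTACTCGGGAGGCTGAGGCAGGAGAATGGCGTGAACCCG"
    "GGAGGCGGAGCTTGCAGTGAGCCGAGATCGCGCCACTGCACTCCAGCCTGGGCGACAGAGCGAGACTCC"
    "GTCTCAAAAAAA"
)
ALU_CONSENSUS = ALU_CONSENSUS + "A" * (300 - len(ALU_CONSENSUS))

ALU_FAMILIES = ("AluY", "AluSx", "AluSp", "AluJb", "AluSz")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``divergence``."""
    if divergence <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < divergence)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _other_base(base: str, rng: Optional[np.random.Generator] = None) -> str:
    cycle = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}
    return cycle[base]


# ---------------------------------------------------------------------------
# Reference generation


def generate_reference(
    length: int,
    n_repeats: int,
    repeat_divergence: float,
    seed: int,
    offset: int = 1,
    name: str = "synthetic_locus",
) -> tuple[ReferenceLocus, list[RepeatElement]]:
    """Random locus with ``n_repeats`` non-overlapping Alu-like elements.

    Each element is a copy of :data:`ALU_CONSENSUS` with per-base
    substitution probability ``repeat_divergence``, random subfamily label
    and random strand; annotation coordinates are exact.  Raises when the
    requested repeats cannot be placed without overlap.
    """
    if length < 2000:
        raise ValueError("locus length must be >= 2000 bp")
    if not (0.0 <= repeat_divergence <= 0.3):
        raise ValueError("repeat_divergence must be in [0, 0.3]")
    rep_len = len(ALU_CONSENSUS)
    if n_repeats * rep_len > length:
        raise ValueError(
            f"cannot place {n_repeats} non-overlapping {rep_len} bp repeats "
            f"in a {length} bp locus (limit: {length // rep_len})"
        )
    rng = np.random.default_rng(seed)
    background = rng.choice(_BASES, size=length).tobytes().decode()
    seq = list(background)

    placed: list[tuple[int, int]] = []  # 0-based [start, end) spans
    track: list[RepeatElement] = []
    tries = 0
    while len(placed) < n_repeats:
        tries += 1
        if tries > 200 * max(n_repeats, 1):
            raise ValueError(
                f"could not place {n_repeats} non-overlapping repeats in "
                f"{length} bp after {tries} attempts (locus too crowded)"
            )
        s = int(rng.integers(0, length - rep_len + 1))
        if any(s < e0 and s + rep_len > s0 for s0, e0 in placed):
            continue
        placed.append((s, s + rep_len))
        family = str(rng.choice(ALU_FAMILIES))
        strand = "+" if rng.random() < 0.5 else "-"
        copy = _mutate(ALU_CONSENSUS, repeat_divergence, rng)
        if strand == "-":
            copy = revcomp(copy)
        seq[s : s + rep_len] = copy
        track.append(
            RepeatElement(
                family=family,
                start=offset + s,
                end=offset + s + rep_len - 1,
                strand=strand,
                class_="SINE",
            )
        )
    track.sort(key=lambda r: r.start)
    locus = ReferenceLocus(name, offset, "".join(seq))
    return locus, track


# ---------------------------------------------------------------------------
# Planting rearrangements


def derive_allele(locus: ReferenceLocus, truth: TruthRecord) -> str:
    """Reconstruct the rearranged allele from locus + truth record.

    Works for both deletions (``bp5 < bp3``) and tandem duplications
    (``bp3 <= bp5``): the allele is the 5' flank up to ``bp5``, the
    untemplated insertion, then the sequence from ``bp3`` onwards.
    """
    return (
        locus.fetch(locus.start, truth.bp5)
        + truth.inserted_seq
        + locus.fetch(truth.bp3, locus.end)
    )


def plant_nahr_deletion(
    locus: ReferenceLocus,
    repeat5: RepeatElement,
    repeat3: RepeatElement,
    microhomology: int,
) -> tuple[str, TruthRecord]:
    """Deletion through two same-orientation repeats with exact planted
    microhomology.

    A stretch of ``microhomology`` bases at the same internal offset of the
    two repeats is forced identical by copying it from the 5' element onto
    the 3' element (recombining repeats are near-identical there in real
    loci); the bases flanking the stretch are forced to differ so the
    planted length is exact.  All edits fall in the deleted interval or the
    reference only, so the derived allele equals 5'-flank + 3'-flank.
    Modifies ``locus.sequence`` in place; the truth record is
    leftmost-normalized against the edited reference.
    """
    if repeat5.start > repeat3.start:
        repeat5, repeat3 = repeat3, repeat5
    if repeat5.strand != repeat3.strand:
        raise ValueError(
            "NAHR requires two repeats in the same orientation; the "
            f"requested pair is {repeat5.strand}/{repeat3.strand}"
        )
    if repeat5.family_group != repeat3.family_group:
        raise ValueError(
            "NAHR requires repeats of the same superfamily; got "
            f"{repeat5.family} and {repeat3.family}"
        )
    if microhomology < 1:
        raise ValueError("planted microhomology must be >= 1 for NAHR")
    span = min(len(repeat5), len(repeat3))
    if microhomology > span - 2:
        raise ValueError(
            f"microhomology {microhomology} exceeds usable repeat span {span - 2}"
        )
    o = (span - microhomology) // 2
    a = repeat5.start + o  # genomic start of the stretch in the 5' element
    b = repeat3.start + o  # ... and in the 3' element
    m = microhomology

    seq = list(locus.sequence)
    ia, ib = locus.local(a), locus.local(b)
    seq[ib : ib + m] = seq[ia : ia + m]
    # Force mismatches at both stretch boundaries so recovery is exact.
    # Edited positions lie inside the deleted interval [a, b-1], leaving the
    # derived allele untouched.
    if seq[ia - 1] == seq[ib - 1]:
        seq[ib - 1] = _other_base(seq[ia - 1])
    if seq[ia + m] == seq[ib + m]:
        seq[ia + m] = _other_base(seq[ib + m])
    locus.sequence = "".join(seq)

    bp5, bp3 = a - 1, b
    got, _mh_seq, _iv = compute_microhomology(locus, bp5, bp3)
    assert got == m, f"planted {m} bp of homology but reference carries {got}"
    truth = TruthRecord(
        event_type="deletion",
        bp5=bp5,
        bp3=bp3,
        planted_microhomology=m,
        inserted_seq="",
        mechanism_label="NAHR",
    )
    return derive_allele(locus, truth), truth


def plant_nhej_deletion(
    locus: ReferenceLocus,
    bp5: int,
    bp3: int,
    inserted_seq: str = "",
) -> tuple[str, TruthRecord]:
    """Blunt or short-insertion deletion junction (end-joining style).

    ``bp5``/``bp3`` are the last retained base before and the first retained
    base after the join.  The junction flanks must share fewer than 5 bp of
    identity; an insertion must not begin or end with the adjoining
    reference base (otherwise the representation would be reducible and the
    planted record ambiguous) — violations raise, callers resample.
    """
    if not (locus.contains(bp5) and locus.contains(bp3)) or not bp5 < bp3:
        raise ValueError("need locus-internal coordinates with bp5 < bp3")
    if inserted_seq:
        if inserted_seq[-1] == locus.base(bp3 - 1) or inserted_seq[0] == locus.base(bp5 + 1):
            raise ValueError(
                "insertion shares its boundary base with the reference flank; "
                "junction representation would be ambiguous — pick another "
                "insertion or position"
            )
        bp5n, bp3n, ins = bp5, bp3, inserted_seq
    else:
        mh, _seq, _iv = compute_microhomology(locus, bp5, bp3)
        if mh >= 5:
            raise ValueError(
                f"junction flanks share {mh} bp of identity; end-joining "
                "junctions require < 5 bp — pick other breakpoints"
            )
        bp5n, bp3n, ins = leftmost_normalize(locus, bp5, bp3)
    truth = TruthRecord(
        event_type="deletion",
        bp5=bp5n,
        bp3=bp3n,
        planted_microhomology=0,
        inserted_seq=ins,
        mechanism_label="NHEJ",
    )
    return derive_allele(locus, truth), truth


def plant_tandem_duplication(
    locus: ReferenceLocus,
    start: int,
    end: int,
    inserted_seq: str = "",
) -> tuple[str, TruthRecord]:
    """Head-to-tail tandem duplication of ``[start, end]`` with an optional
    untemplated insertion at the junction between the two copies."""
    if not (locus.contains(start) and locus.contains(end)) or start > end:
        raise ValueError("need locus-internal coordinates with start <= end")
    if inserted_seq:
        if inserted_seq[-1] == locus.base(start - 1) or (
            locus.contains(end + 1) and inserted_seq[0] == locus.base(end + 1)
        ):
            raise ValueError(
                "insertion shares its boundary base with the reference flank; "
                "junction representation would be ambiguous — pick another "
                "insertion or interval"
            )
        bp5n, bp3n, ins = end, start, inserted_seq
    else:
        bp5n, bp3n, ins = normalize_duplication_junction(locus, end, start)
    truth = TruthRecord(
        event_type="duplication",
        bp5=bp5n,
        bp3=bp3n,
        planted_microhomology=0,
        inserted_seq=ins,
        mechanism_label="NHEJ",
    )
    return derive_allele(locus, truth), truth


def plant_rearrangement(
    locus: ReferenceLocus,
    request: Mapping,
    repeat_track: Sequence[RepeatElement] = (),
) -> tuple[str, TruthRecord]:
    """Dispatcher over the planting functions.

    ``request`` mirrors a truth record: keys ``event_type``
    (deletion/duplication), ``mechanism_label`` (NAHR/NHEJ), and either
    ``repeat5``/``repeat3`` (indices into ``repeat_track`` or elements) plus
    ``microhomology`` for NAHR, or ``bp5``/``bp3`` (deletion) or
    ``start``/``end`` (duplication) plus optional ``inserted_seq``.
    """
    ev = request["event_type"]
    if ev == "duplication":
        return plant_tandem_duplication(
            locus, request["start"], request["end"], request.get("inserted_seq", "")
        )
    if ev != "deletion":
        raise ValueError(f"bad event_type {ev!r}")
    if request.get("mechanism_label") == "NAHR":
        r5, r3 = request["repeat5"], request["repeat3"]
        if isinstance(r5, int):
            r5 = repeat_track[r5]
        if isinstance(r3, int):
            r3 = repeat_track[r3]
        return plant_nahr_deletion(locus, r5, r3, request["microhomology"])
    return plant_nhej_deletion(
        locus, request["bp5"], request["bp3"], request.get("inserted_seq", "")
    )


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    allele: str,
    read_length: int,
    depth: float,
    error_rate: float,
    seed: int,
) -> list[tuple[str, str]]:
    """Uniform-start reads with independent per-base substitution errors.

    The read count is ``round(depth * len(allele) / read_length)``.  Returns
    ``(read_id, sequence)`` pairs; write with
    :func:`rearrangemap.io.write_fastq` (constant quality line).
    """
    if read_length > len(allele):
        raise ValueError(
            f"read length {read_length} exceeds allele length {len(allele)}"
        )
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * len(allele) / read_length))
    starts = rng.integers(0, len(allele) - read_length + 1, size=n_reads)
    reads = []
    for i, s in enumerate(starts):
        sub = allele[s : s + read_length]
        if error_rate > 0:
            sub = _mutate(sub, error_rate, rng)
        reads.append((f"read_{i}", sub))
    return reads


# ---------------------------------------------------------------------------
# MLPA peak-area simulation


def simulate_mlpa(
    copy_number_by_exon: Mapping[str, int],
    n_controls: int = 4,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_reference_probes: int = 8,
    case_id: str = "case",
) -> pd.DataFrame:
    """Peak-area table for one test sample plus diploid controls.

    One probe per exon plus ``n_reference_probes`` reference probes that are
    diploid in every sample (the kit's normalization probes).  Expected
    normalized ratio before noise is ``copy_number / 2``; measurement noise
    is lognormal with log-scale sd ``noise_sd``.  Two independent reactions
    are generated per sample.
    """
    bad = {e: cn for e, cn in copy_number_by_exon.items() if cn not in (0, 1, 2, 3)}
    if bad:
        raise ValueError(f"copy numbers must be in {{0,1,2,3}}: {bad}")
    if n_controls < 3:
        raise ValueError("need at least 3 control samples in the batch")
    rng = np.random.default_rng(seed)
    probes = [(f"P_{exon}", exon, False) for exon in copy_number_by_exon]
    probes += [(f"REF{i+1}", f"ref{i+1}", True) for i in range(n_reference_probes)]
    base_area = {p: float(rng.uniform(500.0, 2000.0)) for p, _e, _r in probes}

    samples = [case_id] + [f"control_{i+1}" for i in range(n_controls)]
    rows = []
    for sample in samples:
        for reaction in (1, 2):
            for probe, exon, is_ref in probes:
                if sample == case_id and not is_ref:
                    cn = copy_number_by_exon[exon]
                else:
                    cn = 2
                area = base_area[probe] * (cn / 2.0)
                if noise_sd > 0:
                    area *= float(np.exp(rng.normal(0.0, noise_sd)))
                rows.append(
                    {
                        "sample_id": sample,
                        "reaction": reaction,
                        "probe": probe,
                        "exon": exon,
                        "peak_area": area,
                        "is_reference": is_ref,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aCGH probe simulation


def simulate_cgh(
    copy_number_segments: Sequence[tuple[int, int, int]],
    probe_spacing: int,
    noise_sd: float,
    seed: int,
    region: tuple[int, int],
    chrom: str = "locus",
) -> pd.DataFrame:
    """Probe log2-ratio track over ``region`` at fixed spacing.

    ``copy_number_segments`` lists ``(start, end, copy_number)`` aberrations
    on a diploid background; expected log2 ratio is ``log2(cn/2)`` (0 for
    CN=2, ~0.585 for CN=3, -1 for CN=1) plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    positions = np.arange(region[0], region[1] + 1, probe_spacing)
    log2 = np.zeros(len(positions))
    for start, end, cn in copy_number_segments:
        if cn < 1:
            raise ValueError("segment copy number must be >= 1")
        mask = (positions >= start) & (positions <= end)
        log2[mask] = np.log2(cn / 2.0)
    if noise_sd > 0:
        log2 = log2 + rng.normal(0.0, noise_sd, size=len(positions))
    return pd.DataFrame(
        {"chrom": chrom, "position": positions, "log2_ratio": log2}
    )


# ---------------------------------------------------------------------------
# Cohort simulation

DEFAULT_PHENOTYPE_RATES = {
    "LGR": {"CRC": 0.55, "EC": 0.11},
    "point": {"CRC": 0.42, "EC": 0.14},
}


def simulate_cohort(
    n_carrier_families: int,
    n_point_families: int,
    phenotype_rates: Optional[Mapping[str, Mapping[str, float]]] = None,
    seed: int = 0,
    individuals_per_family: int = 3,
    mean_onset_age: float = 43.0,
    sd_onset_age: float = 12.0,
    lgr_ams1: Optional[int] = None,
) -> pd.DataFrame:
    """Per-individual cohort table with Bernoulli tumor indicators.

    ``n_carrier_families`` families segregate a large rearrangement (LGR),
    ``n_point_families`` a point mutation; every individual is a carrier of
    the family variant.  Tumor types are drawn independently per individual
    at the class-specific rates; ages at diagnosis are normal, truncated at
    18.  Family variants are flagged pathogenic.  Clinical criteria are
    drawn at random unless ``lgr_ams1`` fixes how many of the LGR families
    meet the stricter colorectal-only criteria (AMS I), the remainder
    being AMS II.
    """
    rates = phenotype_rates if phenotype_rates is not None else DEFAULT_PHENOTYPE_RATES
    rng = np.random.default_rng(seed)
    rows = []
    fam = 0
    for mclass, n_fam in (("LGR", n_carrier_families), ("point", n_point_families)):
        for fam_idx in range(n_fam):
            fam += 1
            if mclass == "LGR" and lgr_ams1 is not None:
                criteria = "AMS I" if fam_idx < lgr_ams1 else "AMS II"
            else:
                criteria = "AMS I" if rng.random() < 0.58 else "AMS II"
            for ind in range(individuals_per_family):
                tumors = []
                for ttype, rate in rates.get(mclass, {}).items():
                    if rng.random() < rate:
                        age = max(18, int(round(rng.normal(mean_onset_age, sd_onset_age))))
                        tumors.append(f"{ttype}:{age}")
                rows.append(
                    {
                        "family_id": f"F{fam:03d}",
                        "individual_id": f"F{fam:03d}-{ind+1}",
                        "criteria": criteria,
                        "mutation_class": mclass,
                        "carrier": True,
                        "affected": bool(tumors),
                        "tumors": ";".join(tumors),
                        "pathogenic": True,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standard event battery


@dataclass
class PlantedEvent:
    """One simulated rearrangement with everything needed to test recovery."""

    locus: ReferenceLocus
    repeat_track: list[RepeatElement]
    allele: str
    truth: TruthRecord


def standard_event_battery(
    seed: int,
    n_nahr: int = 8,
    n_blunt: int = 6,
    insertion_lengths: Sequence[int] = (4, 5, 7, 9, 12),
    n_duplications: int = 1,
    locus_length: int = 15000,
    n_repeats: int = 12,
    repeat_divergence: float = 0.08,
    nahr_microhomologies: Sequence[int] = (10, 15, 20, 24, 30, 40, 48, 60),
) -> list[PlantedEvent]:
    """A mixed battery of planted events, each on its own random locus.

    Defaults give 20 events: NAHR deletions spanning the observed
    microhomology range (10-60 bp), blunt end-joining deletions,
    end-joining deletions with short untemplated insertions, and one
    tandem head-to-tail duplication with a 7 bp insertion.  Deterministic
    under ``seed``; loci are repeat-dense (about a quarter of the sequence
    in Alu-like elements) so breakpoints see realistic repeat context.
    """
    rng = np.random.default_rng(seed)
    events: list[PlantedEvent] = []
    i = 0

    def next_locus(n_rep: int) -> tuple[ReferenceLocus, list[RepeatElement]]:
        nonlocal i
        i += 1
        return generate_reference(
            locus_length, n_rep, repeat_divergence, seed=seed * 1000 + i
        )

    while len(events) < n_nahr:
        locus, track = next_locus(n_repeats)
        pairs = [
            (a, b)
            for j, a in enumerate(track)
            for b in track[j + 1 :]
            if a.strand == b.strand
            and b.start - a.end > 1500
            and a.start > 400
            and b.end < locus_length - 500
        ]
        if not pairs:
            continue
        r5, r3 = pairs[int(rng.integers(len(pairs)))]
        mh = nahr_microhomologies[len(events) % len(nahr_microhomologies)]
        try:
            allele, truth = plant_nahr_deletion(locus, r5, r3, mh)
        except ValueError:
            continue
        events.append(PlantedEvent(locus, track, allele, truth))

    def random_deletion(locus, track, ins_len: int) -> Optional[PlantedEvent]:
        for _ in range(100):
            bp5 = int(rng.integers(2000, 6000))
            bp3 = bp5 + int(rng.integers(1500, min(7000, locus_length - bp5 - 1500)))
            ins = "".join(rng.choice(list("ACGT"), ins_len)) if ins_len else ""
            try:
                allele, truth = plant_nhej_deletion(locus, bp5, bp3, ins)
            except ValueError:
                continue
            return PlantedEvent(locus, track, allele, truth)
        return None

    target = n_nahr + n_blunt
    while len(events) < target:
        ev = random_deletion(*next_locus(n_repeats - 2), 0)
        if ev:
            events.append(ev)
    for ins_len in insertion_lengths:
        while True:
            ev = random_deletion(*next_locus(n_repeats - 2), ins_len)
            if ev:
                events.append(ev)
                break
    planted_dups = 0
    while planted_dups < n_duplications:
        locus, track = next_locus(n_repeats - 2)
        for _ in range(100):
            s = int(rng.integers(3000, 5000))
            e = s + int(rng.integers(2500, 6000))
            ins = "".join(rng.choice(list("ACGT"), 7))
            try:
                allele, truth = plant_tandem_duplication(locus, s, e, ins)
            except ValueError:
                continue
            events.append(PlantedEvent(locus, track, allele, truth))
            planted_dups += 1
            break
    return events
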
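"""Shared fixtures: small seeded loci and a Table-2-structured cohort."""

from __future__ import annotations

import pandas as pd
import pytest

from rearrangemap import generate_reference


@pytest.fixture(scope="session")
def repeat_locus():
    """A 12 kb locus with 10 Alu-like repeats at 8% divergence (seeded)."""
    return generate_reference(12000, 10, 0.08, seed=42)


@pytest.fixture(scope="session")
def plain_locus():
    """A 10 kb repeat-free locus (seeded)."""
    locus, _track = generate_reference(10000, 0, 0.0, seed=7)
    return locus


def make_table2_cohort() -> pd.DataFrame:
    """A cohort whose per-class counts equal the published 2x2 tables.

    Point-mutation carriers: 107 (54 affected / 53 healthy; 36 one tumor /
    18 more than one; 45 CRC, 15 EC).  Rearrangement carriers: 27 (16/11;
    10/6; 15 CRC, 3 EC).
    """
    rows = []

    def add(mclass: str, n: int, tumor_lists):
        start = len(rows)
        for i in range(n):
            tumors = tumor_lists[i] if i < len(tumor_lists) else ""
            rows.append(
                {
                    "family_id": f"{mclass}{(start + i) // 2}",
                    "individual_id": f"{mclass}{start + i}",
                    "criteria": "AMS I",
                    "mutation_class": mclass,
                    "carrier": True,
                    "affected": bool(tumors),
                    "tumors": tumors,
                    "pathogenic": True,
                }
            )

    # LGR: 6 multi-tumor (3 CRC+EC, 3 CRC+UC), 10 single (9 CRC, 1 UC), 11 healthy
    lgr = (
        ["CRC:45;EC:50"] * 3
        + ["CRC:45;UC:55"] * 3
        + ["CRC:44"] * 9
        + ["UC:60"]
        + [""] * 11
    )
    add("LGR", 27, lgr)
    # point: 18 multi (6 CRC+EC, 12 CRC+UC), 36 single (27 CRC, 9 EC), 53 healthy
    point = (
        ["CRC:40;EC:48"] * 6
        + ["CRC:41;UC:52"] * 12
        + ["CRC:43"] * 27
        + ["EC:47"] * 9
        + [""] * 53
    )
    add("point", 107, point)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def table2_cohort():
    return make_table2_cohort()


def junction_shift_oracle(locus, bp5, bp3, window: int = 200, max_shift: int = 80):
    """Exhaustive junction-shift scan: microhomology length and leftmost bp5.

    Tries every shifted junction and keeps those reconstructing the same
    local allele window; independent of the analytical implementation.
    """
    lo = max(locus.start, bp5 - window)
    hi = min(locus.end, bp3 + window)

    def window_allele(b5, b3):
        return locus.fetch(lo, b5) + locus.fetch(b3, hi)

    target = window_allele(bp5, bp3)
    valid = []
    for d in range(-max_shift, max_shift + 1):
        b5, b3 = bp5 + d, bp3 + d
        if b5 < lo or b3 > hi or b5 >= b3:
            continue
        if window_allele(b5, b3) == target:
            valid.append(d)
    return max(valid) - min(valid), bp5 + min(valid)


@pytest.fixture(scope="session")
def table3_rows():
    """The six fully characterized junctions: microhomology, flanking
    repeats and orientation as published, with the expected mechanism."""
    return [
        # (microhomology, repeat5 family, repeat3 family, strands, expected)
        (24, "AluY", "AluSp", ("+", "+"), "NAHR"),
        (48, "AluY", "AluY", ("+", "+"), "NAHR"),
        (15, "AluJb", "AluSz", ("+", "+"), "NAHR"),
        (0, "AluSx", None, ("+", None), "NHEJ"),
        (0, None, None, (None, None), "NHEJ"),
        (0, None, "AluSx", (None, "+"), "NHEJ"),
    ]
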
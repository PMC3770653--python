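"""Cohort-level rearrangement frequencies and genotype-phenotype tables.

Frequencies are reported as percentages rounded half-up to one decimal
(the convention of the clinical tables this module reproduces); per-class
tumor frequencies are reported as integer percentages, floor-rounded.
Association between mutation class (point mutation vs large rearrangement)
and phenotype is tested on 2x2 tables; the primary method is the
chi-square test with continuity correction, with Fisher's exact test and
the uncorrected chi-square reported alongside for transparency, and ages
at first diagnosis are compared with an equal-variance two-sample t-test.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ContingencyResult

# ---------------------------------------------------------------------------
# Rounding conventions


def frequency_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (e.g. 9/83 -> 10.8)."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in frequency computation")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tumor_frequency_pct(numerator: int, denominator: int) -> int:
    """Integer percentage, floor-rounded (e.g. 15/27 -> 55)."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in tumor frequency")
    return math.floor(100 * numerator / denominator)


# ---------------------------------------------------------------------------
# Cohort table helpers

def _parse_tumors(cell: str) -> list[tuple[str, int]]:
    """Parse a ``"CRC:45;EC:50"`` tumor-history cell."""
    if not cell or (isinstance(cell, float) and np.isnan(cell)):
        return []
    out = []
    for item in str(cell).split(";"):
        item = item.strip()
        if not item:
            continue
        ttype, _, age = item.partition(":")
        out.append((ttype.strip(), int(age)))
    return out


def _family_level(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort.groupby("family_id").agg(
        criteria=("criteria", "first"),
        mutation_class=("mutation_class", "first"),
        pathogenic=("pathogenic", "any"),
    )


# ---------------------------------------------------------------------------
# Frequencies


def lgr_frequencies(
    cohort: pd.DataFrame,
    n_families_total: int = 83,
    n_ams1: int = 48,
    n_ams2: int = 35,
    n_msh2_alterations: int = 44,
) -> dict[str, float]:
    """Family-level rearrangement frequencies as one-decimal percentages.

    Counts families carrying a pathogenic large rearrangement (LGR) in the
    cohort table and relates them to the screening denominators: all
    families with a pathogenic alteration, all alterations at the locus,
    and the per-criteria family counts (Amsterdam I / Amsterdam II).
    """
    for name, d in (
        ("n_families_total", n_families_total),
        ("n_ams1", n_ams1),
        ("n_ams2", n_ams2),
        ("n_msh2_alterations", n_msh2_alterations),
    ):
        if d == 0:
            raise ZeroDivisionError(f"{name} is zero")
    fams = _family_level(cohort)
    lgr = fams[(fams["mutation_class"] == "LGR") & fams["pathogenic"]]
    n_lgr = len(lgr)
    n_lgr_ams1 = int((lgr["criteria"] == "AMS I").sum())
    n_lgr_ams2 = int((lgr["criteria"] == "AMS II").sum())
    return {
        "n_pathogenic_lgr_families": float(n_lgr),
        "pct_of_all_families": frequency_pct(n_lgr, n_families_total),
        "pct_of_msh2_alterations": frequency_pct(n_lgr, n_msh2_alterations),
        "pct_ams1": frequency_pct(n_lgr_ams1, n_ams1),
        "pct_ams2": frequency_pct(n_lgr_ams2, n_ams2),
    }


# ---------------------------------------------------------------------------
# Genotype-phenotype table


def phenotype_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and floor-rounded tumor percentages by mutation class.

    Rows: affected / healthy carriers, carriers with one vs more than one
    tumor, carriers developing colorectal (CRC) and endometrial (EC)
    cancer, and mean age at first diagnosis.  Columns: point / LGR.
    An empty cohort yields all-zero counts.
    """
    rows: dict[str, dict[str, float]] = {}
    classes = ("point", "LGR")
    per_class: dict[str, pd.DataFrame] = {
        c: cohort[(cohort["mutation_class"] == c) & cohort["carrier"]]
        for c in classes
    }
    for c in classes:
        sub = per_class[c]
        tumors = [_parse_tumors(t) for t in sub["tumors"]] if len(sub) else []
        n = len(sub)
        affected = sum(1 for t in tumors if t)
        one = sum(1 for t in tumors if len(t) == 1)
        multi = sum(1 for t in tumors if len(t) > 1)
        crc = sum(1 for t in tumors if any(tt == "CRC" for tt, _ in t))
        ec = sum(1 for t in tumors if any(tt == "EC" for tt, _ in t))
        first_ages = [min(a for _, a in t) for t in tumors if t]
        col = {
            "n_carriers": n,
            "affected": affected,
            "healthy": n - affected,
            "one_tumor": one,
            "multi_tumor": multi,
            "CRC": crc,
            "EC": ec,
            "CRC_pct": tumor_frequency_pct(crc, n) if n else 0,
            "EC_pct": tumor_frequency_pct(ec, n) if n else 0,
            "mean_age_first_dx": float(np.mean(first_ages)) if first_ages else float("nan"),
        }
        for k, v in col.items():
            rows.setdefault(k, {})[c] = v
    return pd.DataFrame(rows).T[list(classes)]


# ---------------------------------------------------------------------------
# Association tests


def _fisher(table: np.ndarray) -> tuple[float, float]:
    odds, p = stats.fisher_exact(table)
    return float(odds), float(p)


def association_tests(
    counts: Sequence[Sequence[int]],
    ages_a: Optional[Sequence[float]] = None,
    ages_b: Optional[Sequence[float]] = None,
) -> dict[str, ContingencyResult]:
    """Association tests for one 2x2 table (and optional age comparison).

    Returns the continuity-corrected chi-square as ``primary``, plus
    ``chi2_uncorrected`` and ``fisher_exact``; when any expected cell is
    below 1 only Fisher's exact test is reported (with a note in the
    method string).  When two age samples are supplied an equal-variance
    two-sample t-test is added under ``age_ttest``.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    tab = tuple(tuple(int(v) for v in row) for row in table)

    results: dict[str, ContingencyResult] = {}
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total if total else table
    odds, p_f = _fisher(table)
    if (expected < 1).any():
        results["primary"] = ContingencyResult(
            tab, odds, p_f, "Fisher exact (chi-square unreliable: expected cell < 1)"
        )
        results["fisher_exact"] = results["primary"]
        return results

    chi2c = stats.chi2_contingency(table, correction=True)
    chi2u = stats.chi2_contingency(table, correction=False)
    results["primary"] = ContingencyResult(
        tab, float(chi2c.statistic), float(chi2c.pvalue),
        "chi-square with continuity correction (df=1)",
    )
    results["chi2_uncorrected"] = ContingencyResult(
        tab, float(chi2u.statistic), float(chi2u.pvalue), "chi-square (df=1)"
    )
    results["fisher_exact"] = ContingencyResult(tab, odds, p_f, "Fisher exact")
    if ages_a is not None and ages_b is not None:
        t, p = stats.ttest_ind(list(ages_a), list(ages_b), equal_var=True)
        results["age_ttest"] = ContingencyResult(
            tab, float(t), float(p), "two-sample t-test (equal variance)"
        )
    return results


def cohort_association_summary(cohort: pd.DataFrame) -> dict[str, dict[str, ContingencyResult]]:
    """Standard comparisons between point-mutation and LGR carriers:
    affected vs healthy, single vs multiple tumors, CRC, EC, and age."""
    pt = phenotype_table(cohort)

    def first_dx_ages(mclass):
        sub = cohort[(cohort["mutation_class"] == mclass) & cohort["carrier"]]
        parsed = (_parse_tumors(t) for t in sub["tumors"])
        return [min(a for _t, a in t) for t in parsed if t]

    out = {}
    out["affected_vs_healthy"] = association_tests(
        [[pt.loc["affected", "point"], pt.loc["affected", "LGR"]],
         [pt.loc["healthy", "point"], pt.loc["healthy", "LGR"]]],
        ages_a=first_dx_ages("point") or None,
        ages_b=first_dx_ages("LGR") or None,
    )
    out["one_vs_multi_tumor"] = association_tests(
        [[pt.loc["one_tumor", "point"], pt.loc["one_tumor", "LGR"]],
         [pt.loc["multi_tumor", "point"], pt.loc["multi_tumor", "LGR"]]]
    )
    for tumor in ("CRC", "EC"):
        k_pt, k_lgr = pt.loc[tumor, "point"], pt.loc[tumor, "LGR"]
        n_pt, n_lgr = pt.loc["n_carriers", "point"], pt.loc["n_carriers", "LGR"]
        out[tumor] = association_tests(
            [[k_pt, k_lgr], [n_pt - k_pt, n_lgr - k_lgr]]
        )
    return out
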
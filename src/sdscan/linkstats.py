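"""Sex-linkage statistics for genotyping assays.

PCR presence/absence markers and allele-specific (KASPar-style) genotyping
assays are scored against phenotypic sex with Pearson's chi-square test using
Yates' continuity correction on a 2x2 contingency table.  For genotype assays
on an XY system the informative signal is heterozygosity in males versus
homozygosity in females, so the table crosses sex with called genotype class
and uncalled individuals are excluded from the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeCountTable",
    "LinkageResult",
    "UndefinedTestError",
    "yates_chi2",
    "marker_presence_test",
    "genotype_linkage",
    "format_p",
]

#: p-values below this floor are printed as "< 2.2e-16" in formatted reports.
P_FLOOR = 2.22e-16


class UndefinedTestError(ValueError):
    """Raised when a 2x2 table has a zero row or column margin.

    With an empty margin the expected counts are degenerate and the
    chi-square statistic is not defined; callers should report the test as
    not computable rather than silently significant or non-significant.
    """


@dataclass(frozen=True)
class GenotypeCountTable:
    """Per-assay genotype call counts split by phenotypic sex.

    ``ho``/``he``/``u`` are homozygote, heterozygote and uncalled counts;
    per-sex totals are derived, so the ho+he+u = n invariant holds by
    construction.
    """

    assay_id: str
    male_ho: int
    male_he: int
    male_u: int
    female_ho: int
    female_he: int
    female_u: int

    def __post_init__(self) -> None:
        for name in ("male_ho", "male_he", "male_u", "female_ho", "female_he", "female_u"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.assay_id}: {name} must be >= 0")

    @property
    def n_males(self) -> int:
        return self.male_ho + self.male_he + self.male_u

    @property
    def n_females(self) -> int:
        return self.female_ho + self.female_he + self.female_u

    @property
    def n_total(self) -> int:
        return self.n_males + self.n_females


@dataclass(frozen=True)
class LinkageResult:
    """Outcome of one sex-linkage test.

    ``pct_genotyped`` is the share of the recruited cohort with any assay
    result (uncalled included); ``pct_assigned`` is the share of assayed
    individuals carrying the sex-concordant state (heterozygous male or
    homozygous female for genotype assays).  ``pct_assigned_called`` uses
    successfully called genotypes as the denominator instead and is kept as a
    secondary diagnostic.  ``table_used`` is the 2x2 actually tested.
    """

    assay_id: str
    chi2: float
    p: float
    pct_genotyped: float
    pct_assigned: float
    table_used: tuple[tuple[int, int], tuple[int, int]]
    pct_assigned_called: float = field(default=float("nan"))

    @property
    def p_formatted(self) -> str:
        return format_p(self.p)


def format_p(p: float) -> str:
    """Report-style p-value string with a floor at 2.2e-16."""
    if p < P_FLOOR:
        return "< 2.2e-16"
    return f"{p:.4g}"


def yates_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square with Yates' continuity correction on [[a, b], [c, d]].

    The statistic is sum((|O - E| - 0.5)^2 / E) over the four cells, with the
    corrected deviation clamped at zero so near-independent tables cannot
    contribute negative-looking terms.  p is the upper tail of the chi-square
    distribution with one degree of freedom.

    Raises
    ------
    UndefinedTestError
        If any row or column margin is zero.
    """
    tab = np.array([[a, b], [c, d]], dtype=float)
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise UndefinedTestError(f"zero margin in table [[{a},{b}],[{c},{d}]]")
    expected = np.outer(rows, cols) / tab.sum()
    dev = np.maximum(np.abs(tab - expected) - 0.5, 0.0)
    chi2 = float((dev * dev / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def marker_presence_test(
    pos_m: int, n_m: int, pos_f: int, n_f: int, assay_id: str = ""
) -> LinkageResult:
    """Sex association of a presence/absence marker.

    Tests [[pos_m, n_m - pos_m], [pos_f, n_f - pos_f]].  For a Y-linked
    marker the concordant states are marker-positive males and
    marker-negative females, which is what ``pct_assigned`` reports.
    """
    if not (0 <= pos_m <= n_m and 0 <= pos_f <= n_f):
        raise ValueError("positives must satisfy 0 <= pos <= n for each sex")
    table = ((pos_m, n_m - pos_m), (pos_f, n_f - pos_f))
    chi2, p = yates_chi2(*table[0], *table[1])
    n = n_m + n_f
    return LinkageResult(
        assay_id=assay_id,
        chi2=chi2,
        p=p,
        pct_genotyped=100.0,
        pct_assigned=100.0 * (pos_m + (n_f - pos_f)) / n,
        pct_assigned_called=100.0 * (pos_m + (n_f - pos_f)) / n,
        table_used=table,
    )


def genotype_linkage(t: GenotypeCountTable, cohort_size: int | None = None) -> LinkageResult:
    """Sex linkage of a genotyping assay from Ho/He/U counts.

    Uncalled genotypes are excluded and the tested table is
    [[male_he, male_ho], [female_he, female_ho]].  ``pct_genotyped`` divides
    the assayed total by ``cohort_size`` (the number of recruited
    individuals; defaults to the assayed total).  ``pct_assigned`` divides
    concordant calls (He males + Ho females) by the assayed total,
    ``pct_assigned_called`` by the called total.
    """
    called = t.n_total - t.male_u - t.female_u
    if called == 0:
        raise UndefinedTestError(f"{t.assay_id}: no called genotypes")
    table = ((t.male_he, t.male_ho), (t.female_he, t.female_ho))
    chi2, p = yates_chi2(*table[0], *table[1])
    cohort = t.n_total if cohort_size is None else cohort_size
    if cohort <= 0:
        raise ValueError("cohort_size must be positive")
    concordant = t.male_he + t.female_ho
    return LinkageResult(
        assay_id=t.assay_id,
        chi2=chi2,
        p=p,
        pct_genotyped=100.0 * t.n_total / cohort,
        pct_assigned=100.0 * concordant / t.n_total,
        pct_assigned_called=100.0 * concordant / called,
        table_used=table,
    )
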
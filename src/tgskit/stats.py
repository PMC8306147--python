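"""Case–control contingency tests and TGS group comparisons.

Genotype and allele distributions between cohorts are compared with the
Pearson chi-square test of independence (no continuity correction; a
Fisher exact fallback is available for sparse 2x2 tables).  TGS
distributions between independent groups are compared with the two-sided
Wilcoxon rank-sum (Mann–Whitney U) test, the appropriate nonparametric
choice at the small, non-normal sample sizes typical of sports genetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_model import Cohort
from .tgs_engine import TGSResult

__all__ = [
    "TestResult",
    "allele_counts_from_genotype_counts",
    "chi_square_independence",
    "rank_sum_test",
    "group_tgs_summary",
]


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: int | None
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def allele_counts_from_genotype_counts(counts: Sequence[int]) -> tuple[int, int]:
    """(hom1, het, hom2) genotype counts -> (allele1, allele2) counts.

    Each hom1 individual carries two copies of allele 1, each heterozygote
    one of each: allele1 = 2*hom1 + het, allele2 = 2*hom2 + het.
    """
    hom1, het, hom2 = (int(c) for c in counts)
    if min(hom1, het, hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    return 2 * hom1 + het, 2 * hom2 + het


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"contingency table must be at least 2x2, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an all-zero row or column")
    return arr


def chi_square_independence(table, *, exact: bool = False) -> TestResult:
    """Pearson chi-square test of independence, df = (r-1)(c-1), asymptotic
    p-value, no Yates correction.  ``exact=True`` switches a 2x2 table to
    Fisher's exact test (for sparse tables)."""
    arr = _as_table(table)
    if exact:
        if arr.shape != (2, 2):
            raise ValueError("exact test is only available for 2x2 tables")
        res = sps.fisher_exact(arr)
        return TestResult("fisher_exact", float(res.statistic), None, float(res.pvalue))
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult("chi2", float(stat), int(df), float(p))


def rank_sum_test(a: Sequence[float], b: Sequence[float], *,
                  method: Literal["auto", "exact", "asymptotic"] = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Mid-ranks for ties; the asymptotic path uses the normal approximation
    with continuity correction, while ``auto`` switches to the exact null
    distribution for small tie-free samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", use_continuity=True, method=method)
    return TestResult("wilcoxon_rank_sum", float(res.statistic), None, float(res.pvalue))


def group_tgs_summary(results: Sequence[TGSResult], cohort: Cohort, *,
                      value: Literal["normalized", "raw"] = "normalized") -> pd.DataFrame:
    """Per (sex, group) distribution summary of TGS values.

    Returns a frame indexed by (sex, group) with n, median, quartiles, min
    and max; group sizes are conserved from the cohort members scored.
    """
    by_id = {p.sample_id: p for p in cohort.profiles}
    rows = []
    for r in results:
        p = by_id.get(r.sample_id)
        if p is None:
            raise ValueError(f"TGS result for unknown sample {r.sample_id!r}")
        rows.append({"sex": p.sex.value, "group": p.group, "tgs": getattr(r, value)})
    df = pd.DataFrame(rows)
    out = df.groupby(["sex", "group"])["tgs"].agg(
        n="count", median="median",
        q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75),
        min="min", max="max")
    return out
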
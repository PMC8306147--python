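"""Over-representation of multimarker genotype combinations.

A combination is the ordered tuple of genotypes an individual carries
across the panel (e.g. ID-RX-AG-CT on a 4-marker panel; 3^M possible
combinations).  Assuming markers are independent in the population, the
probability of a combination is the product of its per-marker genotype
frequencies, p(M).  If k of n cohort members carry a combination, the
binomial point probability

    P_p(k | n) = C(n, k) * p^k * (1 - p)^(n - k),   p = p(M)

measures how (un)likely that count would be in n random draws from the
population; small values flag over- (or under-) represented combinations.
No linkage-disequilibrium correction and no multiple-testing adjustment is
applied.

``freq_decimals`` / ``p_decimals`` allow rounding the per-marker
frequencies and the combination probability to a fixed number of decimals
before use, mirroring published tables computed from printed (rounded)
values; by default everything is carried at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats as sps

from .genotype_model import Cohort, CohortValidationError, FrequencyTable, Profile

__all__ = [
    "CombinationKey",
    "EnrichmentRecord",
    "combination_key",
    "key_to_str",
    "parse_key",
    "count_combinations",
    "combination_probability",
    "binomial_point_probability",
    "enrichment_table",
    "enrichment_frame",
    "write_enrichment_table",
]

CombinationKey = tuple[str, ...]


@dataclass(frozen=True)
class EnrichmentRecord:
    key: CombinationKey
    k: int          # cohort carriers
    n: int          # cohort size
    p_M: float      # population combination probability
    binom_prob: float  # P_p(M)(k | n)


def combination_key(profile: Profile, panel) -> CombinationKey:
    key = []
    for m in panel:
        gt = profile.genotypes.get(m.gene)
        if gt is None:
            raise CohortValidationError(
                f"sample {profile.sample_id!r}: missing genotype for {m.gene}")
        key.append(gt)
    return tuple(key)


def key_to_str(key: CombinationKey) -> str:
    return "-".join(key)


def parse_key(text: str) -> CombinationKey:
    return tuple(part.strip() for part in text.split("-"))


def count_combinations(cohort: Cohort, *, by_group: bool = False):
    """Tally observed genotype combinations; counts sum to the cohort size.

    Returns ``{key: count}``, or ``{group: {key: count}}`` with ``by_group``.
    """
    if by_group:
        out: dict[str, dict[CombinationKey, int]] = {g: {} for g in cohort.group_labels}
        for p in cohort.profiles:
            key = combination_key(p, cohort.panel)
            out[p.group][key] = out[p.group].get(key, 0) + 1
        return out
    counts: dict[CombinationKey, int] = {}
    for p in cohort.profiles:
        key = combination_key(p, cohort.panel)
        counts[key] = counts.get(key, 0) + 1
    return counts


def combination_probability(freqs: FrequencyTable, key: CombinationKey, panel,
                            *, freq_decimals: int | None = None) -> float:
    """p(M): product of per-marker genotype frequencies under independence."""
    if len(key) != len(panel):
        raise CohortValidationError(
            f"combination {key!r} has {len(key)} genotypes for a {len(panel)}-marker panel")
    p = 1.0
    for m, gt in zip(panel, key):
        f = freqs.frequency(m.gene, gt)
        if freq_decimals is not None:
            f = round(f, freq_decimals)
        p *= f
    return p


def binomial_point_probability(k: int, n: int, p: float) -> float:
    """Binomial pmf ``C(n,k) p^k (1-p)^(n-k)`` (log-space via scipy)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"success probability {p} outside [0, 1]")
    return float(sps.binom.pmf(k, n, p))


def enrichment_table(cohort: Cohort, freqs: FrequencyTable, *,
                     threshold: float = 1.0,
                     freq_decimals: int | None = None,
                     p_decimals: int | None = None) -> list[EnrichmentRecord]:
    """One record per observed combination, ascending by binomial probability.

    Records with ``binom_prob >= threshold`` are dropped (default keeps
    all); ties are broken lexicographically on the combination key.
    """
    counts = count_combinations(cohort)
    n = len(cohort)
    records = []
    for key, k in counts.items():
        p = combination_probability(freqs, key, cohort.panel, freq_decimals=freq_decimals)
        if p_decimals is not None:
            p = round(p, p_decimals)
        bp = binomial_point_probability(k, n, p)
        if bp < threshold:
            records.append(EnrichmentRecord(key, k, n, p, bp))
    return sorted(records, key=lambda r: (r.binom_prob, r.key))


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"combination": key_to_str(r.key), "k": r.k, "n": r.n,
          "p_M": r.p_M, "binom_prob": r.binom_prob} for r in records])


def write_enrichment_table(records: Sequence[EnrichmentRecord], path, *,
                           delimiter: str = ",") -> None:
    enrichment_frame(records).to_csv(path, sep=delimiter, index=False)
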
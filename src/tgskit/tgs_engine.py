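"""Total genotype score (TGS) computation and normalization.

Two scoring conventions are supported:

* ``"WF"`` — the classic Williams–Folland convention: each genotype carries
  an integer score G in {2, 1, 0} (favourable / medium / neutral) and the
  TGS of an n-marker profile is ``(100 / 2n) * sum(G)``, ranging 0–100.
* ``"weighted"`` — signed genotype scores ``G * g`` with direction
  G in {-1, 0, +1} (endurance +, power -, mixed 0) and magnitude g; the raw
  TGS is the plain sum of the profile's genotype scores.

Raw scores live on a table-dependent interval [tgs_min, tgs_max]; for
comparability across panels they are mapped affinely onto [-1, 1]
(endurance extreme -> +1, power extreme -> -1).  Bounds default to the
theoretical per-marker extremes of the score table; empirical cohort
min/max bounds are available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .genotype_model import Cohort, MarkerDef, Profile

__all__ = [
    "ScoreEntry",
    "GenotypeScoreTable",
    "TGSBounds",
    "TGSResult",
    "ScoreTableError",
    "raw_tgs",
    "wf_tgs",
    "theoretical_bounds",
    "empirical_bounds",
    "normalize_tgs",
    "score_cohort",
    "read_score_table",
    "write_score_table",
]

Convention = Literal["WF", "weighted"]
TRAIT_LABELS = ("End", "Mix", "Pow")


class ScoreTableError(ValueError):
    """Raised on malformed score tables or profiles they do not cover."""


@dataclass(frozen=True)
class ScoreEntry:
    score: float
    trait_label: str            # "End" | "Mix" | "Pow"
    provenance: str = "literature"   # "literature" | "derived"


@dataclass
class GenotypeScoreTable:
    """One score per (marker, genotype) of a panel, under one convention.

    WF-convention scores must be in {2, 1, 0}.  Weighted-convention scores
    are signed reals (committee-derived magnitudes are means of absolute
    logistic coefficients and are typically, but not necessarily, below 1).
    """

    panel: tuple[MarkerDef, ...]
    entries: dict[tuple[str, str], ScoreEntry]
    convention: Convention = "weighted"

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        for m in self.panel:
            for gt in m.genotype_labels:
                key = (m.gene, gt)
                if key not in self.entries:
                    raise ScoreTableError(f"score table misses entry for {m.gene} {gt}")
                e = self.entries[key]
                if e.trait_label not in TRAIT_LABELS:
                    raise ScoreTableError(
                        f"{m.gene} {gt}: unknown trait label {e.trait_label!r}")
                if self.convention == "WF" and e.score not in (0, 1, 2):
                    raise ScoreTableError(
                        f"{m.gene} {gt}: WF convention requires score in {{2,1,0}}, "
                        f"got {e.score!r}")

    def score(self, gene: str, genotype: str) -> float:
        try:
            return self.entries[(gene, genotype)].score
        except KeyError:
            raise ScoreTableError(f"no score for {gene} genotype {genotype!r}") from None

    @classmethod
    def from_trait_annotation(cls, panel: Sequence[MarkerDef],
                              traits: dict[tuple[str, str], str],
                              trait_scores: dict[str, float] | None = None,
                              provenance: str = "literature") -> "GenotypeScoreTable":
        """Build a WF-convention table from a trait label per genotype
        (default mapping End -> 2, Mix -> 1, Pow -> 0)."""
        trait_scores = trait_scores or {"End": 2, "Mix": 1, "Pow": 0}
        entries = {}
        for m in panel:
            for gt in m.genotype_labels:
                t = traits[(m.gene, gt)]
                entries[(m.gene, gt)] = ScoreEntry(trait_scores[t], t, provenance)
        return cls(tuple(panel), entries, convention="WF")


@dataclass(frozen=True)
class TGSBounds:
    tgs_min: float
    tgs_max: float

    def __post_init__(self) -> None:
        if not self.tgs_min < self.tgs_max:
            raise ScoreTableError(
                f"invalid bounds: tgs_min={self.tgs_min} must be < tgs_max={self.tgs_max}")


@dataclass
class TGSResult:
    sample_id: str
    raw: float
    normalized: float
    per_marker_contributions: dict[str, float] = field(default_factory=dict)


def _contributions(profile: Profile, table: GenotypeScoreTable) -> dict[str, float]:
    contrib = {}
    for m in table.panel:
        gt = profile.genotypes.get(m.gene)
        if gt is None:
            raise ScoreTableError(f"sample {profile.sample_id!r}: missing genotype for {m.gene}")
        contrib[m.gene] = table.score(m.gene, gt)
    return contrib


def raw_tgs(profile: Profile, table: GenotypeScoreTable) -> float:
    """Raw weighted TGS: the sum of the profile's signed genotype scores."""
    return float(sum(_contributions(profile, table).values()))


def wf_tgs(profile: Profile, table: GenotypeScoreTable) -> float:
    """Williams–Folland TGS on the 0–100 scale: ``(100 / 2n) * sum(G)``."""
    if table.convention != "WF":
        raise ScoreTableError("wf_tgs requires a WF-convention score table")
    n = len(table.panel)
    return 100.0 / (2 * n) * sum(_contributions(profile, table).values())


def theoretical_bounds(table: GenotypeScoreTable) -> TGSBounds:
    """Bounds of the raw genotype-score sum: per-marker extreme scores summed."""
    if not table.panel:
        raise ScoreTableError("cannot compute bounds of an empty score table")
    lo = hi = 0.0
    for m in table.panel:
        scores = [table.score(m.gene, gt) for gt in m.genotype_labels]
        lo += min(scores)
        hi += max(scores)
    return TGSBounds(lo, hi)


def empirical_bounds(raw_scores: Iterable[float]) -> TGSBounds:
    scores = list(raw_scores)
    if not scores:
        raise ScoreTableError("cannot compute empirical bounds without scores")
    return TGSBounds(min(scores), max(scores))


def normalize_tgs(raw: float, bounds: TGSBounds, *, clamp: bool = False) -> float:
    """Map raw TGS affinely from [tgs_min, tgs_max] onto [-1, 1].

    ``tgs_min -> -1`` and ``tgs_max -> +1``; strictly increasing in between.
    Raw values outside the bounds raise unless ``clamp`` is set (relevant
    under empirical bounds applied to new individuals).
    """
    lo, hi = bounds.tgs_min, bounds.tgs_max
    if raw < lo or raw > hi:
        if not clamp:
            raise ScoreTableError(
                f"raw TGS {raw} outside bounds [{lo}, {hi}]; pass clamp=True to clip")
        raw = min(max(raw, lo), hi)
    return 2.0 * (raw - lo) / (hi - lo) - 1.0


def score_cohort(cohort: Cohort, table: GenotypeScoreTable, *,
                 bounds: TGSBounds | Literal["theoretical", "empirical"] = "theoretical",
                 clamp: bool = False) -> list[TGSResult]:
    """Raw + normalized TGS for every complete profile of a cohort.

    ``raw`` is the genotype-score sum under either convention (for a WF
    table this is the unscaled 0..2n sum; :func:`wf_tgs` gives the 0–100
    scale).  Normalization maps the selected bounds onto [-1, 1].
    """
    complete = cohort.complete_profiles()
    contribs = [_contributions(p, table) for p in complete]
    raws = [float(sum(c.values())) for c in contribs]
    if bounds == "theoretical":
        b = theoretical_bounds(table)
    elif bounds == "empirical":
        b = empirical_bounds(raws)
    else:
        b = bounds
    return [TGSResult(p.sample_id, raw, normalize_tgs(raw, b, clamp=clamp), contrib)
            for p, raw, contrib in zip(complete, raws, contribs)]


# ---------------------------------------------------------------------------
# IO — `gene,rsid,genotype,score,trait_label,convention,provenance`

def read_score_table(path, panel: Sequence[MarkerDef], *, delimiter: str = ",") -> GenotypeScoreTable:
    df = pd.read_csv(path, sep=delimiter)
    conventions = set(df["convention"].astype(str))
    if len(conventions) != 1:
        raise ScoreTableError(f"score table mixes conventions: {sorted(conventions)}")
    convention = conventions.pop()
    entries = {}
    for _, r in df.iterrows():
        entries[(str(r["gene"]), str(r["genotype"]).strip())] = ScoreEntry(
            float(r["score"]), str(r["trait_label"]), str(r.get("provenance", "literature")))
    return GenotypeScoreTable(tuple(panel), entries, convention=convention)  # type: ignore[arg-type]


def write_score_table(table: GenotypeScoreTable, path, *, delimiter: str = ",") -> None:
    rows = []
    for m in table.panel:
        for gt in m.genotype_labels:
            e = table.entries[(m.gene, gt)]
            rows.append({"gene": m.gene, "rsid": m.rsid, "genotype": gt,
                         "score": e.score, "trait_label": e.trait_label,
                         "convention": table.convention, "provenance": e.provenance})
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
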
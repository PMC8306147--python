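"""Core data model: markers, profiles, cohorts, genotype frequencies, one-hot encoding.

A marker panel is an ordered list of tri-genotype markers (e.g. *ACE*
rs1799752 with genotypes DD/ID/II).  Individuals carry one genotype per
marker; a cohort groups individuals by trait class (e.g. endurance /
mixed / power) and sex.  All downstream computation — score derivation,
total genotype scores, combination enrichment — works on these containers.

Genotype labels are compared case-sensitively after stripping surrounding
whitespace; heterozygote labels are not reordered ("ID" != "DI"), so input
files must match the panel declaration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "MarkerDef",
    "Profile",
    "Cohort",
    "FrequencyTable",
    "EncodedMatrix",
    "CohortValidationError",
    "MISSING_VALUES",
    "read_cohort",
    "write_cohort",
    "frequencies_from_counts",
    "read_frequency_table",
    "write_frequency_table",
    "one_hot_encode",
]

#: genotype cell values that mark an unobserved genotype
MISSING_VALUES = frozenset({"", "NA", "N/A", ".", "nan", "None"})


class CohortValidationError(ValueError):
    """Raised when a cohort, profile or frequency table violates an invariant."""


class Sex(str, enum.Enum):
    female = "female"
    male = "male"
    unknown = "unknown"

    @classmethod
    def parse(cls, value: str) -> "Sex":
        v = str(value).strip().lower()
        aliases = {"f": "female", "m": "male", "female": "female",
                   "male": "male", "unknown": "unknown", "u": "unknown", "": "unknown"}
        if v not in aliases:
            raise CohortValidationError(f"unrecognised sex value {value!r}")
        return cls(aliases[v])


@dataclass(frozen=True)
class MarkerDef:
    """One genetic marker with its three genotype labels in declared order.

    The declared label order is fixed and used everywhere downstream
    (one-hot column order, score-table rows, combination keys).
    """

    gene: str
    rsid: str
    genotype_labels: tuple[str, str, str]

    def __post_init__(self) -> None:
        labels = tuple(str(l).strip() for l in self.genotype_labels)
        if len(labels) != 3:
            raise CohortValidationError(
                f"marker {self.gene}: exactly 3 genotype labels required, got {len(labels)}")
        if len(set(labels)) != 3:
            raise CohortValidationError(f"marker {self.gene}: genotype labels must be distinct")
        object.__setattr__(self, "genotype_labels", labels)

    @property
    def name(self) -> str:
        """Column identifier ``<gene>_<rsid>`` used in cohort files."""
        return f"{self.gene}_{self.rsid}"


@dataclass
class Profile:
    """One individual: id, sex, trait group and a genotype per panel marker.

    ``genotypes`` maps gene name -> genotype label; a marker absent from the
    mapping (or mapped to ``None``) is missing.
    """

    sample_id: str
    sex: Sex
    group: str
    genotypes: dict[str, str | None]

    def is_complete(self, panel: Sequence[MarkerDef]) -> bool:
        return all(self.genotypes.get(m.gene) is not None for m in panel)


@dataclass
class Cohort:
    """An ordered marker panel plus a list of individual profiles."""

    panel: tuple[MarkerDef, ...]
    profiles: list[Profile]
    group_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        if not self.group_labels:
            seen: list[str] = []
            for p in self.profiles:
                if p.group not in seen:
                    seen.append(p.group)
            self.group_labels = tuple(seen)
        self.validate()

    def validate(self) -> None:
        genes = [m.gene for m in self.panel]
        if len(set(genes)) != len(genes):
            raise CohortValidationError("panel gene names must be unique")
        valid = {m.gene: set(m.genotype_labels) for m in self.panel}
        ids: set[str] = set()
        for i, p in enumerate(self.profiles):
            if p.sample_id in ids:
                raise CohortValidationError(f"duplicate sample id {p.sample_id!r}")
            ids.add(p.sample_id)
            for gene, gt in p.genotypes.items():
                if gene not in valid:
                    raise CohortValidationError(
                        f"sample {p.sample_id!r}: genotype for unknown marker {gene!r}")
                if gt is not None and gt not in valid[gene]:
                    raise CohortValidationError(
                        f"sample {p.sample_id!r} (row {i + 1}): invalid genotype {gt!r} "
                        f"for marker {gene}; expected one of {sorted(valid[gene])}")

    def __len__(self) -> int:
        return len(self.profiles)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in self.group_labels}
        for p in self.profiles:
            sizes[p.group] = sizes.get(p.group, 0) + 1
        return sizes

    def subset(self, groups: Iterable[str]) -> "Cohort":
        """Cohort restricted to the given trait groups (panel unchanged)."""
        wanted = tuple(groups)
        profs = [p for p in self.profiles if p.group in wanted]
        return Cohort(self.panel, profs, wanted)

    def complete_profiles(self) -> list[Profile]:
        return [p for p in self.profiles if p.is_complete(self.panel)]


@dataclass
class FrequencyTable:
    """Per-marker genotype frequencies, e.g. estimated from a control sample.

    ``source_n`` records how many individuals each marker's frequencies
    derive from (0 when frequencies were supplied directly).
    """

    freqs: dict[str, dict[str, float]]
    source_n: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, dist in self.freqs.items():
            total = float(sum(dist.values()))
            if abs(total - 1.0) > 1e-9:
                raise CohortValidationError(
                    f"marker {gene}: genotype frequencies sum to {total!r}, expected 1")
            for gt, f in dist.items():
                if not (0.0 <= f <= 1.0):
                    raise CohortValidationError(
                        f"marker {gene} genotype {gt}: frequency {f!r} outside [0, 1]")

    def frequency(self, gene: str, genotype: str) -> float:
        try:
            return self.freqs[gene][genotype]
        except KeyError:
            raise CohortValidationError(
                f"no frequency for marker {gene!r} genotype {genotype!r}") from None


@dataclass
class EncodedMatrix:
    """Binary one-hot design matrix: one row per profile, one column per
    (marker, genotype) pair in panel x declared-label order."""

    data: np.ndarray
    columns: tuple[str, ...]        # "<gene>_<genotype>"
    keys: tuple[tuple[str, str], ...]  # (gene, genotype) per column
    sample_ids: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.sample_ids), columns=list(self.columns))


# ---------------------------------------------------------------------------
# IO

_REQUIRED_COLUMNS = ("sample_id", "sex", "group")


def _marker_column(marker: MarkerDef, header: Sequence[str]) -> str:
    """Match a panel marker to a file column by '<gene>_<rsid>' or bare gene name."""
    for cand in (marker.name, marker.gene):
        if cand in header:
            return cand
    raise CohortValidationError(f"missing required marker column for {marker.name}")


def read_cohort(path, panel: Sequence[MarkerDef], *, delimiter: str = ",",
                allow_missing: bool = False) -> Cohort:
    """Read a delimited cohort file into a validated :class:`Cohort`.

    The header must declare ``sample_id, sex, group`` plus one column per
    panel marker (``<gene>_<rsid>`` or the bare gene name).  Row order is
    preserved.  Unknown genotype labels raise with the offending row and
    marker; with ``allow_missing`` empty/NA cells mark the genotype missing
    instead of raising.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CohortValidationError(f"missing required column {col!r}")
    marker_cols = {m.gene: _marker_column(m, list(df.columns)) for m in panel}

    profiles: list[Profile] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        genotypes: dict[str, str | None] = {}
        for m in panel:
            raw = str(rowd[marker_cols[m.gene]]).strip()
            if raw in MISSING_VALUES:
                if not allow_missing:
                    raise CohortValidationError(
                        f"row {i + 1} (sample {rowd['sample_id']!r}): missing genotype "
                        f"for marker {m.gene}; pass allow_missing=True to accept")
                genotypes[m.gene] = None
            else:
                genotypes[m.gene] = raw
        profiles.append(Profile(
            sample_id=str(rowd["sample_id"]).strip(),
            sex=Sex.parse(rowd["sex"]),
            group=str(rowd["group"]).strip(),
            genotypes=genotypes,
        ))
    return Cohort(tuple(panel), profiles)


def write_cohort(cohort: Cohort, path, *, delimiter: str = ",") -> None:
    """Write a cohort in the same delimited layout :func:`read_cohort` accepts."""
    rows = []
    for p in cohort.profiles:
        row: dict[str, str] = {"sample_id": p.sample_id, "sex": p.sex.value, "group": p.group}
        for m in cohort.panel:
            gt = p.genotypes.get(m.gene)
            row[m.name] = "" if gt is None else gt
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def frequencies_from_counts(counts: Mapping[str, Mapping[str, int]]) -> FrequencyTable:
    """Turn per-marker genotype counts into frequencies (count / marker total).

    ``counts`` maps gene -> {genotype label -> non-negative count}.  The
    per-marker total is recorded as ``source_n``.  A marker whose counts sum
    to zero is an error.
    """
    freqs: dict[str, dict[str, float]] = {}
    source_n: dict[str, int] = {}
    for gene, dist in counts.items():
        vals = {gt: int(c) for gt, c in dist.items()}
        if any(c < 0 for c in vals.values()):
            raise CohortValidationError(f"marker {gene}: negative genotype count")
        total = sum(vals.values())
        if total == 0:
            raise CohortValidationError(f"marker {gene}: all genotype counts are zero")
        freqs[gene] = {gt: c / total for gt, c in vals.items()}
        source_n[gene] = total
    return FrequencyTable(freqs, source_n)


def read_frequency_table(path, panel: Sequence[MarkerDef], *, delimiter: str = ",") -> FrequencyTable:
    """Read ``gene,rsid,genotype,count`` or ``gene,rsid,genotype,frequency`` text."""
    df = pd.read_csv(path, sep=delimiter)
    if "count" in df.columns:
        counts: dict[str, dict[str, int]] = {}
        for _, r in df.iterrows():
            counts.setdefault(str(r["gene"]), {})[str(r["genotype"]).strip()] = int(r["count"])
        table = frequencies_from_counts(counts)
    elif "frequency" in df.columns:
        freqs: dict[str, dict[str, float]] = {}
        for _, r in df.iterrows():
            freqs.setdefault(str(r["gene"]), {})[str(r["genotype"]).strip()] = float(r["frequency"])
        table = FrequencyTable(freqs)
    else:
        raise CohortValidationError("frequency file needs a 'count' or 'frequency' column")
    for m in panel:
        for gt in m.genotype_labels:
            table.frequency(m.gene, gt)  # raises if absent
    return table


def write_frequency_table(table: FrequencyTable, path, panel: Sequence[MarkerDef], *,
                          delimiter: str = ",") -> None:
    rows = [{"gene": m.gene, "rsid": m.rsid, "genotype": gt,
             "frequency": table.frequency(m.gene, gt)}
            for m in panel for gt in m.genotype_labels]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Encoding

def one_hot_encode(cohort: Cohort, *, skip_incomplete: bool = False) -> EncodedMatrix:
    """One-hot encode genotypes: 3M binary columns for an M-marker panel.

    Each complete profile row contains exactly one 1 per marker block, so a
    4-marker profile such as (DD, RX, AG, CT) becomes the 12-dimensional
    vector (1,0,0, 0,1,0, 0,1,0, 0,1,0) under panel x declared-label column
    order.  Profiles with missing genotypes raise, or are excluded when
    ``skip_incomplete`` is set.
    """
    keys = tuple((m.gene, gt) for m in cohort.panel for gt in m.genotype_labels)
    columns = tuple(f"{g}_{gt}" for g, gt in keys)
    col_index = {k: j for j, k in enumerate(keys)}

    rows: list[np.ndarray] = []
    ids: list[str] = []
    for p in cohort.profiles:
        if not p.is_complete(cohort.panel):
            if skip_incomplete:
                continue
            raise CohortValidationError(
                f"sample {p.sample_id!r} has missing genotypes; "
                "encode with skip_incomplete=True to drop it")
        row = np.zeros(len(keys), dtype=np.int8)
        for m in cohort.panel:
            row[col_index[(m.gene, p.genotypes[m.gene])]] = 1
        rows.append(row)
        ids.append(p.sample_id)
    data = np.vstack(rows) if rows else np.zeros((0, len(keys)), dtype=np.int8)
    return EncodedMatrix(data=data, columns=columns, keys=keys, sample_ids=tuple(ids))
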
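"""Synthetic cohort generation and seeded recovery/power experiments.

Cohorts are simulated from per-group trinomial genotype distributions
(optionally Hardy–Weinberg proportions from an allele frequency), with
markers drawn independently — the same independence assumption the
combination-probability model makes.  The study-design generator emulates
the reference athlete cohort: 180 individuals in endurance/mixed/power
groups split by sex (27/6/17 females, 54/38/38 males), with each
(sex, group) cell drawing genotypes from its empirical distribution in the
bundled study counts.

``recovery_experiment`` plants a genotype-frequency shift in one group and
measures, over seeded replicates, how often the committee-derived score
recovers the planted direction and how often the TGS rank-sum comparison
rejects.  Per replicate the score table is derived on a training cohort
and the rank-sum test runs on an independently simulated evaluation
cohort: testing on the derivation cohort itself would inflate the type-I
error, since derived scores are optimized to separate the training groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .genotype_model import Cohort, MarkerDef, Profile, Sex
from .lr_scores import FitConfig, derive_score_table
from .stats import rank_sum_test
from .tgs_engine import ScoreTableError, score_cohort

__all__ = [
    "GroupSpec",
    "SimCohortConfig",
    "PlantedEffect",
    "RecoverySummary",
    "hwe_genotype_distribution",
    "simulate_cohort",
    "simulate_study_cohort",
    "recovery_experiment",
    "load_sim_config",
    "dump_sim_config",
]


def hwe_genotype_distribution(allele_freq: float) -> tuple[float, float, float]:
    """Hardy–Weinberg genotype proportions (p^2, 2p(1-p), (1-p)^2)."""
    p = float(allele_freq)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    q = 1.0 - p
    return (p * p, 2.0 * p * q, q * q)


@dataclass(frozen=True)
class GroupSpec:
    """One simulated trait group: size, sex composition and per-marker
    genotype distribution (gene -> 3 probabilities in declared label order)."""

    label: str
    size: int
    genotype_dists: Mapping[str, tuple[float, float, float]]
    sex_ratio: float = 0.5  # fraction female

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"group {self.label}: size must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError(f"group {self.label}: sex_ratio outside [0, 1]")
        for gene, dist in self.genotype_dists.items():
            if len(dist) != 3 or any(d < 0 for d in dist):
                raise ValueError(f"group {self.label}, marker {gene}: need 3 "
                                 "non-negative probabilities")
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"group {self.label}, marker {gene}: genotype "
                                 f"distribution sums to {sum(dist)}, expected 1")


@dataclass(frozen=True)
class SimCohortConfig:
    panel: tuple[MarkerDef, ...]
    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        genes = {m.gene for m in self.panel}
        for g in self.groups:
            missing = genes - set(g.genotype_dists)
            if missing:
                raise ValueError(f"group {g.label}: no genotype distribution "
                                 f"for markers {sorted(missing)}")


def _draw_group(rng: np.random.Generator, panel: Sequence[MarkerDef],
                spec: GroupSpec, id_prefix: str) -> list[Profile]:
    n_female = int(round(spec.size * spec.sex_ratio))
    sexes = [Sex.female] * n_female + [Sex.male] * (spec.size - n_female)
    draws = {m.gene: rng.choice(3, size=spec.size, p=np.asarray(spec.genotype_dists[m.gene]))
             for m in panel}
    profiles = []
    for i in range(spec.size):
        genotypes = {m.gene: m.genotype_labels[draws[m.gene][i]] for m in panel}
        profiles.append(Profile(f"{id_prefix}{i + 1:04d}", sexes[i], spec.label, genotypes))
    return profiles


def simulate_cohort(config: SimCohortConfig, *, seed: int | None = None) -> Cohort:
    """Draw a cohort: independent trinomial genotype draws per marker per
    individual from the group's distribution; reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    profiles: list[Profile] = []
    for gi, spec in enumerate(config.groups):
        profiles.extend(_draw_group(rng, config.panel, spec, f"G{gi}_{spec.label[:3].upper()}_"))
    return Cohort(config.panel, profiles, tuple(g.label for g in config.groups))


def simulate_study_cohort(seed: int = 0) -> Cohort:
    """Simulate a cohort matching the reference study design: exact
    (sex, group) cell sizes and genotype distributions equal to the bundled
    per-sex per-group athlete genotype proportions."""
    from . import reference

    panel = reference.study_panel()
    rng = np.random.default_rng(seed)
    profiles: list[Profile] = []
    idx = 0
    for (sex, group), n in reference.GROUP_SIZES.items():
        dists = {}
        for m in panel:
            cell = [reference.GROUP_SEX_GENOTYPE_COUNTS[m.gene][gt][(sex, group)]
                    for gt in m.genotype_labels]
            dists[m.gene] = np.asarray(cell, dtype=float) / sum(cell)
        draws = {m.gene: rng.choice(3, size=n, p=dists[m.gene]) for m in panel}
        for i in range(n):
            idx += 1
            genotypes = {m.gene: m.genotype_labels[draws[m.gene][i]] for m in panel}
            profiles.append(Profile(f"S{idx:04d}", Sex(sex), group, genotypes))
    return Cohort(panel, profiles, ("endurance", "power", "mixed"))


# ---------------------------------------------------------------------------
# Recovery / power experiments

@dataclass(frozen=True)
class PlantedEffect:
    """Raise one genotype's frequency by ``delta`` in one group; the other
    two genotype probabilities are rescaled proportionally."""

    gene: str
    genotype: str
    group: str
    delta: float


@dataclass
class RecoverySummary:
    replicates: int
    sign_recovery_rate: float   # fraction of replicates with correctly signed score
    rejection_rate: float       # fraction with rank-sum p < alpha on eval cohorts
    alpha: float
    ties: int = 0               # replicates where the committee returned a tie
    seeds: list[int] = field(default_factory=list)


def _apply_planting(config: SimCohortConfig, planted: PlantedEffect) -> SimCohortConfig:
    groups = []
    found = False
    for spec in config.groups:
        if spec.label != planted.group:
            groups.append(spec)
            continue
        found = True
        marker = next((m for m in config.panel if m.gene == planted.gene), None)
        if marker is None:
            raise ValueError(f"planted marker {planted.gene!r} not in panel")
        try:
            gi = marker.genotype_labels.index(planted.genotype)
        except ValueError:
            raise ValueError(f"planted genotype {planted.genotype!r} invalid "
                             f"for marker {planted.gene}") from None
        dist = list(spec.genotype_dists[planted.gene])
        target = dist[gi] + planted.delta
        rest = 1.0 - dist[gi]
        if not 0.0 <= target <= 1.0 or (rest == 0.0 and planted.delta != 0.0):
            raise ValueError(f"planting delta={planted.delta} makes genotype "
                             "probabilities invalid")
        scale = (1.0 - target) / rest if rest > 0 else 0.0
        new = [target if j == gi else d * scale for j, d in enumerate(dist)]
        dists = dict(spec.genotype_dists)
        dists[planted.gene] = tuple(new)
        groups.append(replace(spec, genotype_dists=dists))
    if not found:
        raise ValueError(f"planted group {planted.group!r} not in config")
    return replace(config, groups=tuple(groups))


def recovery_experiment(base_config: SimCohortConfig, planted: PlantedEffect,
                        replicates: int, *, alpha: float = 0.05,
                        fit_config: FitConfig | None = None,
                        compare_groups: tuple[str, str] | None = None,
                        trait_map: Mapping[str, str] | None = None) -> RecoverySummary:
    """Seeded end-to-end recovery experiment.

    Per replicate: simulate a training cohort under the planted design,
    derive committee scores, check the planted genotype's score sign
    against the planted direction (positive for an endurance-group
    enrichment, negative for power), then score an independently simulated
    evaluation cohort and run the TGS rank-sum comparison between
    ``compare_groups`` (default: the planted group vs the trait-opposite
    group).  Aggregates the sign-recovery and rejection rates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from .lr_scores import DEFAULT_TRAIT_MAP

    tmap = {k.lower(): v for k, v in (trait_map or DEFAULT_TRAIT_MAP).items()}
    planted_trait = tmap.get(planted.group.lower())
    if planted_trait not in ("End", "Pow"):
        raise ValueError("planted group must map to the End or Pow trait for a "
                         "signed-recovery readout")
    expected_sign = 1.0 if planted_trait == "End" else -1.0
    if compare_groups is None:
        opposite = "Pow" if planted_trait == "End" else "End"
        by_trait = {tmap[g.label.lower()]: g.label for g in base_config.groups}
        compare_groups = (planted.group, by_trait[opposite])

    config = _apply_planting(base_config, planted)
    rng = np.random.default_rng(base_config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * replicates)

    correct = rejected = ties = 0
    for r in range(replicates):
        train = simulate_cohort(config, seed=int(seeds[2 * r]))
        table, decisions, _ = derive_score_table(train, fit_config, trait_map=trait_map)
        dec = next(d for d in decisions
                   if d.gene == planted.gene and d.genotype == planted.genotype)
        if dec.winning_trait == "tie":
            ties += 1
        if dec.score * expected_sign > 0:
            correct += 1
        eval_cohort = simulate_cohort(config, seed=int(seeds[2 * r + 1]))
        try:
            results = score_cohort(eval_cohort, table)
        except ScoreTableError:
            # all-zero derived table (every genotype mixed/tied): the TGS is
            # constant, carries no information, and cannot reject
            continue
        by_id = {p.sample_id: p.group for p in eval_cohort.profiles}
        a = [res.normalized for res in results if by_id[res.sample_id] == compare_groups[0]]
        b = [res.normalized for res in results if by_id[res.sample_id] == compare_groups[1]]
        if len(set(a + b)) > 1 and rank_sum_test(a, b).p_value < alpha:
            rejected += 1
    return RecoverySummary(replicates, correct / replicates, rejected / replicates,
                           alpha, ties, [int(s) for s in seeds])


# ---------------------------------------------------------------------------
# Config file IO (YAML: panel + per-group nested genotype distributions)

def load_sim_config(path) -> SimCohortConfig:
    """Read a simulation design from YAML.

    Layout::

        seed: 7
        panel:
          - {gene: ACE, rsid: rs1799752, genotypes: [DD, ID, II]}
        groups:
          - label: endurance
            size: 80
            sex_ratio: 0.4
            markers:
              ACE: {distribution: [0.3, 0.45, 0.25]}
              # or: ACE: {allele_freq: 0.55, hwe: true}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    panel = tuple(MarkerDef(m["gene"], m.get("rsid", ""), tuple(m["genotypes"]))
                  for m in doc["panel"])
    groups = []
    for g in doc["groups"]:
        dists = {}
        for gene, spec in g["markers"].items():
            if spec.get("hwe"):
                dists[gene] = hwe_genotype_distribution(float(spec["allele_freq"]))
            else:
                dists[gene] = tuple(float(x) for x in spec["distribution"])
        groups.append(GroupSpec(str(g["label"]), int(g["size"]), dists,
                                float(g.get("sex_ratio", 0.5))))
    return SimCohortConfig(panel, tuple(groups), int(doc.get("seed", 0)))


def dump_sim_config(config: SimCohortConfig, path) -> None:
    doc = {
        "seed": config.seed,
        "panel": [{"gene": m.gene, "rsid": m.rsid, "genotypes": list(m.genotype_labels)}
                  for m in config.panel],
        "groups": [{
            "label": g.label, "size": g.size, "sex_ratio": g.sex_ratio,
            "markers": {gene: {"distribution": [float(x) for x in dist]}
                        for gene, dist in g.genotype_dists.items()},
        } for g in config.groups],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
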
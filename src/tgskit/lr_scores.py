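"""Data-driven genotype-score derivation from pairwise logistic classifiers.

Three binary logistic-regression classifiers are fitted on one-hot genotype
features: endurance(1) vs power(0), endurance(1) vs mixed(0) and
power(1) vs mixed(0).  Because the features are binary indicators, each
coefficient b alone measures how strongly its genotype pushes the decision
toward class 1 (b > 0) or class 0 (b < 0); ``sigmoid(b)`` is the implied
single-genotype class probability.

The three classifiers then act as a committee voting on every genotype's
trait direction.  The majority trait wins; a genotype assigned to the
endurance (power) trait receives a positive (negative) score whose
magnitude is the mean absolute coefficient over the classifiers that voted
for the winner, and a mixed-majority genotype scores 0 by construction of
the endurance(+1)/mixed(0)/power(-1) TGS axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .genotype_model import Cohort, EncodedMatrix, one_hot_encode
from .tgs_engine import GenotypeScoreTable, ScoreEntry

__all__ = [
    "FitConfig",
    "PairwiseFit",
    "CVReport",
    "CommitteeDecision",
    "PAIR_CLASSES",
    "DEFAULT_TRAIT_MAP",
    "fit_pairwise",
    "class_probability",
    "cross_validate",
    "vote_of",
    "committee_scores",
    "derive_score_table",
]

#: classifier name -> (class 1 trait, class 0 trait)
PAIR_CLASSES: dict[str, tuple[str, str]] = {
    "E_vs_P": ("End", "Pow"),
    "E_vs_M": ("End", "Mix"),
    "P_vs_M": ("Pow", "Mix"),
}

#: default cohort group label -> trait label mapping
DEFAULT_TRAIT_MAP: dict[str, str] = {
    "endurance": "End", "end": "End",
    "mixed": "Mix", "mix": "Mix",
    "power": "Pow", "pow": "Pow",
}


@dataclass(frozen=True)
class FitConfig:
    """Fitting settings for the pairwise classifiers.

    ``penalty_strength`` is the L2 regularization weight lambda; the
    classifier is fitted with inverse-regularization C = 1/lambda, so the
    default 1.0 matches the common library default.  Derived score
    magnitudes depend on it, which is why it is exposed.
    """

    penalty: Literal["l2", "none"] = "l2"
    penalty_strength: float = 1.0
    fit_intercept: bool = True
    max_iter: int = 2000
    tolerance: float = 1e-8
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.penalty_strength <= 0:
            raise ValueError("penalty_strength must be > 0")


@dataclass
class PairwiseFit:
    """Fitted binary classifier: intercept b0 plus one coefficient per
    (marker, genotype) column and its implied class probability sigmoid(b)."""

    class1_label: str
    class0_label: str
    intercept: float
    coefficients: dict[tuple[str, str], float]
    class_probabilities: dict[tuple[str, str], float]

    @property
    def pair(self) -> tuple[str, str]:
        return (self.class1_label, self.class0_label)


@dataclass
class CVReport:
    fold_accuracies: list[float]
    mean: float
    sd: float
    confusion: np.ndarray  # 2x2, rows = actual (class0, class1), cols = predicted

    def __post_init__(self) -> None:
        acc = np.asarray(self.fold_accuracies, dtype=float)
        if not (np.isclose(self.mean, acc.mean()) and np.isclose(self.sd, acc.std(ddof=1))):
            raise ValueError("CVReport mean/sd inconsistent with fold accuracies")


@dataclass
class CommitteeDecision:
    """How the three classifiers voted on one genotype, and the resulting score."""

    gene: str
    genotype: str
    votes: tuple[str, str, str]  # trait voted by E_vs_P, E_vs_M, P_vs_M ("abstain" if b=0)
    winning_trait: str           # "End" | "Mix" | "Pow" | "tie"
    supporting_magnitudes: list[float] = field(default_factory=list)
    score: float = 0.0


def class_probability(b):
    """Single-coefficient class probability ``1 / (1 + exp(-b))``."""
    return 1.0 / (1.0 + np.exp(-np.asarray(b, dtype=float))) if np.ndim(b) else \
        float(1.0 / (1.0 + np.exp(-float(b))))


def _make_estimator(config: FitConfig) -> LogisticRegression:
    # an unpenalized fit is the C -> inf limit of the default L2 penalty
    return LogisticRegression(
        C=np.inf if config.penalty == "none" else 1.0 / config.penalty_strength,
        fit_intercept=config.fit_intercept,
        max_iter=config.max_iter,
        tol=config.tolerance,
        solver="lbfgs",
    )


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes in labels, got {classes.tolist()}")
    return y


def fit_pairwise(encoded: EncodedMatrix, labels: Sequence[int],
                 class1_label: str, class0_label: str,
                 config: FitConfig | None = None) -> PairwiseFit:
    """Fit one regularized binary logistic classifier on one-hot features.

    ``labels`` are 0/1 per row of ``encoded`` (1 = ``class1_label``).  All
    three genotype columns per marker are kept (no reference level); the L2
    penalty keeps the fit unique despite the resulting collinearity.
    """
    config = config or FitConfig()
    y = _check_labels(np.asarray(labels, dtype=int))
    if len(y) != encoded.data.shape[0]:
        raise ValueError("labels do not align with encoded rows")
    est = _make_estimator(config)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            est.fit(encoded.data, y)
        except ConvergenceWarning as exc:  # pragma: no cover - lbfgs+L2 converges
            raise RuntimeError(
                f"logistic fit did not converge in {config.max_iter} iterations: {exc}")
    coeffs = {key: float(b) for key, b in zip(encoded.keys, est.coef_[0])}
    return PairwiseFit(
        class1_label=class1_label, class0_label=class0_label,
        intercept=float(est.intercept_[0]) if config.fit_intercept else 0.0,
        coefficients=coeffs,
        class_probabilities={k: class_probability(b) for k, b in coeffs.items()},
    )


def cross_validate(encoded: EncodedMatrix, labels: Sequence[int],
                   config: FitConfig | None = None, *,
                   confusion_mode: Literal["resubstitution", "pooled_cv"] = "resubstitution",
                   ) -> CVReport:
    """Stratified k-fold held-out accuracy plus a pooled confusion table.

    The confusion table defaults to the final classifier trained on all
    data and evaluated on all data (resubstitution); ``pooled_cv`` pools
    held-out predictions across folds instead.
    """
    config = config or FitConfig()
    y = _check_labels(np.asarray(labels, dtype=int))
    counts = np.bincount(y)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than cv_folds={config.cv_folds}")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    accs: list[float] = []
    pooled_pred = np.empty_like(y)
    for train, test in skf.split(encoded.data, y):
        est = _make_estimator(config)
        est.fit(encoded.data[train], y[train])
        pred = est.predict(encoded.data[test])
        pooled_pred[test] = pred
        accs.append(float(np.mean(pred == y[test])))
    if confusion_mode == "resubstitution":
        final = _make_estimator(config)
        final.fit(encoded.data, y)
        pred_all = final.predict(encoded.data)
    else:
        pred_all = pooled_pred
    conf = confusion_matrix(y, pred_all, labels=[0, 1])
    acc = np.asarray(accs)
    return CVReport(accs, float(acc.mean()), float(acc.std(ddof=1)), conf)


def vote_of(b: float, pair: tuple[str, str]) -> str:
    """Trait a single coefficient votes for: b > 0 backs class 1's trait,
    b < 0 class 0's trait, b = 0 abstains."""
    if tuple(pair) not in PAIR_CLASSES.values():
        raise ValueError(f"unknown classifier pair {pair!r}; expected one of "
                         f"{sorted(PAIR_CLASSES.values())}")
    if b > 0:
        return pair[0]
    if b < 0:
        return pair[1]
    return "abstain"


def _majority(votes: Sequence[str]) -> str:
    cast = [v for v in votes if v != "abstain"]
    if not cast:
        return "tie"
    counts: dict[str, int] = {}
    for v in cast:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    winners = [t for t, c in counts.items() if c == best]
    if len(winners) > 1 or (best == 1 and len(cast) > 1):
        return "tie"
    return winners[0]


def committee_scores(fit_ep: PairwiseFit, fit_em: PairwiseFit, fit_pm: PairwiseFit,
                     panel, *, mixed_mode: Literal["zero", "signed_mean"] = "zero",
                     provenance: str = "derived",
                     ) -> tuple[GenotypeScoreTable, list[CommitteeDecision]]:
    """Combine the three pairwise fits into a signed genotype-score table.

    For each genotype the three coefficient signs vote on a trait.  The
    majority trait wins; an endurance (power) win scores +(-) the mean of
    the absolute coefficients of the supporting classifiers; a mixed win
    scores 0 under the default rule.  ``mixed_mode="signed_mean"`` instead
    scores a mixed win as the signed mean of the supporting coefficients —
    this departs from the stated rule but matches one published table entry
    (see package docs).  Three-way splits are ties: score 0, flagged, and
    warned about.
    """
    fits = (fit_ep, fit_em, fit_pm)
    expected_pairs = tuple(PAIR_CLASSES.values())
    for f, exp in zip(fits, expected_pairs):
        if f.pair != exp:
            raise ValueError(f"classifier pair {f.pair} given where {exp} expected")
    keysets = [set(f.coefficients) for f in fits]
    if not (keysets[0] == keysets[1] == keysets[2]):
        raise ValueError("the three fits do not share one panel encoding")

    entries: dict[tuple[str, str], ScoreEntry] = {}
    decisions: list[CommitteeDecision] = []
    for m in panel:
        for gt in m.genotype_labels:
            key = (m.gene, gt)
            bs = [f.coefficients[key] for f in fits]
            votes = tuple(vote_of(b, f.pair) for b, f in zip(bs, fits))
            winner = _majority(votes)
            supporting = [abs(b) for b, v in zip(bs, votes) if v == winner]
            if winner == "End":
                score = float(np.mean(supporting))
            elif winner == "Pow":
                score = -float(np.mean(supporting))
            elif winner == "Mix":
                if mixed_mode == "signed_mean":
                    score = float(np.mean([b for b, v in zip(bs, votes) if v == "Mix"]))
                else:
                    score = 0.0
            else:  # tie
                warnings.warn(f"{m.gene} {gt}: no committee majority "
                              f"(votes {votes}); score set to 0", stacklevel=2)
                score, supporting = 0.0, []
            decisions.append(CommitteeDecision(m.gene, gt, votes, winner, supporting, score))
            trait = winner if winner in ("End", "Mix", "Pow") else "Mix"
            entries[key] = ScoreEntry(score, trait, provenance)
    return GenotypeScoreTable(tuple(panel), entries, convention="weighted"), decisions


def derive_score_table(cohort: Cohort, config: FitConfig | None = None, *,
                       trait_map: Mapping[str, str] | None = None,
                       mixed_mode: Literal["zero", "signed_mean"] = "zero",
                       with_cv: bool = False):
    """End-to-end derivation: encode a 3-group cohort, fit the three pairwise
    classifiers, and apply the committee rule.

    Returns ``(table, decisions, fits)`` or, with ``with_cv``,
    ``(table, decisions, fits, cv_reports)`` where ``fits`` and
    ``cv_reports`` are keyed by classifier name (E_vs_P, E_vs_M, P_vs_M).
    """
    config = config or FitConfig()
    tmap = {k.lower(): v for k, v in (trait_map or DEFAULT_TRAIT_MAP).items()}
    group_by_trait: dict[str, str] = {}
    for g in cohort.group_labels:
        trait = tmap.get(g.lower())
        if trait is None:
            raise ValueError(f"cannot map cohort group {g!r} to a trait; pass trait_map")
        group_by_trait[trait] = g

    fits: dict[str, PairwiseFit] = {}
    cv_reports: dict[str, CVReport] = {}
    for pair_name, (t1, t0) in PAIR_CLASSES.items():
        sub = cohort.subset([group_by_trait[t0], group_by_trait[t1]])
        enc = one_hot_encode(sub, skip_incomplete=True)
        kept = {p.sample_id: p for p in sub.complete_profiles()}
        y = np.array([1 if tmap[kept[sid].group.lower()] == t1 else 0
                      for sid in enc.sample_ids], dtype=int)
        fits[pair_name] = fit_pairwise(enc, y, t1, t0, config)
        if with_cv:
            cv_reports[pair_name] = cross_validate(enc, y, config)
    table, decisions = committee_scores(
        fits["E_vs_P"], fits["E_vs_M"], fits["P_vs_M"], cohort.panel, mixed_mode=mixed_mode)
    if with_cv:
        return table, decisions, fits, cv_reports
    return table, decisions, fits
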
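"""Bundled reference data: the four-marker endurance/power panel with
published pairwise logistic-regression coefficients and case–control
genotype counts from a study of 180 Lithuanian elite athletes (endurance /
mixed / power) and 255 population controls.

These values let every pipeline stage run without the study's per-athlete
genotype data, which are not redistributed here: the committee rule can be
replayed on the printed coefficients, population genotype frequencies can
be rebuilt from the control counts, and the synthetic-cohort generator can
emulate the study's per-sex per-group genotype composition.
"""

from __future__ import annotations

from .genotype_model import FrequencyTable, MarkerDef, frequencies_from_counts

__all__ = [
    "study_panel",
    "PAIRWISE_COEFFICIENTS",
    "ATHLETE_GENOTYPE_COUNTS",
    "CONTROL_GENOTYPE_COUNTS",
    "WF_TRAIT_ANNOTATION",
    "GROUP_SEX_GENOTYPE_COUNTS",
    "GROUP_SIZES",
    "control_frequencies",
    "pairwise_fits",
]


def study_panel() -> tuple[MarkerDef, ...]:
    """The ACE / ACTN3 / MB / AMPD1 panel in its canonical order."""
    return (
        MarkerDef("ACE", "rs1799752", ("DD", "ID", "II")),
        MarkerDef("ACTN3", "rs1815739", ("RR", "RX", "XX")),
        MarkerDef("MB", "rs7293", ("AA", "AG", "GG")),
        MarkerDef("AMPD1", "rs17602729", ("CC", "CT", "TT")),
    )


#: Coefficients b of the three pairwise logistic classifiers fitted on the
#: athlete cohort (class coding: E(1) vs P(0), E(1) vs M(0), P(1) vs M(0)),
#: one per one-hot genotype column, as published to 3 decimals.
PAIRWISE_COEFFICIENTS: dict[str, dict[tuple[str, str], float]] = {
    "E_vs_P": {
        ("ACTN3", "RR"): -0.080, ("ACTN3", "RX"): 0.289, ("ACTN3", "XX"): -0.209,
        ("AMPD1", "CC"): 0.288, ("AMPD1", "CT"): 0.062, ("AMPD1", "TT"): -0.350,
        ("MB", "AA"): 0.088, ("MB", "AG"): 0.223, ("MB", "GG"): -0.311,
        ("ACE", "DD"): 0.415, ("ACE", "ID"): 0.194, ("ACE", "II"): -0.610,
    },
    "E_vs_M": {
        ("ACTN3", "RR"): -0.199, ("ACTN3", "RX"): 0.241, ("ACTN3", "XX"): -0.041,
        ("AMPD1", "CC"): 0.222, ("AMPD1", "CT"): -0.453, ("AMPD1", "TT"): 0.230,
        ("MB", "AA"): 0.117, ("MB", "AG"): 0.095, ("MB", "GG"): -0.212,
        ("ACE", "DD"): 0.418, ("ACE", "ID"): -0.044, ("ACE", "II"): -0.374,
    },
    "P_vs_M": {
        ("ACTN3", "RR"): 0.039, ("ACTN3", "RX"): -0.071, ("ACTN3", "XX"): 0.032,
        ("AMPD1", "CC"): -0.047, ("AMPD1", "CT"): -0.403, ("AMPD1", "TT"): 0.451,
        ("MB", "AA"): -0.068, ("MB", "AG"): -0.125, ("MB", "GG"): 0.194,
        ("ACE", "DD"): -0.071, ("ACE", "ID"): -0.250, ("ACE", "II"): 0.321,
    },
}

#: Published class-probability column (sigmoid of the unrounded coefficients).
PAIRWISE_CLASS_PROBABILITIES: dict[str, dict[tuple[str, str], float]] = {
    "E_vs_P": {
        ("ACTN3", "RR"): 0.479, ("ACTN3", "RX"): 0.571, ("ACTN3", "XX"): 0.447,
        ("AMPD1", "CC"): 0.571, ("AMPD1", "CT"): 0.515, ("AMPD1", "TT"): 0.413,
        ("MB", "AA"): 0.522, ("MB", "AG"): 0.555, ("MB", "GG"): 0.422,
        ("ACE", "DD"): 0.602, ("ACE", "ID"): 0.548, ("ACE", "II"): 0.351,
    },
    "E_vs_M": {
        ("ACTN3", "RR"): 0.450, ("ACTN3", "RX"): 0.560, ("ACTN3", "XX"): 0.489,
        ("AMPD1", "CC"): 0.555, ("AMPD1", "CT"): 0.388, ("AMPD1", "TT"): 0.557,
        ("MB", "AA"): 0.529, ("MB", "AG"): 0.523, ("MB", "GG"): 0.447,
        ("ACE", "DD"): 0.603, ("ACE", "ID"): 0.488, ("ACE", "II"): 0.407,
    },
    "P_vs_M": {
        ("ACTN3", "RR"): 0.509, ("ACTN3", "RX"): 0.482, ("ACTN3", "XX"): 0.508,
        ("AMPD1", "CC"): 0.488, ("AMPD1", "CT"): 0.400, ("AMPD1", "TT"): 0.610,
        ("MB", "AA"): 0.482, ("MB", "AG"): 0.468, ("MB", "GG"): 0.548,
        ("ACE", "DD"): 0.482, ("ACE", "ID"): 0.437, ("ACE", "II"): 0.579,
    },
}

#: Genotype counts in the athlete cohort (n=180) and population controls (n=255).
ATHLETE_GENOTYPE_COUNTS: dict[str, dict[str, int]] = {
    "ACE": {"DD": 46, "ID": 84, "II": 50},
    "ACTN3": {"RR": 56, "RX": 102, "XX": 22},
    "AMPD1": {"CC": 133, "CT": 45, "TT": 2},
    "MB": {"AA": 35, "AG": 116, "GG": 29},
}

CONTROL_GENOTYPE_COUNTS: dict[str, dict[str, int]] = {
    "ACE": {"DD": 63, "ID": 94, "II": 98},
    "ACTN3": {"RR": 104, "RX": 125, "XX": 26},
    "AMPD1": {"CC": 184, "CT": 65, "TT": 6},
    "MB": {"AA": 69, "AG": 116, "GG": 70},
}

#: Literature-based trait direction per genotype for the Williams–Folland model
#: (End -> 2, Mix -> 1, Pow -> 0).
WF_TRAIT_ANNOTATION: dict[tuple[str, str], str] = {
    ("ACE", "DD"): "End", ("ACE", "ID"): "Mix", ("ACE", "II"): "Pow",
    ("ACTN3", "RR"): "End", ("ACTN3", "RX"): "Mix", ("ACTN3", "XX"): "Pow",
    ("AMPD1", "CC"): "End", ("AMPD1", "CT"): "Mix", ("AMPD1", "TT"): "Pow",
    ("MB", "AA"): "End", ("MB", "AG"): "Mix", ("MB", "GG"): "Pow",
}

#: Athlete counts per genotype, split by sex and sport group
#: (gene -> genotype -> (sex, group) -> count).  Column sums give the study
#: design: females 27/6/17 and males 54/38/38 across endurance/power/mixed.
GROUP_SEX_GENOTYPE_COUNTS: dict[str, dict[str, dict[tuple[str, str], int]]] = {
    "ACE": {
        "DD": {("female", "endurance"): 10, ("female", "power"): 2, ("female", "mixed"): 4,
               ("male", "endurance"): 15, ("male", "power"): 7, ("male", "mixed"): 8},
        "ID": {("female", "endurance"): 15, ("female", "power"): 1, ("female", "mixed"): 7,
               ("male", "endurance"): 24, ("male", "power"): 16, ("male", "mixed"): 21},
        "II": {("female", "endurance"): 2, ("female", "power"): 3, ("female", "mixed"): 6,
               ("male", "endurance"): 15, ("male", "power"): 15, ("male", "mixed"): 9},
    },
    "ACTN3": {
        "RR": {("female", "endurance"): 9, ("female", "power"): 4, ("female", "mixed"): 3,
               ("male", "endurance"): 13, ("male", "power"): 12, ("male", "mixed"): 15},
        "RX": {("female", "endurance"): 15, ("female", "power"): 2, ("female", "mixed"): 12,
               ("male", "endurance"): 35, ("male", "power"): 20, ("male", "mixed"): 18},
        "XX": {("female", "endurance"): 3, ("female", "power"): 0, ("female", "mixed"): 2,
               ("male", "endurance"): 6, ("male", "power"): 6, ("male", "mixed"): 5},
    },
    "MB": {
        "AA": {("female", "endurance"): 8, ("female", "power"): 0, ("female", "mixed"): 5,
               ("male", "endurance"): 8, ("male", "power"): 9, ("male", "mixed"): 5},
        "AG": {("female", "endurance"): 16, ("female", "power"): 1, ("female", "mixed"): 10,
               ("male", "endurance"): 38, ("male", "power"): 25, ("male", "mixed"): 26},
        "GG": {("female", "endurance"): 3, ("female", "power"): 5, ("female", "mixed"): 2,
               ("male", "endurance"): 8, ("male", "power"): 4, ("male", "mixed"): 7},
    },
    "AMPD1": {
        "CC": {("female", "endurance"): 20, ("female", "power"): 3, ("female", "mixed"): 11,
               ("male", "endurance"): 43, ("male", "power"): 30, ("male", "mixed"): 26},
        "CT": {("female", "endurance"): 7, ("female", "power"): 2, ("female", "mixed"): 6,
               ("male", "endurance"): 10, ("male", "power"): 18, ("male", "mixed"): 12},
        "TT": {("female", "endurance"): 0, ("female", "power"): 1, ("female", "mixed"): 0,
               ("male", "endurance"): 1, ("male", "power"): 0, ("male", "mixed"): 0},
    },
}

#: Study group sizes per (sex, group).
GROUP_SIZES: dict[tuple[str, str], int] = {
    ("female", "endurance"): 27, ("female", "power"): 6, ("female", "mixed"): 17,
    ("male", "endurance"): 54, ("male", "power"): 38, ("male", "mixed"): 38,
}


def control_frequencies() -> FrequencyTable:
    """Population genotype frequencies from the control counts (n=255)."""
    return frequencies_from_counts(CONTROL_GENOTYPE_COUNTS)


def pairwise_fits():
    """The three published pairwise classifiers as :class:`PairwiseFit` objects.

    Coefficients are the printed 3-decimal values; intercepts are not
    published and are set to 0 (they do not enter score derivation).
    """
    from .lr_scores import PAIR_CLASSES, PairwiseFit, class_probability

    fits = {}
    for pair_name, (class1, class0) in PAIR_CLASSES.items():
        coeffs = dict(PAIRWISE_COEFFICIENTS[pair_name])
        fits[pair_name] = PairwiseFit(
            class1_label=class1, class0_label=class0, intercept=0.0,
            coefficients=coeffs,
            class_probabilities={k: class_probability(b) for k, b in coeffs.items()},
        )
    return fits["E_vs_P"], fits["E_vs_M"], fits["P_vs_M"]
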
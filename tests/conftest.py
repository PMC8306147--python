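import numpy as np
import pytest

from tgskit import reference
from tgskit.genotype_model import Cohort, MarkerDef, Profile, Sex


@pytest.fixture(scope="session")
def study_panel():
    return reference.study_panel()


@pytest.fixture(scope="session")
def toy_panel():
    return (MarkerDef("ACE", "rs1799752", ("DD", "ID", "II")),)


@pytest.fixture(scope="session")
def reference_fits():
    """The three pairwise classifiers rebuilt from the bundled coefficients."""
    return reference.pairwise_fits()


def make_profile(panel, genotypes, sample_id="s1", sex=Sex.unknown, group="endurance"):
    return Profile(sample_id, sex, group,
                   {m.gene: gt for m, gt in zip(panel, genotypes)})


@pytest.fixture(scope="session")
def random_cohort(study_panel):
    """60 individuals with uniform random genotypes in three groups."""
    rng = np.random.default_rng(42)
    profiles = []
    groups = ["endurance", "mixed", "power"]
    for i in range(60):
        genotypes = {m.gene: m.genotype_labels[rng.integers(3)] for m in study_panel}
        profiles.append(Profile(f"r{i:03d}", Sex.female if i % 2 else Sex.male,
                                groups[i % 3], genotypes))
    return Cohort(study_panel, profiles)
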
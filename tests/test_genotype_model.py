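import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from tgskit import reference
from tgskit.genotype_model import (
    Cohort,
    CohortValidationError,
    MarkerDef,
    Profile,
    Sex,
    frequencies_from_counts,
    one_hot_encode,
    read_cohort,
    read_frequency_table,
    write_cohort,
    write_frequency_table,
)
from tgskit.simulate import simulate_study_cohort

from conftest import make_profile


class TestMarkerDef:
    def test_requires_three_distinct_labels(self):
        with pytest.raises(CohortValidationError):
            MarkerDef("ACE", "rs1", ("DD", "DD", "II"))

    def test_labels_are_trimmed_not_reordered(self):
        m = MarkerDef("ACE", "rs1", (" DD", "ID ", "II"))
        assert m.genotype_labels == ("DD", "ID", "II")


class TestReadCohort:
    def test_minimal_csv_roundtrip(self, toy_panel, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("sample_id,sex,group,ACE_rs1799752\na,F,endurance,DD\nb,M,power,II\n")
        cohort = read_cohort(f, toy_panel)
        assert len(cohort) == 2
        assert cohort.profiles[0].genotypes["ACE"] == "DD"
        assert cohort.profiles[1].sex is Sex.male
        out = tmp_path / "out.csv"
        write_cohort(cohort, out)
        again = read_cohort(out, toy_panel)
        for p, q in zip(cohort.profiles, again.profiles):
            assert (p.sample_id, p.sex, p.group, p.genotypes) == \
                   (q.sample_id, q.sex, q.group, q.genotypes)

    def test_invalid_genotype_label_names_row_and_marker(self, toy_panel, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("sample_id,sex,group,ACE_rs1799752\na,F,endurance,ZZ\n")
        with pytest.raises(CohortValidationError, match="ZZ") as exc:
            read_cohort(f, toy_panel)
        assert "ACE" in str(exc.value)

    def test_duplicate_sample_id_rejected(self, toy_panel, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("sample_id,sex,group,ACE_rs1799752\na,F,endurance,DD\na,M,power,II\n")
        with pytest.raises(CohortValidationError, match="duplicate"):
            read_cohort(f, toy_panel)

    def test_missing_required_column_rejected(self, toy_panel, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("sample_id,sex,ACE_rs1799752\na,F,DD\n")
        with pytest.raises(CohortValidationError, match="group"):
            read_cohort(f, toy_panel)

    def test_missing_genotype_error_unless_allowed(self, toy_panel, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("sample_id,sex,group,ACE_rs1799752\na,F,endurance,\n")
        with pytest.raises(CohortValidationError, match="missing"):
            read_cohort(f, toy_panel)
        cohort = read_cohort(f, toy_panel, allow_missing=True)
        assert not cohort.profiles[0].is_complete(toy_panel)
        assert one_hot_encode(cohort, skip_incomplete=True).data.shape == (0, 3)

    def test_study_design_cohort_has_published_group_sizes(self, study_panel, tmp_path):
        # 180 individuals, 4 markers, groups endurance/power/mixed = 81/44/55
        cohort = simulate_study_cohort(seed=5)
        f = tmp_path / "study.csv"
        write_cohort(cohort, f)
        again = read_cohort(f, study_panel)
        assert len(again) == 180
        assert again.group_sizes() == {"endurance": 81, "power": 44, "mixed": 55}


class TestFrequencies:
    def test_control_counts_give_published_frequencies(self):
        table = frequencies_from_counts(reference.CONTROL_GENOTYPE_COUNTS)
        ace = table.freqs["ACE"]
        assert (round(ace["DD"], 3), round(ace["ID"], 3), round(ace["II"], 3)) == \
               (0.247, 0.369, 0.384)
        ampd = table.freqs["AMPD1"]
        assert (round(ampd["CC"], 3), round(ampd["CT"], 3), round(ampd["TT"], 3)) == \
               (0.722, 0.255, 0.024)
        assert table.source_n == {"ACE": 255, "ACTN3": 255, "MB": 255, "AMPD1": 255}

    def test_degenerate_distribution(self):
        t = frequencies_from_counts({"ACE": {"DD": 5, "ID": 0, "II": 0}})
        assert t.freqs["ACE"] == {"DD": 1.0, "ID": 0.0, "II": 0.0}

    def test_all_zero_marker_rejected(self):
        with pytest.raises(CohortValidationError, match="zero"):
            frequencies_from_counts({"ACE": {"DD": 0, "ID": 0, "II": 0}})

    @given(counts=hst.lists(hst.integers(0, 10_000), min_size=3, max_size=3)
           .filter(lambda c: sum(c) > 0))
    @settings(max_examples=50, derandomize=True)
    def test_frequencies_sum_to_one(self, counts):
        t = frequencies_from_counts({"M": dict(zip("abc", counts))})
        assert abs(sum(t.freqs["M"].values()) - 1.0) < 1e-12

    def test_frequency_file_roundtrip(self, study_panel, tmp_path):
        table = frequencies_from_counts(reference.CONTROL_GENOTYPE_COUNTS)
        f = tmp_path / "freqs.csv"
        write_frequency_table(table, f, study_panel)
        again = read_frequency_table(f, study_panel)
        for m in study_panel:
            for gt in m.genotype_labels:
                assert again.frequency(m.gene, gt) == pytest.approx(
                    table.frequency(m.gene, gt), abs=1e-12)


class TestOneHot:
    def test_worked_twelve_dimensional_example(self, study_panel):
        # (DD, RX, AG, CT) on the 4-marker panel -> (1,0,0, 0,1,0, 0,1,0, 0,1,0)
        p = make_profile(study_panel, ("DD", "RX", "AG", "CT"))
        enc = one_hot_encode(Cohort(study_panel, [p]))
        assert enc.data.shape == (1, 12)
        assert enc.data[0].tolist() == [1, 0, 0, 0, 1, 0, 0, 1, 0, 0, 1, 0]
        assert enc.columns[0] == "ACE_DD"

    def test_single_marker_second_label(self, toy_panel):
        p = make_profile(toy_panel, ("ID",))
        enc = one_hot_encode(Cohort(toy_panel, [p]))
        assert enc.data[0].tolist() == [0, 1, 0]

    def test_every_row_sums_to_marker_count(self, random_cohort):
        enc = one_hot_encode(random_cohort)
        assert (enc.data.sum(axis=1) == len(random_cohort.panel)).all()
        # one 1 per marker block
        for block in range(4):
            assert (enc.data[:, 3 * block:3 * block + 3].sum(axis=1) == 1).all()

    @given(choice=hst.lists(hst.integers(0, 2), min_size=4, max_size=4),
           other=hst.lists(hst.integers(0, 2), min_size=4, max_size=4))
    @settings(max_examples=50, derandomize=True)
    def test_injective_on_complete_profiles(self, study_panel, choice, other):
        profiles = [
            make_profile(study_panel,
                         [m.genotype_labels[i] for m, i in zip(study_panel, idx)],
                         sample_id=f"s{j}")
            for j, idx in enumerate((choice, other))]
        enc = one_hot_encode(Cohort(study_panel, profiles))
        rows_equal = (enc.data[0] == enc.data[1]).all()
        assert rows_equal == (choice == other)
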
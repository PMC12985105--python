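"""Cohort parsing, contrasts, cross-tabulation and confounder eligibility."""

import pandas as pd
import pytest

import marrowde as m
from marrowde.cohort import binarize_factor
from marrowde.errors import DegenerateContrastError, SchemaError, ValidationError

from conftest import write_cohort_tsv


class TestLoadCohort:
    def test_packaged_table_has_fourteen_subjects(self, cohort):
        assert len(cohort) == 14

    def test_outcomes_binary_and_batch_present(self, cohort):
        assert set(cohort.data["cgvhd"]) <= {0, 1}
        assert set(cohort.data["relapse"]) <= {0, 1}
        assert cohort.data["batch"].notna().all()

    def test_ptcy_derived_from_prophylaxis(self, cohort):
        assert int(cohort.data["ptcy"].sum()) == 6

    def test_missing_column_is_schema_error(self, tmp_path, toy_cohort_frame):
        p = write_cohort_tsv(tmp_path, toy_cohort_frame.drop(columns=["batch"]))
        with pytest.raises(SchemaError):
            m.load_cohort(p)

    def test_duplicate_subject_id_rejected(self, tmp_path, toy_cohort_frame):
        df = toy_cohort_frame.copy()
        df.loc[1, "subject_id"] = df.loc[0, "subject_id"]
        with pytest.raises(ValidationError, match="duplicated"):
            m.load_cohort(write_cohort_tsv(tmp_path, df))

    def test_nonbinary_outcome_rejected(self, tmp_path, toy_cohort_frame):
        df = toy_cohort_frame.copy()
        df["cgvhd"] = df["cgvhd"].astype(object)
        df.loc[2, "cgvhd"] = "maybe"
        with pytest.raises(ValidationError, match="not binary"):
            m.load_cohort(write_cohort_tsv(tmp_path, df))

    def test_yes_no_values_normalized(self, tmp_path, toy_cohort_frame):
        df = toy_cohort_frame.copy()
        df["cgvhd"] = ["Yes", "YES", "yes", "No", "no", "NO"]
        c = m.load_cohort(write_cohort_tsv(tmp_path, df))
        assert c.data["cgvhd"].tolist() == [1, 1, 1, 0, 0, 0]


class TestContrasts:
    def test_cgvhd_contrast_sizes(self, cohort):
        c = m.build_contrast(cohort, "cgvhd")
        assert (c.n_positive, c.n_negative) == (6, 8)
        assert set(c.covariates) == {"batch", "relapse"}

    def test_relapse_contrast_sizes(self, cohort):
        c = m.build_contrast(cohort, "relapse")
        assert (c.n_positive, c.n_negative) == (5, 9)
        assert set(c.covariates) == {"batch", "cgvhd"}

    def test_groups_partition_cohort(self, cohort):
        for v in ("cgvhd", "relapse"):
            c = m.build_contrast(cohort, v)
            assert c.positive_group & c.negative_group == frozenset()
            assert c.positive_group | c.negative_group == frozenset(cohort.subjects)

    def test_single_subject_group_degenerate(self, tmp_path, toy_cohort_frame):
        df = toy_cohort_frame.copy()
        df["cgvhd"] = [1, 0, 0, 0, 0, 0]
        c = m.load_cohort(write_cohort_tsv(tmp_path, df))
        with pytest.raises(DegenerateContrastError):
            m.build_contrast(c, "cgvhd")

    def test_unknown_variable_rejected(self, cohort):
        with pytest.raises(ValueError):
            m.build_contrast(cohort, "agvhd")


class TestCrosstab:
    def test_study_crosstab_cells(self, cohort):
        tab = m.crosstab_outcomes(cohort)
        assert tab.loc[1, 1] == 1  # cGvHD+ / relapse+
        assert tab.loc[1, 0] == 5
        assert tab.loc[0, 1] == 4
        assert tab.loc[0, 0] == 4

    def test_margins_match_contrast_sizes(self, cohort):
        tab = m.crosstab_outcomes(cohort)
        cg = m.build_contrast(cohort, "cgvhd")
        rl = m.build_contrast(cohort, "relapse")
        assert tab.sum(axis=1).tolist() == [cg.n_positive, cg.n_negative]
        assert tab.sum(axis=0).tolist() == [rl.n_positive, rl.n_negative]
        assert tab.to_numpy().sum() == len(cohort)

    def test_all_positive_toy_cohort(self, tmp_path, toy_cohort_frame):
        df = toy_cohort_frame.iloc[:3].copy()
        df["cgvhd"] = 1
        df["relapse"] = 1
        tab = m.crosstab_outcomes(m.load_cohort(write_cohort_tsv(tmp_path, df)))
        assert tab.loc[1, 1] == 3 and tab.to_numpy().sum() == 3


class TestEligibility:
    def test_study_factors(self, cohort):
        got = m.eligible_confounders(cohort)
        # hla_match minority (full-match pool vs 5/10 majority) is 7; ptcy 6;
        # all_risk 5; donor source and prior acute GvHD have minority 3
        assert got == ["hla_match", "ptcy", "all_risk"]

    def test_hla_minority_count(self, cohort):
        b = binarize_factor(cohort.data["hla_match"])
        assert int(min(b.sum(), (1 - b).sum())) == 7

    def test_threshold_boundary(self, tmp_path, toy_cohort_frame):
        df = pd.concat([toy_cohort_frame] * 2, ignore_index=True)
        df["subject_id"] = [f"T{i}" for i in range(12)]
        df["fac"] = ["x"] * 9 + ["y"] * 3  # minority exactly 3
        c = m.load_cohort(write_cohort_tsv(tmp_path, df))
        assert m.eligible_confounders(c, ["fac"], min_minority=4) == []
        assert m.eligible_confounders(c, ["fac"], min_minority=3) == ["fac"]

    def test_constant_factor_never_eligible(self, tmp_path, toy_cohort_frame):
        df = toy_cohort_frame.copy()
        df["fac"] = "same"
        c = m.load_cohort(write_cohort_tsv(tmp_path, df))
        assert m.eligible_confounders(c, ["fac"], min_minority=1) == []

    def test_unknown_factor_is_schema_error(self, cohort):
        with pytest.raises(SchemaError):
            m.eligible_confounders(cohort, ["no_such_column"])
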
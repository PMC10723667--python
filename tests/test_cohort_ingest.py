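"""Cohort ingest: validation, disease-pair merge, exact profiles, age bands."""

import numpy as np
import pandas as pd
import pytest

import morbigraph as mg
from morbigraph.cohort import AGE_COL, ID_COL, OUTCOME_COLS

import oracles


def small_frame(flags, names=("A", "B", "C")):
    flags = np.asarray(flags)
    df = pd.DataFrame({ID_COL: [f"p{i}" for i in range(len(flags))],
                       AGE_COL: 40})
    for j, n in enumerate(names):
        df[n] = flags[:, j]
    df[OUTCOME_COLS[0]] = 1
    df[OUTCOME_COLS[1]] = 0
    return df


class TestReadValidation:
    def test_well_formed_roundtrip(self, tmp_path):
        cat = mg.DiseaseCatalogue(("A", "B", "C"))
        df = small_frame([[1, 0, 0], [0, 1, 1], [0, 0, 0]])
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        cohort = mg.read_cohort(path, cat)
        assert cohort.n == 3
        out = tmp_path / "c2.csv"
        mg.write_cohort(cohort, out)
        again = mg.read_cohort(out, cat)
        assert np.array_equal(again.flags, cohort.flags)
        assert np.array_equal(again.ages, cohort.ages)
        assert list(again.person_id) == list(cohort.person_id)

    @pytest.mark.parametrize("mutate, fragment", [
        (lambda df: df.assign(B=[0, 2, 0]), "non-binary flag"),
        (lambda df: df.assign(**{OUTCOME_COLS[0]: [1, -1, 0]}), "invalid value"),
        (lambda df: df.assign(person_id=["p0", "p0", "p2"]), "duplicate person_id"),
        (lambda df: df.drop(columns=["C"]), "missing columns"),
    ])
    def test_structural_errors_name_the_cell(self, mutate, fragment):
        cat = mg.DiseaseCatalogue(("A", "B", "C"))
        df = mutate(small_frame([[1, 0, 0], [0, 1, 1], [0, 0, 0]]))
        with pytest.raises(mg.CohortValidationError, match=fragment):
            mg.Cohort.from_dataframe(df, cat)


class TestMerge:
    def test_or_semantics_and_column_removal(self):
        cat = mg.DiseaseCatalogue(("Cancer", "Metastatic Cancer", "Other"),
                                  (("Cancer", "Metastatic Cancer", "Any Cancer"),))
        flags = np.array([[1, 0, 0], [0, 1, 1], [1, 1, 0], [0, 0, 1]], dtype=np.int8)
        cohort = mg.Cohort(flags, [40] * 4, [0] * 4, [0] * 4, cat)
        merged = mg.merge_disease_pairs(cohort)
        assert merged.catalogue.names == ("Any Cancer", "Other")
        j = merged.catalogue.index("Any Cancer")
        assert merged.flags[:, j].tolist() == [1, 1, 1, 0]
        assert np.array_equal(merged.outpatient, cohort.outpatient)

    def test_merged_prevalence_equals_union_of_carriers(self, rng):
        # 20-row fixture checked against direct set union
        flags = (rng.random((20, 4)) < 0.4).astype(np.int8)
        cat = mg.DiseaseCatalogue(("A", "B", "C", "D"), (("A", "B", "AB"),))
        cohort = mg.Cohort(flags, [50] * 20, [0] * 20, [0] * 20, cat)
        merged = mg.merge_disease_pairs(cohort)
        rows = oracles.rows_as_sets(flags, ("A", "B", "C", "D"))
        union = oracles.carriers(rows, "A") | oracles.carriers(rows, "B")
        j = merged.catalogue.index("AB")
        assert merged.flags[:, j].sum() == len(union)

    def test_merge_never_changes_outcomes_or_drops_more_than_one(self, rng):
        flags = (rng.random((50, 4)) < 0.5).astype(np.int8)
        cat = mg.DiseaseCatalogue(("A", "B", "C", "D"), (("A", "B", "AB"),))
        cohort = mg.Cohort(flags, [50] * 50, rng.poisson(2, 50), rng.poisson(1, 50), cat)
        merged = mg.merge_disease_pairs(cohort)
        drop = cohort.flags.sum(axis=1) - merged.flags.sum(axis=1)
        assert set(drop.tolist()) <= {0, 1}
        assert np.array_equal(merged.inpatient, cohort.inpatient)

    def test_default_catalogue_has_three_pairs_and_26_diseases(self):
        pre = mg.elixhauser_catalogue(merged=False)
        assert len(pre.merge_map) == 3
        assert len(pre) == 29
        post = pre.merged()
        assert len(post) == 26
        assert {"Any Cancer", "Diabetes", "Hypertension"} <= set(post.names)


class TestExactProfile:
    def test_profile_is_sorted_and_order_invariant(self):
        cat1 = mg.DiseaseCatalogue(("Hypertension", "Diabetes", "Obesity"))
        cat2 = mg.DiseaseCatalogue(("Obesity", "Diabetes", "Hypertension"))
        row1 = [1, 1, 0]
        row2 = [0, 1, 1]  # same diseases under the permuted catalogue
        p1 = mg.exact_profile(row1, cat1)
        p2 = mg.exact_profile(row2, cat2)
        assert p1 == p2
        assert p1.members == ("Diabetes", "Hypertension")
        assert p1.label == "Diabetes&Hypertension"

    def test_disease_free_person_has_no_profile(self):
        cat = mg.DiseaseCatalogue(("A", "B"))
        assert mg.exact_profile([0, 0], cat) is None


class TestAgeBands:
    def test_half_open_convention(self):
        std = mg.esp2013(min_age=20)
        assert mg.assign_age_band(20, std) == 0
        assert mg.assign_age_band(24, std) == 0
        assert mg.assign_age_band(25, std) == 1
        assert mg.assign_age_band(95, std) == std.n_bands - 1

    def test_below_lowest_band_errors(self):
        with pytest.raises(ValueError, match="below the lowest band"):
            mg.assign_age_band(19, mg.esp2013(min_age=20))

    def test_esp_weights_sum_to_standard_total(self):
        assert sum(mg.ESP_2013.weights) == 100_000


class TestEmpiricalSummary:
    def test_prevalence_and_histogram_shapes(self):
        cat = mg.DiseaseCatalogue(("A", "B"))
        flags = np.array([[1, 0]] * 2 + [[0, 0]] * 8, dtype=np.int8)
        outp = np.array([0, 3] + [0] * 8)
        cohort = mg.Cohort(flags, [40] * 10, outp, [0] * 10, cat)
        s = mg.empirical_summary(cohort)
        assert s.prevalence["A"] == pytest.approx(0.2)
        hist = s.count_histograms["outpatient_count"]
        assert hist["count"].tolist() == [0, 1, 2, 3]  # gapless
        assert hist["frequency"].sum() == 10
        inp = s.count_histograms["inpatient_unplanned_count"]
        assert inp["frequency"].tolist() == [10]  # all mass at zero

    def test_empty_cohort_errors(self):
        cat = mg.DiseaseCatalogue(("A",))
        cohort = mg.Cohort(np.zeros((0, 1), np.int8), [], [], [], cat)
        with pytest.raises(mg.CohortValidationError):
            mg.empirical_summary(cohort)
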
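"""Hypergraph construction: edges, weights, strata — vs brute-force oracles."""

import numpy as np
import pytest

import morbigraph as mg

import oracles


class TestEnumerateEdges:
    def test_direct_counts_on_three_persons(self):
        cat = mg.DiseaseCatalogue(("A", "B"))
        flags = np.array([[1, 1], [1, 1], [1, 0]], dtype=np.int8)
        cohort = mg.Cohort(flags, [40] * 3, [0] * 3, [0] * 3, cat)
        edges, n_exact, n_all, _ = mg.enumerate_edges(cohort)
        assert [e.label for e in edges] == ["A&B"]
        assert n_exact.tolist() == [2] and n_all.tolist() == [2]

    def test_superset_counts(self):
        cat = mg.DiseaseCatalogue(("A", "B", "C"))
        flags = np.array([[1, 1, 1], [1, 1, 0]], dtype=np.int8)
        cohort = mg.Cohort(flags, [40] * 2, [0] * 2, [0] * 2, cat)
        edges, n_exact, n_all, _ = mg.enumerate_edges(cohort)
        by = {e.label: (ne, na) for e, ne, na in zip(edges, n_exact, n_all)}
        assert by == {"A&B": (1, 2), "A&B&C": (1, 1)}

    def test_no_multimorbidity_warns_and_is_empty(self):
        cat = mg.DiseaseCatalogue(("A", "B"))
        flags = np.array([[1, 0], [0, 1], [0, 0]], dtype=np.int8)
        cohort = mg.Cohort(flags, [40] * 3, [0] * 3, [0] * 3, cat)
        edges, n_exact, n_all, _ = mg.enumerate_edges(cohort)
        assert edges == () and len(n_exact) == 0

    def test_exact_strata_partition_multimorbid_persons(self, rng):
        for _ in range(10):
            cohort, _ = oracles.random_toy_cohort(rng)
            _, n_exact, _, _ = mg.enumerate_edges(cohort)
            assert n_exact.sum() == (cohort.flags.sum(axis=1) >= 2).sum()


class TestOverlapCoefficient:
    def test_hand_computed_intersection(self):
        # carriers A={0,1,2,3}, B={1,2,3,4,5}: |inter|=3, min=4 -> 0.75
        cat = mg.DiseaseCatalogue(("A", "B"))
        flags = np.zeros((6, 2), dtype=np.int8)
        flags[[0, 1, 2, 3], 0] = 1
        flags[[1, 2, 3, 4, 5], 1] = 1
        cohort = mg.Cohort(flags, [40] * 6, [0] * 6, [0] * 6, cat)
        assert mg.overlap_coefficient(("A", "B"), cohort) == pytest.approx(0.75)

    def test_nested_carriers_give_one_disjoint_give_zero(self):
        cat = mg.DiseaseCatalogue(("A", "B", "C"))
        flags = np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1]], dtype=np.int8)
        cohort = mg.Cohort(flags, [40] * 3, [0] * 3, [0] * 3, cat)
        assert mg.overlap_coefficient(("A", "B"), cohort) == 1.0  # A subset of B
        assert mg.overlap_coefficient(("A", "C"), cohort) == 0.0

    def test_zero_carrier_member_errors(self):
        cat = mg.DiseaseCatalogue(("A", "B"))
        flags = np.array([[1, 0]], dtype=np.int8)
        cohort = mg.Cohort(flags, [40], [0], [0], cat)
        with pytest.raises(ValueError, match="no carriers"):
            mg.overlap_coefficient(("A", "B"), cohort)


class TestBruteForceAgreement:
    def test_weights_and_counts_match_set_enumeration(self, rng):
        for _ in range(20):
            cohort, names = oracles.random_toy_cohort(rng)
            rows = oracles.rows_as_sets(cohort.flags, names)
            h = mg.build_hypergraph(cohort, "prevalence_overlap")
            expected = oracles.exact_profile_edges(rows)
            assert {e.members for e in h.edges} == set(expected)
            for e, ne, na, w in zip(h.edges, h.n_exact, h.n_all, h.edge_weights):
                assert ne == expected[e.members]["n_exact"]
                assert na == expected[e.members]["n_all"]
                assert w == oracles.overlap(rows, e.members)
            for j, name in enumerate(names):
                assert h.node_weights[j] == oracles.prevalence(rows, name)


class TestHRUWeights:
    def test_single_person_stratum_rate(self):
        cat = mg.DiseaseCatalogue(("A", "B"))
        flags = np.array([[1, 1], [1, 1], [1, 0]], dtype=np.int8)
        outp = np.array([4, 4, 7])
        cohort = mg.Cohort(flags, [40, 40, 40], outp, [0] * 3, cat)
        h = mg.build_hypergraph(cohort, "outpatient_hru")
        # edge {A,B}: two persons, 4 events each -> 400,000 per 100,000
        assert h.edge_weights.tolist() == [400_000.0]
        # node A: exact-singleton stratum = person 2 with 7 events
        assert h.node_weights[0] == 700_000.0

    def test_missing_singleton_stratum_gets_zero_weight(self, caplog):
        cat = mg.DiseaseCatalogue(("A", "B"))
        flags = np.array([[1, 1], [1, 0]], dtype=np.int8)
        cohort = mg.Cohort(flags, [40, 40], [1, 1], [0, 0], cat)
        with caplog.at_level("WARNING"):
            h = mg.build_hypergraph(cohort, "inpatient_hru")
        assert h.node_weights[cat.index("B")] == 0.0
        assert "empty stratum" in caplog.text

    def test_doubling_counts_doubles_all_hru_weights(self, rng):
        cohort, _ = oracles.random_toy_cohort(rng)
        doubled = mg.Cohort(cohort.flags, cohort.ages, 2 * cohort.outpatient,
                            2 * cohort.inpatient, cohort.catalogue)
        h1 = mg.build_hypergraph(cohort, "outpatient_hru")
        h2 = mg.build_hypergraph(doubled, "outpatient_hru")
        assert np.allclose(h2.edge_weights, 2 * h1.edge_weights)
        assert np.allclose(h2.node_weights, 2 * h1.node_weights)

    def test_all_carriers_node_stratum_option(self):
        cat = mg.DiseaseCatalogue(("A", "B"))
        flags = np.array([[1, 1], [1, 0]], dtype=np.int8)
        cohort = mg.Cohort(flags, [40, 40], [2, 4], [0, 0], cat)
        h = mg.build_hypergraph(cohort, "outpatient_hru", node_stratum="all_carriers")
        assert h.node_weights[0] == 300_000.0  # mean of 2 and 4 per person


class TestSchemeContracts:
    def test_three_schemes_share_edge_list(self, rng):
        cohort, _ = oracles.random_toy_cohort(rng)
        labels = [
            mg.build_hypergraph(cohort, s).edge_labels() for s in mg.SCHEMES
        ]
        assert labels[0] == labels[1] == labels[2]

    def test_weight_ranges(self, rng):
        cohort, _ = oracles.random_toy_cohort(rng)
        h = mg.build_hypergraph(cohort, "prevalence_overlap")
        assert ((0 <= h.edge_weights) & (h.edge_weights <= 1)).all()
        assert ((0 <= h.node_weights) & (h.node_weights <= 1)).all()
        hh = mg.build_hypergraph(cohort, "inpatient_hru")
        assert (hh.edge_weights >= 0).all() and (hh.node_weights >= 0).all()

    def test_row_permutation_changes_no_weight(self, rng):
        cohort, _ = oracles.random_toy_cohort(rng)
        perm = rng.permutation(cohort.n)
        shuffled = cohort.take(perm)
        for scheme in mg.SCHEMES:
            h1 = mg.build_hypergraph(cohort, scheme)
            h2 = mg.build_hypergraph(shuffled, scheme)
            assert h1.edge_labels() == h2.edge_labels()
            assert np.allclose(h1.edge_weights, h2.edge_weights)
            assert np.allclose(h1.node_weights, h2.node_weights)

    def test_toy5_fixture_verified_by_set_arithmetic(self, toy5):
        cohort, expected = toy5
        h = mg.build_hypergraph(cohort, "prevalence_overlap")
        by = dict(zip(h.edge_labels(), h.edge_weights))
        assert by == pytest.approx(expected["overlap"])
        rows = oracles.rows_as_sets(cohort.flags, cohort.catalogue.names)
        for lab in by:
            assert by[lab] == oracles.overlap(rows, lab.split("&"))
        for name, prev in expected["prevalence"].items():
            assert h.node_weights[cohort.catalogue.index(name)] == pytest.approx(prev)


def test_hypergraph_csv_roundtrip(tmp_path, rng):
    cohort, _ = oracles.random_toy_cohort(rng)
    h = mg.build_hypergraph(cohort, "outpatient_hru")
    mg.write_hypergraph(h, tmp_path / "n.csv", tmp_path / "e.csv")
    again = mg.read_hypergraph(tmp_path / "n.csv", tmp_path / "e.csv", h.scheme)
    assert again.edge_labels() == h.edge_labels()
    assert np.allclose(again.edge_weights, h.edge_weights)
    assert np.allclose(again.node_weights, h.node_weights)
    assert np.array_equal(again.n_exact, h.n_exact)
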
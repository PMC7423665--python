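import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from paleotrait import (
    assign_functional_entities,
    build_functional_space,
    categorize_species_redundancy,
    count_possible_entities,
    fe_timeseries_metrics,
    functional_richness_timeseries,
    gower_distance_matrix,
    null_expectation,
    occupancy_percentage,
)
from paleotrait.data_io import PresenceMatrix
from paleotrait.functional_diversity import FunctionalSpace, _fe_metrics_for_subset
from paleotrait.simulate import simulate_trait_table
from paleotrait.traits import Trait, TraitScheme, SpeciesTraitTable


def _table(scheme, states):
    states = np.asarray(states)
    return SpeciesTraitTable(
        scheme=scheme,
        species_ids=[f"sp{i}" for i in range(len(states))],
        states=states,
    )


class TestFunctionalEntities:
    def test_duplicate_rows_share_an_entity(self, small_scheme):
        fe = assign_functional_entities(
            _table(small_scheme, [[0, 0], [0, 0], [1, 2]])
        )
        assert fe.n_fe == 2
        assert sorted(fe.occupancy) == [1, 2]

    def test_all_distinct_rows(self, small_scheme):
        fe = assign_functional_entities(
            _table(small_scheme, [[0, 0], [0, 1], [1, 2]])
        )
        assert fe.n_fe == 3 and (fe.occupancy == 1).all()

    def test_against_brute_force_set_oracle(self, mollusc_scheme):
        table = simulate_trait_table(mollusc_scheme, 200, seed=9)
        fe = assign_functional_entities(table)
        distinct = {tuple(row) for row in table.states}
        assert fe.n_fe == len(distinct)
        assert fe.occupancy.sum() == table.n_species
        # occupancy of each species' FE equals the multiplicity of its row
        from collections import Counter

        mult = Counter(tuple(row) for row in table.states)
        expect = np.array([mult[tuple(row)] for row in table.states])
        np.testing.assert_array_equal(fe.species_occupancy, expect)

    def test_possible_entities_product(self, mollusc_scheme, small_scheme):
        assert count_possible_entities(mollusc_scheme) == 6**5 == 7776
        assert count_possible_entities(small_scheme) == 6
        one = TraitScheme((Trait("t", ("only",)),))
        assert count_possible_entities(one) == 1

    def test_occupancy_percentage(self, mollusc_scheme):
        assert occupancy_percentage(352, mollusc_scheme) == 4.53
        assert occupancy_percentage(0, mollusc_scheme) == 0.0
        assert occupancy_percentage(7776, mollusc_scheme) == 100.0
        with pytest.raises(ValueError):
            occupancy_percentage(7777, mollusc_scheme)


class TestRedundancyCategories:
    @pytest.mark.parametrize(
        "occupancy,expected",
        [
            (1, "unique"),
            (2, "very_low"),
            (3, "very_low"),
            (4, "low"),
            (10, "low"),
            (11, "high"),
            (32, "high"),
            (33, "very_high"),
            (200, "very_high"),
        ],
    )
    def test_boundaries(self, occupancy, expected, small_scheme):
        from paleotrait.functional_diversity import FEAssignment

        fe = FEAssignment(
            species_ids=[f"s{i}" for i in range(occupancy)],
            fe_index=np.zeros(occupancy, dtype=int),
            occupancy=np.array([occupancy]),
        )
        assert categorize_species_redundancy(fe)[0] == expected

    def test_categories_partition_positive_integers(self, small_scheme):
        from paleotrait.functional_diversity import FEAssignment

        seen = []
        for n in range(1, 200):
            fe = FEAssignment(
                species_ids=[f"s{i}" for i in range(n)],
                fe_index=np.zeros(n, dtype=int),
                occupancy=np.array([n]),
            )
            seen.append(categorize_species_redundancy(fe)[0])
        # monotone through the five categories, no gaps
        order = {c: i for i, c in enumerate(
            ["unique", "very_low", "low", "high", "very_high"])}
        ranks = [order[c] for c in seen]
        assert ranks == sorted(ranks)
        assert set(seen) == set(order)


class TestFETimeseries:
    @staticmethod
    def _presence(n_species, bins):
        """bins: list of boolean lists per bin."""
        presence = np.array(bins).T
        edges = np.arange(presence.shape[1], -1, -1, dtype=float)
        return PresenceMatrix(
            bin_edges=edges,
            presence=presence,
            species_ids=[f"sp{i}" for i in range(n_species)],
        )

    def test_hand_computed_bin(self, small_scheme):
        # FE sizes (3,2,1): redundancy 2.0, over-redundancy 50%
        table = _table(
            small_scheme, [[0, 0]] * 3 + [[1, 1]] * 2 + [[1, 2]]
        )
        pm = self._presence(6, [[True] * 6])
        out = fe_timeseries_metrics(pm, table)
        assert out.loc[0, "n_fe"] == 3
        assert out.loc[0, "redundancy"] == pytest.approx(2.0)
        assert out.loc[0, "over_redundancy"] == pytest.approx(50.0)

    def test_all_unique_bin(self, small_scheme):
        table = _table(small_scheme, [[0, 0], [0, 1], [1, 2]])
        out = fe_timeseries_metrics(self._presence(3, [[True] * 3]), table)
        assert out.loc[0, "redundancy"] == pytest.approx(1.0)
        assert out.loc[0, "over_redundancy"] == 0.0

    def test_single_fe_bin_scores_zero_over_redundancy(self, small_scheme):
        table = _table(small_scheme, [[0, 0]] * 4)
        out = fe_timeseries_metrics(self._presence(4, [[True] * 4]), table)
        assert out.loc[0, "n_fe"] == 1
        assert out.loc[0, "redundancy"] == pytest.approx(4.0)
        assert out.loc[0, "over_redundancy"] == 0.0

    def test_empty_bin_flagged_missing(self, small_scheme):
        table = _table(small_scheme, [[0, 0], [1, 2]])
        pm = self._presence(2, [[True, True], [False, False]])
        out = fe_timeseries_metrics(pm, table)
        assert np.isnan(out.loc[1, "redundancy"])

    def test_invariants_on_random_tables(self, mollusc_scheme):
        table = simulate_trait_table(mollusc_scheme, 150, seed=2)
        rng = np.random.default_rng(0)
        presence = rng.random((150, 5)) < 0.6
        presence[:, 0] = True  # keep every species somewhere
        pm = PresenceMatrix(
            bin_edges=np.arange(5, -1, -1, dtype=float),
            presence=presence,
            species_ids=table.species_ids,
        )
        out = fe_timeseries_metrics(pm, table)
        cap = count_possible_entities(mollusc_scheme)
        ok = out["n_species"] > 0
        assert (out.loc[ok, "n_fe"] <= np.minimum(out.loc[ok, "n_species"], cap)).all()
        assert (out.loc[ok, "redundancy"] >= 1).all()
        assert (out.loc[ok, "over_redundancy"] >= 0).all()
        assert (out.loc[ok, "over_redundancy"] < 100).all()


class TestGower:
    def test_identical_and_fully_different(self, mollusc_scheme):
        # two species differing in every unordered trait -> 1, identical -> 0
        names = [t.name for t in mollusc_scheme.traits]
        scheme = TraitScheme(
            tuple(Trait(n, tuple(f"{n}_s{k}" for k in range(6))) for n in names)
        )
        table = _table(scheme, [[0] * 5, [0] * 5, [1] * 5])
        d = gower_distance_matrix(table)
        assert d[0, 1] == 0.0
        assert d[0, 2] == pytest.approx(1.0)

    def test_partial_mismatch_average(self):
        scheme = TraitScheme(
            tuple(Trait(f"t{v}", ("a", "b", "c")) for v in range(5))
        )
        table = _table(scheme, [[0] * 5, [1, 1, 0, 0, 0]])
        assert gower_distance_matrix(table)[0, 1] == pytest.approx(0.4)

    def test_ordinal_trait_rank_normalized(self):
        scheme = TraitScheme((Trait("size", ("s1", "s2", "s3", "s4"), ordinal=True),))
        table = _table(scheme, [[0], [1], [3]])
        d = gower_distance_matrix(table)
        assert d[0, 1] == pytest.approx(1 / 3)
        assert d[0, 2] == pytest.approx(1.0)

    def test_constant_trait_rescales_by_k_over_k_plus_1(self, small_scheme):
        table = _table(small_scheme, [[0, 0], [0, 1], [1, 2], [1, 0]])
        d2 = gower_distance_matrix(table)
        wider = TraitScheme(small_scheme.traits + (Trait("extra", ("only",)),))
        table3 = SpeciesTraitTable(
            scheme=wider,
            species_ids=table.species_ids,
            states=np.hstack([table.states, np.zeros((4, 1), dtype=int)]),
        )
        d3 = gower_distance_matrix(table3)
        np.testing.assert_allclose(d3, d2 * 2 / 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=12), st.integers(0, 2**31 - 1))
    def test_metric_properties(self, n, seed):
        scheme = TraitScheme(
            (Trait("a", ("x", "y", "z")), Trait("b", ("p", "q"), ordinal=True))
        )
        table = simulate_trait_table(scheme, n, seed=seed)
        d = gower_distance_matrix(table)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()


class TestFunctionalSpace:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(1)
        pts = rng.random((12, 2))
        d = squareform(pdist(pts))
        space = build_functional_space(d, max_dim=4)
        assert space.quality[2] == pytest.approx(0.0, abs=1e-12)
        assert space.chosen_dim == 2
        np.testing.assert_allclose(
            pdist(space.chosen_coordinates()), pdist(pts), atol=1e-8
        )

    def test_equidistant_points_have_equal_leading_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        space = build_functional_space(d, max_dim=2)
        assert space.eigenvalues[0] == pytest.approx(space.eigenvalues[1])

    def test_quality_scan_on_simulated_traits(self, mollusc_scheme):
        table = simulate_trait_table(mollusc_scheme, 60, seed=3)
        d = gower_distance_matrix(table)
        space = build_functional_space(d, max_dim=4)
        assert 2 <= space.chosen_dim <= 4
        dims = sorted(space.quality)
        scores = [space.quality[m] for m in dims]
        # adding axes cannot make the embedding represent distances worse
        assert all(a >= b - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_degenerate_space_rejected(self):
        with pytest.raises(ValueError):
            build_functional_space(np.zeros((4, 4)), max_dim=2)


class TestFunctionalRichness:
    @staticmethod
    def _square_space():
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        return FunctionalSpace(
            species_ids=[f"c{i}" for i in range(4)],
            coordinates=corners,
            eigenvalues=np.array([1.0, 1.0]),
            quality={2: 0.0},
            chosen_dim=2,
            input_distances=squareform(pdist(corners)),
        )

    def test_triangle_over_square_is_half(self):
        space = self._square_space()
        presence = np.array([[True, True], [True, True], [True, True], [True, False]])
        pm = PresenceMatrix(
            bin_edges=np.array([2.0, 1.0, 0.0]),
            presence=presence,
            species_ids=space.species_ids,
        )
        out = functional_richness_timeseries(space, pm)
        assert out.loc[0, "functional_richness"] == pytest.approx(100.0)
        assert out.loc[1, "functional_richness"] == pytest.approx(50.0)

    def test_underdetermined_bin_flagged_missing(self):
        space = self._square_space()
        presence = np.array([[True, True], [True, True], [True, False], [True, False]])
        pm = PresenceMatrix(
            bin_edges=np.array([2.0, 1.0, 0.0]),
            presence=presence,
            species_ids=space.species_ids,
        )
        out = functional_richness_timeseries(space, pm)
        assert np.isnan(out.loc[1, "functional_richness"])

    def test_containment_monotonicity(self, mollusc_scheme):
        table = simulate_trait_table(mollusc_scheme, 40, seed=8)
        space = build_functional_space(
            gower_distance_matrix(table), max_dim=3, species_ids=table.species_ids
        )
        rng = np.random.default_rng(5)
        small = rng.random(40) < 0.5
        big = small | (rng.random(40) < 0.3)
        presence = np.column_stack([np.ones(40, bool), small, big])
        pm = PresenceMatrix(
            bin_edges=np.array([3.0, 2.0, 1.0, 0.0]),
            presence=presence,
            species_ids=table.species_ids,
        )
        out = functional_richness_timeseries(space, pm)
        assert out.loc[1, "functional_richness"] <= out.loc[2, "functional_richness"]
        assert (out["functional_richness"].dropna() <= 100 + 1e-9).all()


class TestNullExpectation:
    def test_whole_pool_bin_collapses_to_observed(self, small_table):
        n = small_table.n_species
        pm = PresenceMatrix(
            bin_edges=np.array([1.0, 0.0]),
            presence=np.ones((n, 1), bool),
            species_ids=small_table.species_ids,
        )
        out = null_expectation("redundancy", pm, small_table, n_iter=100, seed=0)
        assert out.loc[0, "null_mean"] == pytest.approx(out.loc[0, "observed"])
        assert out.loc[0, "q025"] == pytest.approx(out.loc[0, "observed"])
        assert not out.loc[0, "significant"]

    def test_matches_exhaustive_enumeration_on_tiny_pool(self, small_scheme):
        # 5 species, bins of 3: all C(5,3)=10 subsets enumerable exactly
        table = _table(
            small_scheme, [[0, 0], [0, 0], [0, 1], [1, 2], [1, 2]]
        )
        presence = np.zeros((5, 1), bool)
        presence[:3, 0] = True
        presence[:, 0] |= ~presence.any(axis=1)  # keep invariant: all in >=1 bin
        pm = PresenceMatrix(
            bin_edges=np.array([1.0, 0.0]),
            presence=np.ones((5, 1), bool),
            species_ids=table.species_ids,
        )
        # bin of richness 3 via a dedicated presence matrix
        pm3 = PresenceMatrix(
            bin_edges=np.array([2.0, 1.0, 0.0]),
            presence=np.column_stack([np.ones(5, bool),
                                      [True, True, True, False, False]]),
            species_ids=table.species_ids,
        )
        out = null_expectation("n_fe", pm3, table, n_iter=2000, seed=3)
        exact = [
            _fe_metrics_for_subset(table.states[list(c)])[0]
            for c in itertools.combinations(range(5), 3)
        ]
        exact = np.array(exact, dtype=float)
        draws_mean = out.loc[1, "null_mean"]
        se = exact.std(ddof=0) / np.sqrt(2000)
        assert abs(draws_mean - exact.mean()) < 4 * se
        assert out.loc[1, "q025"] >= exact.min()
        assert out.loc[1, "q975"] <= exact.max()

    def test_random_subsets_rarely_flagged(self, mollusc_scheme):
        table = simulate_trait_table(mollusc_scheme, 60, seed=11)
        rng = np.random.default_rng(13)
        n_trials, flagged = 20, 0
        for trial in range(n_trials):
            mask = np.zeros(60, bool)
            mask[rng.choice(60, size=25, replace=False)] = True
            pm = PresenceMatrix(
                bin_edges=np.array([2.0, 1.0, 0.0]),
                presence=np.column_stack([np.ones(60, bool), mask]),
                species_ids=table.species_ids,
            )
            out = null_expectation("redundancy", pm, table, n_iter=199, seed=trial)
            flagged += int(out.loc[1, "significant"])
        assert flagged <= 2  # >= 90% non-significant

    def test_too_few_iterations_rejected(self, small_table):
        pm = PresenceMatrix(
            bin_edges=np.array([1.0, 0.0]),
            presence=np.ones((small_table.n_species, 1), bool),
            species_ids=small_table.species_ids,
        )
        with pytest.raises(ValueError):
            null_expectation("redundancy", pm, small_table, n_iter=50, seed=0)
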
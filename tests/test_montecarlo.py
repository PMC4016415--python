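"""Pathway microsimulation: sampling contracts and distribution summaries."""

import numpy as np
import pytest

from lifecourse.cohort import InitialMix
from lifecourse.estimation import CostTable
from lifecourse.montecarlo import (
    PathwayCollection,
    draw_initial_state,
    simulate_collection,
    simulate_pathway,
    summarize_costs,
    summarize_years,
)
from lifecourse.states import Gender, HealthState

from conftest import e1_mix, single_state_matrices


def collection_from_costs(costs, genders=None) -> PathwayCollection:
    costs = np.asarray(costs, dtype=float)
    n = len(costs)
    if genders is None:
        genders = np.zeros(n, dtype=np.int8)
    return PathwayCollection(
        genders=np.asarray(genders, dtype=np.int8),
        states=np.zeros((n, 2), dtype=np.int8),
        years_in_state=np.ones((n, 6), dtype=np.int64),
        lifetime_cost=costs,
    )


class TestPathways:
    def test_certain_death_gives_length_one(self):
        path = simulate_pathway(
            single_state_matrices(1.0), Gender.F, HealthState.E1,
            np.random.default_rng(0),
        )
        assert path.states == (HealthState.E1, HealthState.DEAD)
        assert path.years_lived == 1

    def test_same_seed_same_pathway(self, truth):
        p1 = simulate_pathway(
            truth.matrices, Gender.M, HealthState.E1, np.random.default_rng(33)
        )
        p2 = simulate_pathway(
            truth.matrices, Gender.M, HealthState.E1, np.random.default_rng(33)
        )
        assert p1 == p2

    def test_dead_initial_state_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_pathway(
                truth.matrices, Gender.F, HealthState.DEAD, np.random.default_rng(0)
            )

    def test_geometric_mean_length(self):
        """q=0.2 gives mean lifetime 5; the MC average lands within 3 SE."""
        zero = CostTable(base=np.full((2, 6), 0.0))
        coll = simulate_collection(
            single_state_matrices(0.2), e1_mix(), 10_000, zero, seed=4
        )
        se = np.sqrt((1 - 0.2) / 0.2**2 / 20_000)
        assert coll.lengths.mean() == pytest.approx(5.0, abs=3 * se)

    def test_forced_death_at_age_cap(self):
        path = simulate_pathway(
            single_state_matrices(0.0), Gender.F, HealthState.E1,
            np.random.default_rng(0), max_age=30,
        )
        assert len(path.states) == 32  # ages 0..30 lived, then forced DEAD
        assert path.states[-1] is HealthState.DEAD
        assert path.years_lived == 31


class TestCollection:
    def test_counts_per_gender(self, truth, cost_table):
        coll = simulate_collection(truth.matrices, truth.initial_mix, 10, cost_table, seed=0)
        assert len(coll) == 20
        assert coll.gender_mask(Gender.F).sum() == 10

    def test_same_seed_identical_collections(self, truth, cost_table):
        a = simulate_collection(truth.matrices, truth.initial_mix, 200, cost_table, seed=5)
        b = simulate_collection(truth.matrices, truth.initial_mix, 200, cost_table, seed=5)
        assert (a.states == b.states).all()
        assert (a.lifetime_cost == b.lifetime_cost).all()

    def test_zero_cost_table_zero_lifetime_costs(self, truth):
        zero = CostTable(base=np.zeros((2, 6)))
        coll = simulate_collection(truth.matrices, truth.initial_mix, 50, zero, seed=1)
        assert (coll.lifetime_cost == 0).all()

    def test_no_state_after_death(self, small_collection):
        states = small_collection.states
        for row in states[:200]:
            seen = row[row != -1]
            dead_at = np.flatnonzero(seen == 6)
            if dead_at.size:
                assert dead_at[0] == len(seen) - 1


class TestInitialDraw:
    def test_point_mass_mix(self):
        coll_mix = e1_mix()
        g, s = draw_initial_state(coll_mix, np.random.default_rng(0))
        assert s is HealthState.E1

    def test_marginal_frequencies_converge(self):
        mix = InitialMix.default()
        rng = np.random.default_rng(8)
        draws = [draw_initial_state(mix, rng) for _ in range(50_000)]
        e1_share = np.mean([s is HealthState.E1 for _, s in draws])
        se = np.sqrt(0.96 * 0.04 / 50_000)
        assert e1_share == pytest.approx(0.96, abs=3 * se)
        male_share = np.mean([g is Gender.M for g, _ in draws])
        assert male_share == pytest.approx(0.505, abs=3 * np.sqrt(0.25 / 50_000))


class TestSummaries:
    def test_quartiles_by_linear_interpolation(self):
        s = summarize_costs(collection_from_costs([100, 200, 300, 400]), Gender.F)
        assert s.mean == 250 and s.p50 == 250
        assert s.p25 == 175 and s.p75 == 325
        assert s.minimum == 100 and s.maximum == 400
        assert s.n_trials == 4

    def test_degenerate_distribution_has_undefined_shape(self):
        s = summarize_costs(collection_from_costs([7.0, 7.0, 7.0]), Gender.F)
        assert s.sd == 0 and s.variance == 0
        assert np.isnan(s.skewness) and np.isnan(s.kurtosis_excess)

    def test_variance_is_sd_squared(self, small_collection):
        for g in Gender:
            s = summarize_costs(small_collection, g)
            assert s.variance == pytest.approx(s.sd**2, rel=1e-9)
            assert s.minimum <= s.p25 <= s.p50 <= s.p75 <= s.maximum

    def test_empty_gender_rejected(self):
        coll = collection_from_costs([1.0, 2.0])  # all female
        with pytest.raises(ValueError):
            summarize_costs(coll, Gender.M)

    def test_state_years_partition_pathway_length(self, small_collection):
        ys = summarize_years(small_collection)
        for g in Gender:
            mean_total = ys.loc[ys["gender"] == g.name, "mean"].sum()
            mean_len = small_collection.lengths[small_collection.gender_mask(g)].mean()
            assert mean_total == pytest.approx(mean_len, rel=1e-9)

    def test_constant_years_summary(self):
        coll = collection_from_costs([0.0] * 5)
        coll.years_in_state[:] = 0
        coll.years_in_state[:, 1] = 3  # everyone: exactly 3 years acute
        ys = summarize_years(coll)
        row = ys[(ys["gender"] == "F") & (ys["state"] == "E2")].iloc[0]
        assert row["mean"] == 3 and row["sd"] == 0
        assert row["min"] == 3 and row["max"] == 3
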
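"""Transition counting, MLE matrices, homogeneity test, cost table."""

import numpy as np
import pandas as pd
import pytest

from lifecourse.estimation import (
    CostTable,
    TransitionCounts,
    anderson_goodman,
    count_transitions,
    estimate_cost_table,
    estimate_matrices,
    estimate_matrices_per_period,
    read_matrices,
    stationarity_report,
    stationarity_test,
    write_matrices,
)
from lifecourse.panel import PersonYearPanel
from lifecourse.states import DEFAULT_SCHEME, Gender, HealthState, N_STATES

from conftest import panel_from_rows

E1, E2, E56, DEAD = 0, 1, 3, 6


def counts_from_array(arr) -> TransitionCounts:
    """Wrap a (P, 7, 7) count array into a single-stratum TransitionCounts."""
    arr = np.asarray(arr)
    counts = np.zeros((2, 10, arr.shape[0], N_STATES, N_STATES), dtype=np.int64)
    counts[0, 0] = arr
    periods = tuple((2004 + k, 2005 + k) for k in range(arr.shape[0]))
    return TransitionCounts(counts=counts, periods=periods)


class TestCounting:
    def test_hand_counted_toy_panel(self):
        """One stayer, one acute onset, one death - counted in the right cells."""
        panel = panel_from_rows(
            [
                ("A", 2004, "M", 30, "E1"),
                ("A", 2005, "M", 31, "E1"),
                ("B", 2004, "M", 30, "E1"),
                ("B", 2005, "M", 31, "E2"),
                ("C", 2004, "M", 30, "E56"),
                ("C", 2005, "M", 31, "DEAD"),
            ]
        )
        counts = count_transitions(panel)
        band = DEFAULT_SCHEME.group(30)
        block = counts.counts[Gender.M, band, 0]
        assert block[E1, E1] == 1
        assert block[E1, E2] == 1
        assert block[E56, DEAD] == 1
        assert counts.counts.sum() == 3

    def test_single_observation_and_gap_contribute_nothing(self):
        panel = panel_from_rows(
            [
                ("A", 2004, "F", 50, "E1"),          # one year only
                ("B", 2004, "F", 50, "E1"),
                ("B", 2006, "F", 52, "E1"),          # gap: censored
                ("C", 2004, "F", 50, "E1"),
                ("C", 2005, "F", 51, "E1"),
            ]
        )
        counts = count_transitions(panel)
        assert counts.counts.sum() == 1  # only C's consecutive pair

    def test_stratum_by_age_at_origin(self):
        """A person crossing a band boundary contributes to two strata."""
        panel = panel_from_rows(
            [
                ("A", 2004, "F", 14, "E1"),
                ("A", 2005, "F", 15, "E1"),
                ("A", 2006, "F", 16, "E1"),
            ]
        )
        counts = count_transitions(panel)
        assert counts.counts[Gender.F, 1, 0, E1, E1] == 1  # origin age 14, band 1-14
        assert counts.counts[Gender.F, 2, 1, E1, E1] == 1  # origin age 15, band 15-24

    def test_single_year_panel_rejected(self):
        panel = panel_from_rows([("A", 2004, "F", 30, "E1")])
        with pytest.raises(ValueError, match="no transitions"):
            count_transitions(panel)

    def test_row_totals_partition_counts(self, small_panel):
        counts = count_transitions(small_panel)
        assert (counts.row_totals() == counts.counts.sum(axis=-1)).all()
        assert (counts.counts[:, :, :, DEAD, :] == 0).all()  # no exits from death


class TestMLE:
    def test_printed_formula_on_simple_row(self):
        arr = np.zeros((1, 7, 7), dtype=int)
        arr[0, E1, E1], arr[0, E1, E2] = 8, 2
        mset = estimate_matrices(counts_from_array(arr))
        assert mset.probs[0, 0, E1, E1] == pytest.approx(0.8)
        assert mset.probs[0, 0, E1, E2] == pytest.approx(0.2)

    def test_pooling_over_periods(self):
        """Periods with 1/10 and 3/10 give 0.1 and 0.3 per period, 0.2 pooled."""
        arr = np.zeros((2, 7, 7), dtype=int)
        arr[0, E1, E1], arr[0, E1, E2] = 9, 1
        arr[1, E1, E1], arr[1, E1, E2] = 7, 3
        counts = counts_from_array(arr)
        pooled = estimate_matrices(counts)
        per_period = estimate_matrices_per_period(counts)
        assert per_period[0].probs[0, 0, E1, E2] == pytest.approx(0.1)
        assert per_period[1].probs[0, 0, E1, E2] == pytest.approx(0.3)
        assert pooled.probs[0, 0, E1, E2] == pytest.approx(0.2)

    def test_single_period_per_period_equals_pooled(self):
        arr = np.zeros((1, 7, 7), dtype=int)
        arr[0, E1, E1], arr[0, E1, E2] = 5, 5
        counts = counts_from_array(arr)
        (only,) = estimate_matrices_per_period(counts)
        assert np.allclose(only.probs, estimate_matrices(counts).probs)

    def test_dead_row_absorbing_and_identity_fallback(self):
        arr = np.zeros((1, 7, 7), dtype=int)
        arr[0, E1, E1] = 1
        with pytest.warns(UserWarning, match="identity"):
            mset = estimate_matrices(counts_from_array(arr))
        dead_row = np.zeros(7)
        dead_row[DEAD] = 1.0
        assert np.allclose(mset.probs[:, :, DEAD, :], dead_row)
        # an unobserved origin row stays put rather than guessing dynamics
        assert mset.probs[0, 0, E2, E2] == 1.0
        mset.validate()  # all rows stochastic despite empty cells

    def test_estimated_rows_sum_to_one(self, small_panel):
        with pytest.warns(UserWarning):
            mset = estimate_matrices(count_transitions(small_panel))
        assert np.allclose(mset.probs.sum(axis=-1), 1.0, atol=1e-10)


class TestAndersonGoodman:
    def test_zero_statistic_under_identical_frequencies(self):
        arr = np.zeros((2, 7, 7), dtype=int)
        for t in range(2):
            arr[t, E1, E1], arr[t, E1, E2] = 18, 2
            arr[t, E2, E1], arr[t, E2, E2] = 5, 5
        stat, _, _, p = anderson_goodman(arr)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_state_example(self):
        """Period rows (9,1) and (7,3) of 10: statistic 2*(0.125+0.5) = 1.25."""
        c = np.array([[[9, 1], [0, 0]], [[7, 3], [0, 0]]])
        stat, df_nom, df_adj, p = anderson_goodman(c)
        assert stat == pytest.approx(1.25)
        assert df_nom == 2 * 1 * 1
        assert df_adj == 1  # only the observed row's free parameter remains
        assert 0 < p < 1

    def test_nominal_df_formula(self):
        """m(m-1)(P-1): three states observed over three periods gives 12."""
        rng = np.random.default_rng(0)
        c = rng.integers(1, 50, size=(3, 3, 3))
        _, df_nom, _, _ = anderson_goodman(c)
        assert df_nom == 3 * 2 * 2

    def test_single_period_rejected(self):
        with pytest.raises(ValueError):
            anderson_goodman(np.ones((1, 3, 3), dtype=int))

    def test_stratified_report(self, small_panel):
        counts = count_transitions(small_panel)
        results = stationarity_test(counts, alpha=0.05)
        assert len(results) == 20
        rep = stationarity_report(results)
        assert set(rep["decision"]) <= {"stationary", "non-stationary"}
        assert ((rep["p_value"] >= 0) & (rep["p_value"] <= 1)).all()
        assert (rep["df_adjusted"] <= rep["df_nominal"]).all()


class TestCostTable:
    def test_two_point_mean_and_gender_fallback(self):
        rows = [("A", 2004, "F", 30, "E1", 100.0), ("B", 2004, "F", 35, "E1", 300.0)]
        rows += [
            (f"P{i}", 2004, "F", 40 + i, state, 50.0 * (i + 1))
            for i, state in enumerate(["E2", "E34", "E56", "E79", "E8"])
        ]
        df = pd.DataFrame(
            rows, columns=["person_id", "year", "gender", "age", "state", "cost"]
        )
        with pytest.warns(UserWarning):  # male cells borrow the pooled state mean
            table = estimate_cost_table(PersonYearPanel(df))
        assert table.cost(Gender.F, 3, HealthState.E1) == pytest.approx(200.0)
        assert table.cost(Gender.M, 3, HealthState.E1) == pytest.approx(200.0)

    def test_state_with_no_costed_person_years_rejected(self):
        df = pd.DataFrame(
            [("A", 2004, "F", 30, "E1", 100.0)],
            columns=["person_id", "year", "gender", "age", "state", "cost"],
        )
        with pytest.raises(ValueError, match="no costed person-years"):
            estimate_cost_table(PersonYearPanel(df))

    def test_zero_dispersion_panel_recovers_reference_means(self, truth):
        """With cost noise off, cell means reproduce the configured table exactly."""
        from lifecourse.synthetic import SynthConfig, generate_panel, GroundTruth

        frozen = GroundTruth(
            matrices=truth.matrices,
            initial_mix=truth.initial_mix,
            cost_model=type(truth.cost_model)(means=truth.cost_model.means, cv=0.0),
            out_migration_rate=0.0,
            in_migration_rate=0.0,
        )
        panel = generate_panel(frozen, SynthConfig(n_individuals=4_000, seed=9))
        table = estimate_cost_table(panel)
        assert table.base == pytest.approx(truth.cost_model.means, abs=5e-3)
        assert table.cost(Gender.F, 5, HealthState.E56) == pytest.approx(2739.67, abs=5e-3)

    def test_small_cells_fall_back_to_gender_state_mean(self, small_panel):
        table = estimate_cost_table(small_panel, scheme=DEFAULT_SCHEME, min_cell=10**9)
        assert np.isnan(table.by_band).all()
        assert np.allclose(table.effective, table.base[:, None, :])

    def test_costless_panel_rejected(self):
        panel = panel_from_rows(
            [("A", 2004, "F", 30, "E1"), ("A", 2005, "F", 31, "E1")]
        )
        with pytest.raises(ValueError, match="cost"):
            estimate_cost_table(panel)


class TestIO:
    def test_matrix_round_trip_to_12_decimals(self, truth, tmp_path):
        path = write_matrices(truth.matrices, tmp_path / "m.csv")
        back = read_matrices(path)
        assert np.allclose(back.probs, truth.matrices.probs, atol=1e-12)

    def test_cost_table_round_trip(self, small_panel, tmp_path):
        table = estimate_cost_table(small_panel, scheme=DEFAULT_SCHEME, min_cell=5)
        back = CostTable.read(table.write(tmp_path / "c.csv"))
        assert np.allclose(back.effective, table.effective, atol=1e-6)
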
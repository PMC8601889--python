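import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytoedm import (
    EmbeddingConfig,
    lagged_embedding,
    select_embedding,
    simplex_forecast,
)
from phytoedm.errors import (
    InsufficientLengthError,
    InsufficientPredictionsError,
    InvalidDimensionError,
    SeriesUnusableError,
    UndefinedCorrelationError,
)
from conftest import seasonal_sine, series
from _oracle import brute_force_simplex


class TestLaggedEmbedding:
    def test_identity_embedding_at_E1(self):
        times, pts = lagged_embedding(series([1, 2, 3, 4]), E=1)
        assert list(times) == [0, 1, 2, 3]
        assert pts.tolist() == [[1], [2], [3], [4]]

    def test_E2_vectors_pair_current_with_previous(self):
        times, pts = lagged_embedding(series([1, 2, 3, 4]), E=2)
        assert list(times) == [1, 2, 3]
        assert pts.tolist() == [[2, 1], [3, 2], [4, 3]]

    def test_vectors_touching_a_gap_are_dropped(self):
        times, pts = lagged_embedding(series([1, np.nan, 3, 4, 5]), E=2)
        assert list(times) == [3, 4]
        assert pts.tolist() == [[4, 3], [5, 4]]

    def test_error_contracts(self):
        with pytest.raises(InvalidDimensionError):
            lagged_embedding(series([1, 2, 3]), E=0)
        with pytest.raises(InsufficientLengthError):
            lagged_embedding(series([1, 2, 3]), E=3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        n=st.integers(5, 40),
        E=st.integers(1, 4),
        gap=st.integers(0, 39),
    )
    def test_every_vector_reads_back_from_the_series(self, n, E, gap):
        rng = np.random.default_rng(n * 100 + E)
        vals = rng.uniform(0, 10, n)
        if gap < n:
            vals[gap] = np.nan
        s = series(vals)
        if n < E + 1:
            return
        times, pts = lagged_embedding(s, E)
        for t, p in zip(times, pts):
            expect = [vals[t - j] for j in range(E)]
            assert not np.isnan(expect).any()
            assert p.tolist() == expect


class TestSimplexForecast:
    def test_noiseless_seasonal_series_is_nearly_perfectly_predicted(self):
        r = simplex_forecast(seasonal_sine(240), E=3)
        assert r.rho >= 0.999

    def test_iid_noise_has_no_predictability(self):
        rng = np.random.default_rng(12345)
        r = select_embedding(series(rng.uniform(0, 1, 240)))
        assert abs(r.rho) < 0.3

    def test_constant_series_has_undefined_correlation(self):
        with pytest.raises(UndefinedCorrelationError):
            simplex_forecast(series([5.0] * 30), E=2)

    def test_too_few_pairs_raises(self):
        with pytest.raises(InsufficientPredictionsError):
            simplex_forecast(series([1.0, 2.0, 3.0]), E=2)

    def test_predictions_are_weighted_averages_of_observed_targets(self):
        rng = np.random.default_rng(99)
        r = simplex_forecast(series(rng.uniform(0, 5, 60)), E=2)
        lo, hi = r.observed.min(), r.observed.max()
        assert (r.predicted >= lo).all() and (r.predicted <= hi).all()

    def test_brute_force_oracle_equivalence_small_batch(self):
        rng = np.random.default_rng(2024)
        for case in range(30):
            n = int(rng.integers(15, 61))
            vals = rng.uniform(0, 10, n)
            if case % 3 == 0:
                vals[rng.integers(0, n)] = np.nan
            E = int(rng.integers(1, 5))
            got = simplex_forecast(series(vals), E)
            expected = brute_force_simplex(list(vals), E)
            assert got.n_pairs == len(expected)
            for (gt, go, gp), (et, eo, ep) in zip(got.pairs, expected):
                assert gt == et
                assert go == eo
                assert abs(gp - ep) < 1e-12

    def test_duplicate_patterns_enter_with_weight_one(self):
        # exactly repeating block: every pattern has exact duplicates, and
        # their shared continuation is the prediction
        vals = [1.0, 2.0, 3.0] * 8
        r = simplex_forecast(series(vals), E=2)
        assert np.allclose(r.predicted, r.observed)
        assert r.rho == pytest.approx(1.0)


class TestSelectEmbedding:
    def test_scans_range_and_returns_argmax(self, sine_series):
        r = select_embedding(sine_series)
        assert 1 <= r.E_opt <= 10
        assert r.rho >= 0.999

    def test_ties_break_toward_smallest_E(self):
        # strictly 12-periodic: many E reach rho = 1 within 1e-9
        vals = list(range(1, 13)) * 10
        r = select_embedding(series([float(v) for v in vals]))
        assert r.rho == pytest.approx(1.0, abs=1e-9)
        assert r.E_opt == 1

    def test_scan_restricted_to_feasible_E(self):
        vals = [np.nan] * 20 + [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
        r = select_embedding(series(vals))
        # with 8 observed months only small E admit >= 3 forecast pairs
        assert r.E_opt <= 5

    def test_unusable_series_raises(self):
        with pytest.raises(SeriesUnusableError):
            select_embedding(series([5.0] * 40))


class TestSkillProperties:
    def test_perfect_skill_limit_for_periodic_series(self):
        for period in (6, 12):
            t = np.arange(period * 6)
            vals = np.sin(2 * np.pi * t / period) + 1.5 + 0.3 * np.cos(
                4 * np.pi * t / period
            )
            r = select_embedding(series(vals))
            assert r.rho >= 0.999

    def test_shuffling_never_improves_seasonal_skill(self):
        base = seasonal_sine(120)
        r0 = select_embedding(base).rho
        for seed in range(3):
            rng = np.random.default_rng(seed)
            shuffled = series(rng.permutation(base.values))
            assert select_embedding(shuffled).rho <= r0 + 1e-12

    def test_missingness_only_affects_local_predictions(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(1, 9, 48)
        E, tau, tp = 2, 1, 1
        full = simplex_forecast(series(vals), E)
        gap = 25
        vals2 = vals.copy()
        vals2[gap] = np.nan
        part = simplex_forecast(series(vals2), E)
        part_times = {t for t, _, _ in part.pairs}
        # every pair whose target or delay vector touches the gap is gone:
        # target times gap (target missing), gap+1 and gap+2 (vector touches)
        assert part_times.isdisjoint({gap, gap + tp, gap + tau + tp})
        # all other pairs survive, and a pair changes only if one of the
        # dropped points sat among its nearest neighbors
        full_map = {t: p for t, _, p in full.pairs}
        assert part_times == set(full_map) - {gap, gap + tp, gap + tau + tp}
        expected = {t: p for t, _, p in brute_force_simplex(list(vals2), E)}
        for t, _, p in part.pairs:
            assert abs(p - expected[t]) < 1e-12
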
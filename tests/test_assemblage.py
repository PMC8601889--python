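import numpy as np
import pytest
from scipy import stats

from phytoedm import (
    CommunityTable,
    MonthlyTimeSeries,
    TaxonRecord,
    aggregate,
    coefficient_of_variation,
    exclusion_filter,
    predictability_curve,
    sample_assemblages,
)
from phytoedm.errors import (
    EmptyAssemblageError,
    InvalidStrategyError,
    MemberNotFoundError,
    PoolExhaustedError,
    UndefinedCVError,
)
from conftest import series, tiny_table


def table_from(values_by_id, groups=None, radii=None, start=(2000, 1)):
    taxa = []
    for tid, vals in values_by_id.items():
        taxa.append(
            TaxonRecord(
                taxon_id=tid,
                functional_group=(groups or {}).get(tid, "diatom"),
                cell_radius=(radii or {}).get(tid, 5.0),
                series=series(vals, start=start),
            )
        )
    return CommunityTable(taxa)


class TestAggregate:
    def test_single_member_is_identity(self):
        t = table_from({"a": [1, 2, 3], "b": [4, 5, 6]})
        asm = aggregate(t, ["a"])
        assert asm.series.values.tolist() == [1, 2, 3]

    def test_monthly_sums(self):
        t = table_from({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert aggregate(t, ["a", "b"]).series.values.tolist() == [5, 7, 9]

    def test_missing_member_month_propagates(self):
        t = table_from({"a": [1, 2, 3], "b": [4, np.nan, 6]})
        vals = aggregate(t, ["a", "b"]).series.values
        assert vals[0] == 5 and np.isnan(vals[1]) and vals[2] == 9

    def test_summation_order_is_canonical(self):
        rng = np.random.default_rng(0)
        t = table_from({f"t{i}": rng.uniform(0, 1, 12) for i in range(20)})
        a = aggregate(t, t.taxon_ids).series.values
        b = aggregate(t, list(reversed(t.taxon_ids))).series.values
        assert (a == b).all()  # bit-level identical

    def test_errors(self):
        t = table_from({"a": [1, 2, 3]})
        with pytest.raises(MemberNotFoundError):
            aggregate(t, ["a", "zz"])
        with pytest.raises(EmptyAssemblageError):
            aggregate(t, [])


class TestSampleAssemblages:
    def test_pool_exhausted(self, small_table):
        with pytest.raises(PoolExhaustedError):
            sample_assemblages(small_table, size=3, n_trials=1,
                               strategy="functional_group:diatom")

    def test_full_size_returns_the_unique_combination(self, small_table):
        asms = sample_assemblages(small_table, size=6, n_trials=5, rng_seed=1)
        assert all(a.member_ids == asms[0].member_ids for a in asms)

    def test_size_class_boundary_pools(self):
        t = table_from(
            {c: [1, 2, 3] for c in "abcd"},
            radii={"a": 3.0, "b": 5.0, "c": 12.0, "d": 13.0},
        )
        assert t.size_class_pool("small") == ["a"]
        assert t.size_class_pool("medium") == ["b", "c"]
        assert t.size_class_pool("large") == ["d"]

    def test_invalid_strategies_rejected(self, small_table):
        for bad in ("functional_group:other", "functional_group:algae",
                    "size_class:tiny", "bogus"):
            with pytest.raises(InvalidStrategyError):
                sample_assemblages(small_table, 1, 1, strategy=bad)

    def test_trials_regenerable_from_master_seed(self, small_table):
        a = sample_assemblages(small_table, 3, 4, rng_seed=42)
        b = sample_assemblages(small_table, 3, 4, rng_seed=42)
        assert [x.member_ids for x in a] == [y.member_ids for y in b]

    def test_equal_inclusion_probability(self):
        t = table_from({f"t{i:02d}": [1.0, 2.0, 3.0] for i in range(10)})
        counts = {tid: 0 for tid in t.taxon_ids}
        n_trials = 10_000
        for asm in sample_assemblages(t, size=2, n_trials=n_trials, rng_seed=0):
            for tid in asm.member_ids:
                counts[tid] += 1
        observed = np.array([counts[tid] for tid in t.taxon_ids])
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 0.001


class TestPredictabilityCurve:
    def test_se_zero_at_pool_size(self, small_table):
        (summary,) = predictability_curve(small_table, [6], n_trials=4, rng_seed=0)
        assert summary.se == 0.0
        assert summary.ci95_half_width == 0.0
        assert summary.n_trials == 4

    def test_ci_is_1_96_se(self, small_table):
        (summary,) = predictability_curve(small_table, [2], n_trials=6, rng_seed=0)
        assert summary.ci95_half_width == pytest.approx(1.96 * summary.se)

    def test_surrogate_means_attached_when_requested(self, small_table):
        (summary,) = predictability_curve(
            small_table, [3], n_trials=2, n_surrogates=2, rng_seed=0
        )
        assert summary.mean_surrogate_rho is not None
        assert -1 <= summary.mean_surrogate_rho <= 1

    def test_all_failed_size_flagged_invalid(self):
        t = table_from({"a": [2.0] * 40, "b": [3.0] * 40})
        (summary,) = predictability_curve(t, [2], n_trials=3, rng_seed=0)
        assert not summary.valid
        assert summary.n_failed == 3


class TestCoefficientOfVariation:
    def test_constant_series_has_zero_cv(self):
        t = table_from({"a": [4.0] * 24})
        assert coefficient_of_variation(aggregate(t, ["a"])) == 0.0

    def test_antiphase_members_cancel(self):
        n = 48
        tt = np.arange(n)
        up = np.sin(2 * np.pi * tt / 12) + 2
        down = -np.sin(2 * np.pi * tt / 12) + 2
        t = table_from({"a": up, "b": down})
        assert coefficient_of_variation(aggregate(t, ["a", "b"])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_portfolio_scaling_of_iid_members(self):
        rng = np.random.default_rng(77)
        n_months = 600
        members = {
            f"m{i:03d}": np.abs(rng.normal(100, 10, n_months)) for i in range(64)
        }
        t = table_from(members)
        cv1 = np.mean(
            [coefficient_of_variation(aggregate(t, [tid]))
             for tid in list(members)[:16]]
        )
        for m in (4, 16, 64):
            cv_m = coefficient_of_variation(aggregate(t, list(members)[:m]))
            assert cv_m == pytest.approx(cv1 / np.sqrt(m), rel=0.2)

    def test_undefined_cv(self):
        t = table_from({"a": [0.0] * 24})
        with pytest.raises(UndefinedCVError):
            coefficient_of_variation(aggregate(t, ["a"]))


class TestExclusionFilter:
    def test_top_quarter_by_abundance_removed(self):
        t = table_from({"a": [10.0] * 30, "b": [20.0] * 30,
                        "c": [30.0] * 30, "d": [40.0] * 30})
        kept = exclusion_filter(t, "abundance", 0.25)
        assert kept.taxon_ids == ["a", "b", "c"]

    def test_ceil_rounding_on_198_taxa(self):
        rng = np.random.default_rng(1)
        t = table_from(
            {f"t{i:03d}": np.abs(rng.normal(10 + i, 1, 24)) for i in range(198)}
        )
        kept = exclusion_filter(t, "abundance", 0.25)
        assert len(kept) == 148

    def test_most_predictable_taxon_removed(self):
        rng = np.random.default_rng(2)
        n = 120
        vals = {"noisy%d" % i: np.abs(rng.normal(10, 3, n)) for i in range(3)}
        vals["sine"] = np.sin(2 * np.pi * np.arange(n) / 12) + 2
        t = table_from(vals)
        kept = exclusion_filter(t, "predictability", 0.25)
        assert "sine" not in kept.taxon_ids
        assert len(kept) == 3
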
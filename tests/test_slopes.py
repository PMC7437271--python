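import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainaging.simulate import default_specs, generate_cohort
from brainaging.slopes import (
    SlopeEstimate,
    apoe_effect,
    bootstrap_slope_ci,
    compare_cis,
    fit_group_slope,
    group_slopes,
    relative_volume,
    substream_rng,
)

from conftest import make_group_records, make_spec


class TestRelativeVolume:
    def test_simple_ratio(self):
        assert relative_volume(150_000, 1_500_000) == pytest.approx(10.0)

    def test_zero_volume(self):
        assert relative_volume(0.0, 1.2e6) == 0.0

    def test_scale_invariance(self):
        assert relative_volume(1.3 * 150_000, 1.3 * 1_500_000) == pytest.approx(
            relative_volume(150_000, 1_500_000)
        )

    def test_nonpositive_icv_rejected(self):
        with pytest.raises(ValueError, match="icv"):
            relative_volume(100.0, 0.0)

    def test_vectorized(self):
        out = relative_volume(np.array([1.0, 2.0]), np.array([10.0, 10.0]))
        np.testing.assert_allclose(out, [10.0, 20.0])


class TestFitGroupSlope:
    def test_constant_relative_volume_gives_zero(self):
        ages = np.linspace(65, 85, 20)
        records = make_group_records(ages, np.full(20, 3.0))
        apc, raw = fit_group_slope(records, "brain")
        assert apc == pytest.approx(0.0, abs=1e-12)
        assert raw == pytest.approx(0.0, abs=1e-14)

    def test_arithmetic_oracle(self):
        # r = 80 - 0.32*(age-65); ages evenly spaced on [65, 85] -> mean r = 76.8
        ages = np.linspace(65, 85, 41)
        rel = 80.0 - 0.32 * (ages - 65.0)
        records = make_group_records(ages, rel)
        apc, raw = fit_group_slope(records, "brain")
        assert raw == pytest.approx(-0.32, rel=1e-10)
        assert apc == pytest.approx(100 * (-0.32) / 76.8, rel=1e-10)  # = -0.41667

    def test_all_ages_equal_rejected(self):
        records = make_group_records([70, 70, 70], [3.0, 3.1, 2.9])
        with pytest.raises(ValueError, match="ages equal"):
            fit_group_slope(records, "brain")

    def test_too_few_records_rejected(self):
        records = make_group_records([70, 75], [3.0, 3.1])
        with pytest.raises(ValueError, match="at least 3"):
            fit_group_slope(records, "brain")

    def test_apc_invariant_to_global_volume_rescaling(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(65, 85, 50)
        rel = 5.0 - 0.05 * (ages - 65) + rng.normal(0, 0.2, 50)
        a = make_group_records(ages, rel, icv=1.5e6)
        # scale both volume and ICV by 1.3: relative volumes unchanged
        b = make_group_records(ages, rel, icv=1.5e6 * 1.3)
        assert fit_group_slope(a, "brain")[0] == pytest.approx(
            fit_group_slope(b, "brain")[0], rel=1e-12
        )


class TestBootstrapSlopeCI:
    def test_zero_noise_degenerate_ci(self):
        ages = np.linspace(65, 85, 30)
        rel = 80.0 - 0.3 * (ages - 65.0)
        records = make_group_records(ages, rel)
        est = bootstrap_slope_ci(records, "brain", B=500, seed=1)
        truth = fit_group_slope(records, "brain")[0]
        # every resample fits the same line; CI collapses onto the APC of the
        # resample (tiny spread from varying mean relative volume only)
        assert est.ci_high - est.ci_low < 0.02
        assert est.slope == pytest.approx(truth, rel=1e-12)
        assert est.significant

    def test_point_estimate_equals_plain_fit(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(65, 85, 80)
        rel = 3.0 - 0.02 * (ages - 65) + rng.normal(0, 0.15, 80)
        records = make_group_records(ages, rel)
        est = bootstrap_slope_ci(records, "brain", B=200, seed=3)
        assert est.slope == fit_group_slope(records, "brain")[0]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(65, 85, 60)
        rel = 3.0 - 0.02 * (ages - 65) + rng.normal(0, 0.2, 60)
        records = make_group_records(ages, rel)
        a = bootstrap_slope_ci(records, "brain", B=400, seed=7)
        b = bootstrap_slope_ci(records, "brain", B=400, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_small_B_warns(self):
        records = make_group_records([65, 70, 75, 80], [3.0, 2.9, 2.8, 2.7])
        with pytest.warns(UserWarning, match="very small"):
            bootstrap_slope_ci(records, "brain", B=50, seed=0)

    def test_invalid_level_rejected(self):
        records = make_group_records([65, 70, 75], [3.0, 2.9, 2.8])
        with pytest.raises(ValueError, match="level"):
            bootstrap_slope_ci(records, "brain", B=200, level=1.5, seed=0)

    def test_ci_width_shrinks_with_n(self, small_region_set):
        """Doubling n shrinks the median CI width by a factor in [0.6, 0.8]."""
        widths = {}
        for n in (100, 200):
            ws = []
            for rep in range(30):
                spec = make_spec(n=n, true_apc=-0.5, noise_sd=2.0)
                cohort = generate_cohort([spec], seed=500 + rep, region_set=small_region_set)
                est = bootstrap_slope_ci(list(cohort), "brain", B=400, seed=rep)
                ws.append(est.ci_high - est.ci_low)
            widths[n] = np.median(ws)
        ratio = widths[200] / widths[100]
        assert 0.6 <= ratio <= 0.8


class TestCompareCIs:
    def _est(self, lo, hi, group="g", region="brain"):
        return SlopeEstimate(
            group=group, region=region, slope=(lo + hi) / 2, ci_low=lo, ci_high=hi,
            n=100, B=1000, seed=0,
        )

    def test_published_brain_female_pair_significant(self):
        # Caucasian vs Korean female brain-volume intervals are disjoint
        caucasian = self._est(-1.152, -0.574, "caucasian/female")
        korean = self._est(-0.486, -0.329, "korean/female")
        assert compare_cis(caucasian, korean).significant

    def test_published_cingulate_female_pair_not_significant(self):
        caucasian = self._est(-1.069, -0.275, "caucasian/female", region="cingulate")
        korean = self._est(-0.364, -0.074, "korean/female", region="cingulate")
        assert not compare_cis(caucasian, korean).significant

    def test_identical_intervals_not_significant(self):
        assert not compare_cis(self._est(-1, 0), self._est(-1, 0)).significant

    def test_touching_endpoints_count_as_overlap(self):
        assert not compare_cis(self._est(-2.0, -1.0), self._est(-1.0, 0.0)).significant

    def test_symmetric(self):
        a, b = self._est(-2.0, -1.5, "a"), self._est(-1.0, 0.0, "b")
        assert compare_cis(a, b).significant == compare_cis(b, a).significant

    def test_region_mismatch_rejected(self):
        with pytest.raises(ValueError, match="region mismatch"):
            compare_cis(self._est(-1, 0, region="brain"), self._est(-1, 0, region="insular"))

    @given(
        lows=st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
        widths=st.tuples(st.floats(0, 3), st.floats(0, 3)),
    )
    @settings(max_examples=50, deadline=None)
    def test_significant_iff_disjoint(self, lows, widths):
        a = self._est(lows[0], lows[0] + widths[0])
        b = self._est(lows[1], lows[1] + widths[1])
        expected = a.ci_high < b.ci_low or b.ci_high < a.ci_low
        assert compare_cis(a, b).significant == expected


class TestApoeEffect:
    def _mixed_records(self, seed, n=200, apc_c=-1.0, apc_n=-0.4, freq=0.3, noise=1.0,
                       small_region_set=None):
        spec = make_spec(n=n, true_apc=apc_n, carrier_apc=apc_c, noise_sd=noise,
                         apoe_e4_freq=freq, apoe_missing_rate=0.0)
        cohort = generate_cohort([spec], seed=seed, region_set=small_region_set)
        return list(cohort)

    def test_effect_is_carrier_minus_noncarrier(self, small_region_set):
        records = self._mixed_records(1, noise=0.0, small_region_set=small_region_set)
        eff = apoe_effect(records, "brain", B=300, seed=2)
        assert eff.effect == pytest.approx(-1.0 - (-0.4), abs=1e-9)

    def test_null_case_ci_contains_zero(self, small_region_set):
        records = self._mixed_records(3, apc_c=-0.5, apc_n=-0.5, noise=1.5,
                                      small_region_set=small_region_set)
        eff = apoe_effect(records, "brain", B=800, seed=4)
        assert eff.ci_low <= 0.0 <= eff.ci_high

    def test_empty_stratum_rejected(self):
        records = make_group_records(
            np.linspace(65, 85, 10), np.linspace(3, 2.8, 10), carriers=[False] * 10
        )
        with pytest.raises(ValueError, match="strata"):
            apoe_effect(records, "brain", B=100, seed=0)

    def test_records_without_flags_dropped(self, small_region_set):
        records = self._mixed_records(5, small_region_set=small_region_set)
        from dataclasses import replace

        # null out flags for a handful; result should equal dropping them
        blanked = [
            replace(r, apoe_carrier=None, apoe_genotype=None) if i < 10 else r
            for i, r in enumerate(records)
        ]
        a = apoe_effect(blanked, "brain", B=200, seed=6)
        b = apoe_effect(records[10:], "brain", B=200, seed=6)
        assert a.effect == b.effect
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_deterministic(self, small_region_set):
        records = self._mixed_records(7, small_region_set=small_region_set)
        a = apoe_effect(records, "brain", B=300, seed=8)
        b = apoe_effect(records, "brain", B=300, seed=8)
        assert (a.effect, a.ci_low, a.ci_high) == (b.effect, b.ci_low, b.ci_high)


class TestGroupSlopes:
    def test_order_independence(self, region_set):
        cohort = generate_cohort(default_specs(), seed=12)
        shuffled = cohort.subset(lambda r: True)  # copy
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cohort))
        from dataclasses import replace

        shuffled = replace(cohort, records=tuple(cohort.records[i] for i in perm))
        a = group_slopes(cohort, B=200, seed=5, regions=["brain"])
        b = group_slopes(shuffled, B=200, seed=5, regions=["brain"])
        key = lambda ests: {e.group: (e.slope, e.ci_low, e.ci_high) for e in ests}
        assert key(a) == key(b)

    def test_substreams_differ_across_cells(self):
        a = substream_rng(1, "slope", "g1", "brain").integers(0, 2**32)
        b = substream_rng(1, "slope", "g1", "insular").integers(0, 2**32)
        c = substream_rng(1, "slope", "g2", "brain").integers(0, 2**32)
        assert len({int(a), int(b), int(c)}) == 3

    def test_conservative_vs_difference_bootstrap(self, small_region_set):
        """CI non-overlap implies the difference bootstrap also excludes 0."""
        hits = 0
        for rep in range(12):
            spec_a = make_spec(n=150, true_apc=-1.2, noise_sd=1.2, ethnicity="caucasian")
            spec_b = make_spec(n=150, true_apc=-0.3, noise_sd=1.2)
            ca = generate_cohort([spec_a], seed=900 + rep, region_set=small_region_set)
            cb = generate_cohort([spec_b], seed=950 + rep, region_set=small_region_set)
            ea = bootstrap_slope_ci(list(ca), "brain", B=500, seed=rep, group="a")
            eb = bootstrap_slope_ci(list(cb), "brain", B=500, seed=rep, group="b")
            if compare_cis(ea, eb).significant:
                hits += 1
                # difference bootstrap with independent resampling
                rng = np.random.default_rng(rep)
                from brainaging.slopes import _bootstrap_apcs, _group_arrays

                ages_a, rel_a = _group_arrays(list(ca), "brain")
                ages_b, rel_b = _group_arrays(list(cb), "brain")
                diffs = _bootstrap_apcs(ages_a, rel_a, 500, rng) - _bootstrap_apcs(
                    ages_b, rel_b, 500, rng
                )
                lo, hi = np.quantile(diffs, [0.025, 0.975])
                assert not (lo <= 0.0 <= hi)
        assert hits > 0  # the scenario actually exercises the implication
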
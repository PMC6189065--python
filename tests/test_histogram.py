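"""Histogram-statistic oracles: the hand-worked 4-bin example, closed forms,
a brute-force moment oracle, and the DLE map identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungexpand import (BinaryMask, DisplacementField, HistogramConfig,
                        PERCENTILES, dle_maps, histogram_summary,
                        reference_vc, regional_summaries)
from lungexpand.histogram import binned_distribution


def _uniform_field(shape, vec, spacing=(1.0, 1.0, 1.0)):
    v = np.broadcast_to(np.asarray(vec, float), shape + (3,)).copy()
    return DisplacementField(v, spacing=spacing)


def _full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.ones(shape, bool), spacing=spacing)


class TestDLEMaps:
    def test_pythagorean_3_4_12_13(self):
        shape = (6, 6, 6)
        dmap = dle_maps(_uniform_field(shape, (3.0, 4.0, 12.0)),
                        _full_mask(shape), split_z=2.5)
        assert np.all(dmap.dle_x == 3.0)
        assert np.all(dmap.dle_y == 4.0)
        assert np.all(dmap.dle_z == 12.0)
        np.testing.assert_allclose(dmap.dle_3d, 13.0)

    def test_zero_field(self):
        shape = (5, 5, 5)
        dmap = dle_maps(_uniform_field(shape, (0, 0, 0)), _full_mask(shape),
                        split_z=2.0)
        assert dmap.dle_3d.max() == 0.0

    def test_absolute_value_convention(self):
        shape = (4, 4, 4)
        dmap = dle_maps(_uniform_field(shape, (-5.0, 0, 0)),
                        _full_mask(shape), split_z=1.5)
        assert np.all(dmap.dle_x == 5.0)

    def test_euclidean_identity_on_random_field(self):
        rng = np.random.default_rng(0)
        shape = (7, 7, 7)
        f = DisplacementField(rng.normal(0, 5, shape + (3,)),
                              spacing=(1, 1, 1))
        dmap = dle_maps(f, _full_mask(shape), split_z=3.0)
        lhs = dmap.dle_3d ** 2
        rhs = dmap.dle_x ** 2 + dmap.dle_y ** 2 + dmap.dle_z ** 2
        assert np.abs(lhs - rhs).max() < 1e-9
        assert np.all(dmap.dle_3d + 1e-12
                      >= np.maximum(dmap.dle_x,
                                    np.maximum(dmap.dle_y, dmap.dle_z)))

    def test_split_outside_mask_rejected(self):
        shape = (4, 4, 4)
        with pytest.raises(ValueError, match="split_z"):
            dle_maps(_uniform_field(shape, (1, 1, 1)), _full_mask(shape),
                     split_z=99.0)


class TestHistogramSummary:
    def test_hand_worked_four_bin_example(self):
        values = np.array([1, 2, 2, 3, 3, 3, 4, 4, 4, 4], dtype=float)
        cfg = HistogramConfig(bin_width=1.0, bin_origin=-0.5)  # integer centers
        s = histogram_summary(values, cfg)
        assert s.mean == pytest.approx(3.0, abs=1e-12)
        assert s.sd == pytest.approx(1.0, abs=1e-12)
        assert s.skewness == pytest.approx(-0.6, abs=1e-12)
        assert s.kurtosis == pytest.approx(2.2, abs=1e-12)
        assert s.uniformity == pytest.approx(0.30, abs=1e-12)
        assert s.entropy == pytest.approx(1.8464, abs=1e-4)

    def test_degenerate_distribution(self):
        s = histogram_summary(np.full(50, 5.0))
        # 1 mm bins anchored at 0: the single occupied bin has center 5.5
        assert s.mean == pytest.approx(5.5)
        assert s.sd == 0.0
        assert s.skewness is None and s.kurtosis is None
        assert s.entropy == 0.0
        assert s.uniformity == 1.0
        assert all(v == 5.0 for v in s.percentiles.values())
        s2 = histogram_summary(np.full(50, 5.0), HistogramConfig(bin_width=0.1))
        assert s2.mean == pytest.approx(5.05)

    def test_uniform_bins_closed_form(self):
        n = 16
        values = np.repeat(np.arange(n) + 0.5, 7)
        s = histogram_summary(values)
        assert s.entropy == pytest.approx(np.log2(n), abs=1e-12)
        assert s.uniformity == pytest.approx(1.0 / n, abs=1e-12)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.gamma(3.0, 4.0, size=rng.integers(5, 400))
            _, p = binned_distribution(vals, HistogramConfig())
            assert abs(p.sum() - 1.0) < 1e-12

    def test_moments_match_brute_force_oracle(self):
        # independent oracle: explicit python-loop weighted moments
        from collections import Counter
        rng = np.random.default_rng(42)
        for trial in range(200):
            vals = rng.gamma(rng.uniform(1, 5), rng.uniform(1, 6),
                             size=rng.integers(10, 300))
            cfg = HistogramConfig(bin_width=1.0)
            s = histogram_summary(vals, cfg)
            counts = Counter(int(v // 1.0) for v in vals)
            total = sum(counts.values())
            m = sum((i + 0.5) * c / total for i, c in counts.items())
            var = sum(((i + 0.5) - m) ** 2 * c / total
                      for i, c in counts.items())
            sd = var ** 0.5
            assert abs(s.mean - m) <= 1e-10 * max(1.0, abs(m))
            assert abs(s.sd - sd) <= 1e-10 * max(1.0, sd)
            if sd > 0:
                sk = sum(((i + 0.5) - m) ** 3 * c / total
                         for i, c in counts.items()) / sd ** 3
                ku = sum(((i + 0.5) - m) ** 4 * c / total
                         for i, c in counts.items()) / sd ** 4
                ent = -sum((c / total) * np.log2(c / total)
                           for c in counts.values())
                uni = sum((c / total) ** 2 for c in counts.values())
                assert abs(s.skewness - sk) <= 1e-10 * max(1.0, abs(sk))
                assert abs(s.kurtosis - ku) <= 1e-10 * max(1.0, ku)
                assert abs(s.entropy - ent) <= 1e-10 * max(1.0, ent)
                assert abs(s.uniformity - uni) <= 1e-10

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 80.0), min_size=3, max_size=60),
           st.floats(1.3, 4.0))
    def test_scaling_property(self, values, c):
        values = np.asarray(values)
        base = histogram_summary(values, HistogramConfig(bin_width=1.0))
        scaled = histogram_summary(values * c, HistogramConfig(bin_width=c))
        assert scaled.mean == pytest.approx(c * base.mean, rel=1e-9)
        assert scaled.sd == pytest.approx(c * base.sd, abs=1e-9)
        if base.sd > 0:
            assert scaled.skewness == pytest.approx(base.skewness, rel=1e-6,
                                                    abs=1e-9)
        assert scaled.entropy == pytest.approx(base.entropy, abs=1e-9)
        assert scaled.uniformity == pytest.approx(base.uniformity, abs=1e-9)
        for q in PERCENTILES:
            assert scaled.percentiles[q] == pytest.approx(
                c * base.percentiles[q], rel=1e-9, abs=1e-9)

    def test_percentiles_non_decreasing_and_standardization(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2, 5, 500)
        s = histogram_summary(vals, vc_ref=2.5)
        ordered = [s.percentiles[q] for q in PERCENTILES]
        assert all(a <= b for a, b in zip(ordered, ordered[1:]))
        assert s.standardized_mean == pytest.approx(s.mean / 2.5)
        assert s.standardized_sd == pytest.approx(s.sd / 2.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            histogram_summary(np.array([]))


class TestRegionalSummaries:
    def _phantom_map(self, small_phantom):
        exp_vol, mask, truth = small_phantom
        field = DisplacementField(truth.field.dense(exp_vol),
                                  spacing=exp_vol.spacing)
        return dle_maps(field, mask, truth.split_z)

    def test_partition_counts(self, small_phantom):
        dmap = self._phantom_map(small_phantom)
        df = regional_summaries(dmap)
        assert len(df) == 4 * 3 * 3
        for side in ("right", "left", "both"):
            for axis in ("x", "y", "z", "3d"):
                sub = df[(df.axis == axis) & (df.side == side)]
                whole = sub[sub.zone == "whole"].n_voxels.item()
                parts = sub[sub.zone != "whole"].n_voxels.sum()
                assert whole == parts

    def test_basal_weighted_field_direction(self, small_phantom):
        # craniocaudal expansion dominates in the lower lung
        dmap = self._phantom_map(small_phantom)
        df = regional_summaries(dmap).set_index(["axis", "zone", "side"])
        assert (df.loc[("z", "lower", "both"), "mean"]
                > df.loc[("z", "upper", "both"), "mean"])

    def test_uniform_field_identical_zones(self):
        shape = (6, 6, 6)
        dmap = dle_maps(_uniform_field(shape, (2.0, 1.0, 3.0)),
                        _full_mask(shape), split_z=2.5)
        df = regional_summaries(dmap).set_index(["axis", "zone", "side"])
        for axis in ("x", "y", "z", "3d"):
            vals = [df.loc[(axis, z, "both"), "mean"]
                    for z in ("whole", "upper", "lower")]
            assert len(set(np.round(vals, 12))) == 1


class TestReferenceVC:
    EQ = {"female": {"tlc": {"intercept": 6.0}, "rv": {"intercept": 2.0}}}

    def test_constant_predictors(self):
        assert reference_vc(60, 1.55, "female", self.EQ) == pytest.approx(4.0)

    def test_rv_exceeding_tlc_rejected(self):
        bad = {"female": {"tlc": {"intercept": 2.0}, "rv": {"intercept": 5.0}}}
        with pytest.raises(ValueError, match="nonpositive"):
            reference_vc(60, 1.55, "female", bad)

    def test_linear_coefficients_hand_check(self):
        eq = {"female": {"tlc": {"intercept": -4.0, "height": 6.6,
                                 "age": 0.01},
                         "rv": {"intercept": -1.5, "height": 2.2,
                                "age": 0.02}}}
        got = reference_vc(60, 1.55, "female", eq)
        tlc = -4.0 + 6.6 * 1.55 + 0.01 * 60
        rv = -1.5 + 2.2 * 1.55 + 0.02 * 60
        assert got == pytest.approx(tlc - rv)

    def test_missing_coefficients(self):
        with pytest.raises(ValueError, match="missing"):
            reference_vc(60, 1.55, "male", self.EQ)
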
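"""Endpoint estimation, the dimidiate model, clamping, and grading."""

import math

import numpy as np
import pytest

from rgbfvc import (ContractError, DegenerateDistributionError, compute_fvc,
                    estimate_endpoints, grade_area_fractions, grade_map,
                    make_endpoints, mean_fvc)
from rgbfvc.dichotomy import FVCMap, GradeScheme
from rgbfvc.indices import IndexDefinition

from conftest import make_index_image


def rank_oracle(values, q):
    """Sort-and-count nearest-rank percentile: the ceil(q*n)-th sorted value."""
    s = sorted(values)
    return s[max(math.ceil(q * len(s)), 1) - 1]


class TestEstimateEndpoints:
    def test_integers_1_to_100(self):
        vi = make_index_image(np.arange(1, 101, dtype=float).reshape(10, 10))
        ep = estimate_endpoints(vi, 0.02)
        assert (ep.vi_soil, ep.vi_veg) == (2.0, 98.0)

    def test_decreasing_polarity_swaps_tails(self):
        vi = make_index_image(np.arange(1, 101, dtype=float).reshape(10, 10), name="CIVE")
        ep = estimate_endpoints(vi, 0.02)
        assert (ep.vi_soil, ep.vi_veg) == (98.0, 2.0)

    def test_constant_image_degenerate(self):
        vi = make_index_image(np.full((20, 20), 3.7))
        with pytest.raises(DegenerateDistributionError):
            estimate_endpoints(vi)

    def test_too_few_pixels(self):
        vi = make_index_image(np.arange(99, dtype=float).reshape(9, 11))
        with pytest.raises(ContractError, match="at least"):
            estimate_endpoints(vi)

    @pytest.mark.parametrize("confidence", [0.0, 0.5, 0.7])
    def test_confidence_out_of_range(self, confidence):
        vi = make_index_image(np.arange(100, dtype=float).reshape(10, 10))
        with pytest.raises(ContractError):
            estimate_endpoints(vi, confidence)

    @pytest.mark.parametrize("n", [101, 257, 1000, 9973])
    @pytest.mark.parametrize("confidence", [0.02, 0.05, 0.1])
    def test_agrees_with_sort_oracle(self, rng, n, confidence):
        values = rng.normal(size=n)
        vi = make_index_image(values.reshape(1, -1))
        ep = estimate_endpoints(vi, confidence)
        assert ep.vi_soil == rank_oracle(values, confidence)
        assert ep.vi_veg == rank_oracle(values, 1 - confidence)

    def test_invalid_pixels_excluded(self, rng):
        values = np.concatenate([rng.uniform(0, 1, 200), np.full(50, 1e6)])
        mask = np.concatenate([np.ones(200, bool), np.zeros(50, bool)])
        vi = make_index_image(values.reshape(1, -1), mask=mask.reshape(1, -1))
        ep = estimate_endpoints(vi)
        assert ep.vi_veg <= 1.0  # the masked extreme values never leak in


class TestComputeFVC:
    def test_cive_clamping_published_endpoints(self):
        """Pixels beyond the soil endpoint are bare; beyond the veg endpoint, full cover."""
        ep = make_endpoints(0.105882, -0.819608, "CIVE")
        vi = make_index_image(np.array([[0.2, -0.9, 0.105882, -0.819608]]), name="CIVE")
        f = compute_fvc(vi, ep)
        np.testing.assert_array_equal(f.values, [[0.0, 1.0, 0.0, 1.0]])

    def test_midpoint_maps_to_half(self):
        ep = make_endpoints(10.0, 30.0, "EXG")
        vi = make_index_image(np.array([[20.0]]))
        assert compute_fvc(vi, ep).values[0, 0] == pytest.approx(0.5)

    def test_index_mismatch_rejected(self):
        ep = make_endpoints(0.0, 1.0, "GRVI")
        vi = make_index_image(np.array([[0.5]]), name="EXG")
        with pytest.raises(ContractError, match="does not match"):
            compute_fvc(vi, ep)

    def test_endpoint_polarity_consistency_enforced(self):
        with pytest.raises(ContractError, match="polarity"):
            make_endpoints(5.0, 1.0, "EXG")  # increasing index needs soil < veg
        with pytest.raises(DegenerateDistributionError):
            make_endpoints(1.0, 1.0, "EXG")

    def test_affine_invariance(self, rng):
        """x -> a*x + b applied to image and endpoints leaves FVC unchanged."""
        values = rng.normal(size=(37, 41))
        vi = make_index_image(values)
        ep = estimate_endpoints(vi, 0.02)
        f0 = compute_fvc(vi, ep)
        for a, b in [(3.5, -11.0), (0.01, 4.0), (-2.0, 7.0)]:
            polarity = "increasing" if a > 0 else "decreasing"
            definition = IndexDefinition(name="EXG", polarity=polarity)
            vi2 = make_index_image(a * values + b)
            vi2.index = definition
            ep2 = make_endpoints(a * ep.vi_soil + b, a * ep.vi_veg + b, definition)
            f2 = compute_fvc(vi2, ep2)
            np.testing.assert_allclose(f2.values, f0.values, atol=1e-9)

    def test_polarity_symmetry_generic_case(self, rng):
        """Negating values and flipping polarity reproduces the FVC map when
        the confidence cut does not land exactly on a rank boundary."""
        values = rng.normal(size=(13, 21))  # 273 pixels: 0.02*273 not integer
        vi = make_index_image(values)
        f0 = compute_fvc(vi, estimate_endpoints(vi, 0.02))
        vi_neg = make_index_image(-values)
        vi_neg.index = IndexDefinition(name="EXG", polarity="decreasing")
        f1 = compute_fvc(vi_neg, estimate_endpoints(vi_neg, 0.02))
        np.testing.assert_allclose(f1.values, f0.values, atol=1e-12)

    def test_polarity_symmetry_rank_boundary(self, rng):
        """When confidence*n is an integer the mirrored estimate sits one order
        statistic away; endpoints differ by exactly one rank, no more."""
        n = 200  # 0.02 * 200 = 4, an exact rank boundary
        values = np.sort(rng.normal(size=n))
        vi = make_index_image(values.reshape(1, -1))
        ep = estimate_endpoints(vi, 0.02)
        vi_neg = make_index_image(-values.reshape(1, -1))
        vi_neg.index = IndexDefinition(name="EXG", polarity="decreasing")
        ep_neg = estimate_endpoints(vi_neg, 0.02)
        assert -ep_neg.vi_soil in (values[3], values[4])
        assert ep.vi_soil == values[3]

    def test_clamped_fractions_respect_confidence(self, rng):
        """About a confidence-share of pixels pins to each of 0 and 1."""
        values = rng.normal(size=(100, 100))
        vi = make_index_image(values)
        f = compute_fvc(vi, estimate_endpoints(vi, 0.02))
        n = values.size
        assert np.count_nonzero(f.values == 0.0) >= int(0.02 * n) - 1
        assert np.count_nonzero(f.values == 1.0) >= int(0.02 * n) - 1
        assert f.values.min() >= 0.0 and f.values.max() <= 1.0

    def test_invalid_pixels_stay_invalid(self):
        ep = make_endpoints(0.0, 1.0, "EXG")
        mask = np.array([[True, False]])
        vi = make_index_image(np.array([[0.5, np.nan]]), mask=mask)
        f = compute_fvc(vi, ep)
        assert not f.valid_mask[0, 1]
        assert np.isnan(f.values[0, 1])


class TestMeanFVC:
    def test_constant_and_symmetric(self):
        mask = np.ones((2, 2), bool)
        assert mean_fvc(FVCMap(np.full((2, 2), 0.5), None, mask)) == 0.5
        assert mean_fvc(FVCMap(np.array([[0.0, 1.0], [1.0, 0.0]]), None, mask)) == 0.5

    def test_matches_scalar_loop(self, rng):
        values = rng.uniform(0, 1, (32, 32))
        mask = rng.uniform(size=(32, 32)) > 0.1
        fvc = FVCMap(np.where(mask, values, np.nan), None, mask)
        total = count = 0
        for i in range(32):
            for j in range(32):
                if mask[i, j]:
                    total += values[i, j]
                    count += 1
        assert mean_fvc(fvc) == pytest.approx(total / count, abs=1e-12)

    def test_empty_mask_rejected(self):
        fvc = FVCMap(np.full((2, 2), np.nan), None, np.zeros((2, 2), bool))
        with pytest.raises(ContractError):
            mean_fvc(fvc)


class TestGrading:
    def scalar_grade(self, f, scheme):
        if scheme.zero_class and f == 0.0:
            return 0
        bounds = [0.2, 0.4, 0.6, 0.8, 1.0 + 1e-15]
        for k, upper in enumerate(bounds):
            if f < upper or (upper > 1 and f == 1.0):
                return k + (1 if scheme.zero_class else 1)
        raise AssertionError

    @pytest.mark.parametrize("f,scheme,expected", [
        (0.0, "six_level", 0),    # dedicated zero class
        (1.0, "five_level", 5),   # top grade includes 1.0
        (0.2, "five_level", 2),   # lower-inclusive boundary
        (0.2, "six_level", 2),
        (1e-9, "six_level", 1),   # any positive cover leaves the zero class
        (0.0, "five_level", 1),
    ])
    def test_boundary_examples(self, f, scheme, expected):
        fvc = FVCMap(np.array([[f]]), None, np.ones((1, 1), bool))
        assert grade_map(fvc, scheme).grades[0, 0] == expected

    @pytest.mark.parametrize("scheme_name", ["five_level", "six_level"])
    def test_matches_scalar_oracle(self, rng, scheme_name):
        scheme = GradeScheme.by_name(scheme_name)
        values = rng.uniform(0, 1, (20, 20))
        values.ravel()[::17] = 0.0  # exercise the zero class
        values.ravel()[::23] = 1.0
        fvc = FVCMap(values, None, np.ones((20, 20), bool))
        grades = grade_map(fvc, scheme).grades
        for i in range(20):
            for j in range(20):
                assert grades[i, j] == self.scalar_grade(values[i, j], scheme)

    def test_area_fractions_counting(self):
        grades = grade_map(FVCMap(np.array([[0.1, 0.1], [0.1, 0.9]]), None,
                                  np.ones((2, 2), bool)), "five_level")
        shares = grade_area_fractions(grades)
        assert shares[1] == 0.75 and shares[5] == 0.25
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_area_fractions_sum_to_one(self, rng):
        values = rng.uniform(0, 1, (50, 50))
        mask = rng.uniform(size=(50, 50)) > 0.2
        fvc = FVCMap(np.where(mask, values, np.nan), None, mask)
        shares = grade_area_fractions(grade_map(fvc, "six_level"))
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_one_grade(self):
        fvc = FVCMap(np.full((3, 3), 0.5), None, np.ones((3, 3), bool))
        shares = grade_area_fractions(grade_map(fvc, "five_level"))
        assert shares[3] == 1.0
        assert all(v == 0.0 for k, v in shares.items() if k != 3)
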
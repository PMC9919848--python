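import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dfret import (
    DistanceDistribution,
    choose_r_max,
    evaluate_pdf,
    inverse_sixth_moment,
    make_distribution,
    normalize,
    sample,
)
from dfret.errors import DivergenceError, DomainError, InvalidParametersError

from conftest import dense_trapezoid


class TestEvaluatePdf:
    def test_shifted_vanishes_at_left_limit(self):
        dist = make_distribution("ideal_chain_shifted", b=20.0, r_min=3.0)
        assert evaluate_pdf(dist, 3.0) == 0.0

    def test_shifted_continuity_near_left_limit(self):
        dist = make_distribution("ideal_chain_shifted", b=20.0, r_min=3.0)
        eps = np.array([1e-2, 1e-4, 1e-6])
        vals = evaluate_pdf(dist, 3.0 + eps)
        assert np.all(np.diff(vals) < 0)  # decreasing toward 0
        assert vals[-1] < 1e-10

    def test_legacy_rms_equals_b(self):
        # on an effectively untruncated support the root second moment is b
        b = 17.0
        dist = make_distribution("ideal_chain_legacy", b=b, r_min=0.0, r_max=40.0 * b)
        m2 = dense_trapezoid(
            lambda r: evaluate_pdf(dist, r) * r**2, 0.0, dist.r_max, n=2_000_001
        )
        assert np.sqrt(m2) == pytest.approx(b, rel=1e-9)

    def test_outside_support_raises(self):
        dist = make_distribution("ideal_chain_shifted", b=20.0, r_min=3.0)
        with pytest.raises(DomainError):
            evaluate_pdf(dist, 2.0)
        with pytest.raises(DomainError):
            evaluate_pdf(dist, dist.r_max + 1.0)

    def test_legacy_and_shifted_coincide_at_zero_left_limit(self):
        legacy = make_distribution("ideal_chain_legacy", b=20.0, r_min=0.0, r_max=90.0)
        shifted = make_distribution("ideal_chain_shifted", b=20.0, r_min=0.0, r_max=90.0)
        r = np.linspace(0.0, 90.0, 301)
        np.testing.assert_allclose(
            evaluate_pdf(legacy, r), evaluate_pdf(shifted, r), rtol=1e-12
        )


class TestNormalize:
    def test_integrates_to_one(self):
        dist = make_distribution("skewed_gaussian_shifted", a=0.01, b=15.0, r_min=2.0)
        total = dense_trapezoid(lambda r: evaluate_pdf(dist, r), dist.r_min, dist.r_max)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_idempotent(self):
        dist = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0)
        again = normalize(dist)
        assert again.norm == pytest.approx(dist.norm, rel=1e-12)

    def test_matches_dense_grid_oracle(self):
        dist = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0, r_max=120.0)
        raw = DistanceDistribution(
            model="ideal_chain_shifted", b=18.0, r_min=3.0, r_max=120.0
        )
        oracle = 1.0 / dense_trapezoid(raw.kernel, 3.0, 120.0)
        assert dist.norm == pytest.approx(oracle, rel=1e-7)

    def test_truncated_support_renormalizes(self):
        # r_max cutting > 1% of the kernel mass still yields a unit integral
        dist = make_distribution("ideal_chain_shifted", b=20.0, r_min=3.0, r_max=22.0)
        total = dense_trapezoid(lambda r: evaluate_pdf(dist, r), 3.0, 22.0)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParametersError):
            DistanceDistribution(model="ideal_chain_shifted", b=-1.0, r_min=3.0, r_max=50.0)
        with pytest.raises(InvalidParametersError):
            DistanceDistribution(model="nope", b=10.0, r_min=3.0, r_max=50.0)
        with pytest.raises(InvalidParametersError):
            DistanceDistribution(model="skewed_gaussian_shifted", b=10.0, r_min=3.0, r_max=50.0)

    @settings(max_examples=25, deadline=None)
    @given(
        b=st.floats(5.0, 40.0),
        rl=st.floats(0.5, 5.0),
        model=st.sampled_from(["ideal_chain_shifted", "ideal_chain_legacy"]),
    )
    def test_property_unit_mass(self, b, rl, model):
        dist = make_distribution(model, b=b, r_min=rl)
        total = dense_trapezoid(
            lambda r: evaluate_pdf(dist, r), dist.r_min, dist.r_max, n=200_001
        )
        assert total == pytest.approx(1.0, abs=1e-8)


class TestInverseSixthMoment:
    def test_near_delta_limit(self):
        # sharply peaked skewed Gaussian at ~10 A behaves like a point mass
        dist = make_distribution(
            "skewed_gaussian_legacy", a=400.0, b=10.0, r_min=8.0, r_max=12.0
        )
        assert inverse_sixth_moment(dist) == pytest.approx(1e-6, rel=1e-3)

    def test_matches_dense_grid_oracle(self):
        dist = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0, r_max=120.0)
        oracle = dense_trapezoid(
            lambda r: evaluate_pdf(dist, r) / r**6, 3.0, 120.0, n=2_000_001
        )
        assert inverse_sixth_moment(dist) == pytest.approx(oracle, rel=1e-6)

    def test_decreasing_left_limit_increases_moment(self):
        hi = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0, r_max=120.0)
        lo = make_distribution("ideal_chain_shifted", b=18.0, r_min=1.5, r_max=120.0)
        assert inverse_sixth_moment(lo) > inverse_sixth_moment(hi)

    def test_zero_left_limit_raises(self):
        dist = make_distribution("ideal_chain_legacy", b=18.0, r_min=0.0, r_max=120.0)
        with pytest.raises(DivergenceError):
            inverse_sixth_moment(dist)


class TestSample:
    def test_mean_matches_quadrature(self):
        dist = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0)
        draws = sample(dist, 100_000, seed=42)
        mean_oracle = dense_trapezoid(
            lambda r: evaluate_pdf(dist, r) * r, dist.r_min, dist.r_max
        )
        sem = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - mean_oracle) < 3.0 * sem

    def test_support(self):
        dist = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0)
        draws = sample(dist, 10_000, seed=1)
        assert draws.min() >= dist.r_min and draws.max() <= dist.r_max

    def test_deterministic(self):
        dist = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0)
        np.testing.assert_array_equal(sample(dist, 1000, seed=9), sample(dist, 1000, seed=9))

    def test_ks_distance_against_quadrature_cdf(self):
        dist = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0)
        draws = sample(dist, 100_000, seed=3)
        grid = np.linspace(dist.r_min, dist.r_max, 20001)
        pdf = evaluate_pdf(dist, grid)
        cdf = np.concatenate(([0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0 * np.diff(grid))))
        cdf /= cdf[-1]
        res = stats.ks_1samp(draws, lambda x: np.interp(x, grid, cdf))
        assert res.statistic < 0.01

    def test_invalid_n(self):
        dist = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0)
        with pytest.raises(DomainError):
            sample(dist, 0, seed=0)


class TestChooseRMax:
    def test_tail_bound_holds(self):
        r_max = choose_r_max("ideal_chain_shifted", b=30.0, r_min=5.0, tail_tolerance=1e-6)
        raw = DistanceDistribution(
            model="ideal_chain_shifted", b=30.0, r_min=5.0, r_max=10_000.0
        )
        total = dense_trapezoid(raw.kernel, 5.0, 10_000.0, n=2_000_001)
        tail = dense_trapezoid(raw.kernel, r_max, 10_000.0, n=2_000_001)
        assert tail / total < 1e-6

    def test_monotone_in_tolerance(self):
        kw = dict(b=20.0, r_min=3.0)
        assert choose_r_max("ideal_chain_shifted", tail_tolerance=1e-8, **kw) >= \
            choose_r_max("ideal_chain_shifted", tail_tolerance=1e-4, **kw)

    def test_monotone_in_b(self):
        assert choose_r_max("ideal_chain_shifted", b=40.0, r_min=3.0) > \
            choose_r_max("ideal_chain_shifted", b=20.0, r_min=3.0)

    def test_tolerance_domain(self):
        with pytest.raises(DomainError):
            choose_r_max("ideal_chain_shifted", b=20.0, r_min=3.0, tail_tolerance=0.5)
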
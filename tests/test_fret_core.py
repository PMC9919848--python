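import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfret import (
    Photophysics,
    augmented_j,
    diffusion_influence,
    dynamic_limit_R,
    efficiency_to_reff,
    forster_rate,
    kfret_from_rates,
    make_distribution,
    profile_abscissa_x,
    reff_from_kfret,
    reff_to_efficiency,
    static_limit_L,
)
from dfret.fret_core import static_efficiency
from dfret.errors import (
    DegenerateAmplitudeError,
    DomainError,
    InvalidParametersError,
    NegativeTransferError,
    UndefinedDistanceError,
)

from conftest import dense_trapezoid


class TestPhotophysics:
    def test_rate_lifetime_inverse(self):
        p = Photophysics(tau_d=100.0, r0=10.0)
        assert p.k_d * p.tau_d == pytest.approx(1.0, abs=1e-12)

    def test_rate_components_must_sum(self):
        Photophysics(tau_d=100.0, r0=10.0, k_rad=0.004, k_nrad=0.006)
        with pytest.raises(InvalidParametersError):
            Photophysics(tau_d=100.0, r0=10.0, k_rad=0.004, k_nrad=0.005)


class TestForsterRate:
    def test_at_r0_gives_kd(self):
        p = Photophysics(tau_d=100.0, r0=10.0)
        assert forster_rate(p, 10.0) == pytest.approx(p.k_d, rel=1e-12)

    def test_at_twice_r0(self):
        p = Photophysics(tau_d=100.0, r0=10.0)
        assert forster_rate(p, 20.0) == pytest.approx(0.01 / 64.0, rel=1e-12)

    def test_strictly_decreasing(self):
        p = Photophysics(tau_d=100.0, r0=10.0)
        r = np.linspace(2.0, 40.0, 100)
        assert np.all(np.diff(forster_rate(p, r)) < 0)

    def test_domain(self):
        with pytest.raises(DomainError):
            forster_rate(Photophysics(tau_d=100.0, r0=10.0), 0.0)


class TestRateConversions:
    @pytest.mark.parametrize(
        "k_da,k_d,expected", [(0.02, 0.01, 0.01), (0.01, 0.01, 0.0), (0.011, 0.010, 0.001)]
    )
    def test_kfret_from_rates(self, k_da, k_d, expected):
        assert kfret_from_rates(k_da, k_d) == pytest.approx(expected, abs=1e-15)

    def test_negative_transfer_raises(self):
        with pytest.raises(NegativeTransferError):
            kfret_from_rates(0.009, 0.01)

    def test_reff_at_kd_is_r0(self):
        p = Photophysics(tau_d=100.0, r0=10.0)
        assert reff_from_kfret(p.k_d, p) == pytest.approx(10.0, rel=1e-12)

    def test_reff_sixth_root(self):
        p = Photophysics(tau_d=100.0, r0=10.0)
        assert reff_from_kfret(64.0 * p.k_d, p) == pytest.approx(5.0, rel=1e-12)

    def test_forster_roundtrip(self):
        p = Photophysics(tau_d=100.0, r0=10.0)
        for x in (3.0, 10.0, 25.0):
            assert reff_from_kfret(forster_rate(p, x), p) == pytest.approx(x, rel=1e-12)

    def test_zero_kfret_raises(self):
        with pytest.raises(UndefinedDistanceError):
            reff_from_kfret(0.0, Photophysics(tau_d=100.0, r0=10.0))


class TestEfficiencyConversions:
    def test_midpoint(self):
        assert efficiency_to_reff(0.5, 10.0) == pytest.approx(10.0, rel=1e-12)

    def test_high_efficiency(self):
        assert efficiency_to_reff(64.0 / 65.0, 10.0) == pytest.approx(5.0, rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(e=st.floats(1e-6, 1.0 - 1e-6), r0=st.floats(5.0, 20.0))
    def test_roundtrip_property(self, e, r0):
        assert reff_to_efficiency(efficiency_to_reff(e, r0), r0) == pytest.approx(
            e, rel=1e-12
        )

    def test_domain(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(UndefinedDistanceError):
                efficiency_to_reff(bad, 10.0)


class TestStaticLimit:
    def test_near_delta_gives_r_star(self):
        dist = make_distribution(
            "skewed_gaussian_legacy", a=400.0, b=10.0, r_min=8.0, r_max=12.0
        )
        assert static_limit_L(dist, 10.0) == pytest.approx(10.0, rel=1e-3)

    def test_matches_dense_grid_oracle(self):
        dist = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0)
        r0 = 9.0
        s = dense_trapezoid(
            lambda r: dist.norm * dist.kernel(r) * r**6 / (r**6 + r0**6),
            dist.r_min,
            dist.r_max,
        )
        oracle = r0 * (1.0 / (1.0 - s) - 1.0) ** (1.0 / 6.0)
        assert static_limit_L(dist, r0) == pytest.approx(oracle, rel=1e-6)

    def test_rightward_shift_increases_l(self):
        near = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0, r_max=100.0)
        far = make_distribution("ideal_chain_shifted", b=18.0, r_min=6.0, r_max=103.0)
        assert static_limit_L(far, 9.0) > static_limit_L(near, 9.0)

    def test_efficiency_route_identity(self):
        # Reff from the ensemble efficiency equals the closed form exactly
        dist = make_distribution("ideal_chain_shifted", b=24.0, r_min=4.0)
        r0 = 12.0
        e = static_efficiency(dist, r0)
        assert efficiency_to_reff(e, r0) == pytest.approx(
            static_limit_L(dist, r0), rel=1e-10
        )


class TestDynamicLimit:
    def test_near_delta_gives_r_star(self):
        dist = make_distribution(
            "skewed_gaussian_legacy", a=400.0, b=10.0, r_min=8.0, r_max=12.0
        )
        assert dynamic_limit_R(dist) == pytest.approx(10.0, rel=1e-3)

    def test_matches_dense_grid_oracle(self):
        dist = make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0)
        m6 = dense_trapezoid(
            lambda r: dist.norm * dist.kernel(r) / r**6, dist.r_min, dist.r_max,
            n=2_000_001,
        )
        assert dynamic_limit_R(dist) == pytest.approx(m6 ** (-1.0 / 6.0), rel=1e-6)

    @settings(max_examples=20, deadline=None)
    @given(b=st.floats(8.0, 35.0), rl=st.floats(1.5, 5.0), r0=st.floats(6.0, 18.0))
    def test_dynamic_below_static_property(self, b, rl, r0):
        dist = make_distribution("ideal_chain_shifted", b=b, r_min=rl)
        assert dynamic_limit_R(dist) <= static_limit_L(dist, r0)


class TestAugmentedJ:
    def test_unit_case(self):
        assert augmented_j(1.0, 100.0, 10.0) == pytest.approx(1.0, rel=1e-12)
        assert profile_abscissa_x(1.0, 100.0, 10.0) == pytest.approx(1.0, rel=1e-12)

    def test_product_invariance(self):
        assert augmented_j(10.0, 10.0, 10.0) == pytest.approx(
            augmented_j(1.0, 100.0, 10.0), rel=1e-12
        )

    def test_dimensionless_scaling(self):
        # J is invariant when lengths are expressed in nm instead of A
        j_a = augmented_j(2.0, 50.0, 12.0)  # A^2/ns, ns, A
        j_nm = augmented_j(2.0e-2, 50.0, 1.2)  # nm^2/ns, ns, nm
        assert j_a == pytest.approx(j_nm, rel=1e-12)


class TestDiffusionInfluence:
    def test_endpoints_and_midpoint(self):
        assert diffusion_influence(18.0, 18.0, 14.0) == 0.0
        assert diffusion_influence(14.0, 18.0, 14.0) == 1.0
        assert diffusion_influence(16.0, 18.0, 14.0) == pytest.approx(0.5, rel=1e-12)

    def test_clipping_window(self):
        assert diffusion_influence(18.001, 18.0, 14.0) == 0.0
        with pytest.raises(DomainError):
            diffusion_influence(18.1, 18.0, 14.0)

    def test_degenerate_amplitude(self):
        with pytest.raises(DegenerateAmplitudeError):
            diffusion_influence(10.0, 10.0 + 1e-9, 10.0)
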
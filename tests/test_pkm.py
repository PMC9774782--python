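"""Pseudophase-model forward prediction, reciprocal/nonlinear fitting, algebra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pseudophase import (
    ConsistencyViolationError,
    EmulsionComposition,
    InsufficientDesignError,
    KineticSeries,
    ModelMisfitError,
    PartitionSet,
    fit_nonlinear,
    fit_reciprocal,
    kobs_forward,
    partition_consistency,
)
from conftest import make_composition


def exact_series(P=5.0, k_I=1.0, AO_T=0.004, phi_O=0.1, levels=(0.005, 0.01, 0.02, 0.04)):
    obs = tuple(
        (fi, phi_O, kobs_forward(P, make_composition(fi, phi_O), AO_T, k_I))
        for fi in levels
    )
    return KineticSeries(observations=obs, AO_T=AO_T)


class TestForwardModel:
    def test_hand_computed_rate(self, anchor_composition):
        # 0.004 * 1.0 * 5 / (0.005*5 + 0.1) = 0.16; a 40-fold interfacial
        # enrichment over the stoichiometric 0.004 M.
        assert kobs_forward(5.0, anchor_composition, 0.004, 1.0) == pytest.approx(0.16)

    def test_strong_partitioning_limit(self):
        comp = make_composition(0.02)
        k_large = kobs_forward(1e9, comp, 0.004, 1.0)
        assert k_large == pytest.approx(0.004 * 1.0 / 0.02, rel=1e-6)

    def test_half_partitioning_point(self):
        # phi_I * P = phi_O puts half the antioxidant at the interface.
        comp = make_composition(0.02)
        P = 0.1 / 0.02
        assert kobs_forward(P, comp, 0.004, 1.0) == pytest.approx(
            0.004 * 1.0 * P / (2 * 0.1)
        )

    def test_monotone_decreasing_in_phi_I(self):
        ks = [
            kobs_forward(5.0, make_composition(fi), 0.004, 1.0)
            for fi in np.linspace(0.005, 0.04, 10)
        ]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_accepts_partition_set(self, anchor_composition):
        ps = PartitionSet(P_O_I=5.0)
        assert kobs_forward(ps, anchor_composition, 0.004, 1.0) == pytest.approx(0.16)


class TestReciprocalFit:
    def test_exact_four_point_design_recovers_line_and_parameters(self):
        fit = fit_reciprocal(exact_series())
        assert fit.slope == pytest.approx(250.0, rel=1e-9)
        assert fit.intercept == pytest.approx(5.0, rel=1e-9)
        assert fit.P_O_I == pytest.approx(5.0, rel=1e-9)
        assert fit.k_I == pytest.approx(1.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("P", np.geomspace(0.1, 1e3, 5))
    @pytest.mark.parametrize("k_I", [1e-3, 1.0, 1e3])
    def test_round_trip_across_parameter_ranges(self, P, k_I):
        fit = fit_reciprocal(exact_series(P=P, k_I=k_I))
        assert abs(fit.P_O_I - P) / P < 1e-8
        assert abs(fit.k_I - k_I) / k_I < 1e-8

    def test_flat_series_is_a_model_misfit(self):
        obs = tuple((fi, 0.1, 0.2) for fi in (0.005, 0.01, 0.02, 0.04))
        with pytest.raises(ModelMisfitError):
            fit_reciprocal(KineticSeries(observations=obs, AO_T=0.004))

    def test_too_few_levels_rejected_at_construction(self):
        with pytest.raises(InsufficientDesignError):
            KineticSeries(observations=((0.005, 0.1, 0.2), (0.01, 0.1, 0.1)), AO_T=0.004)

    def test_noisy_series_recovery_against_grid_search(self):
        from pseudophase import SyntheticSpec, make_kinetic_series

        series = make_kinetic_series(SyntheticSpec(seed=11))
        fit = fit_reciprocal(series)
        assert abs(fit.P_O_I - 5.0) / 5.0 < 0.25
        assert abs(fit.k_I - 1.0) / 1.0 < 0.10

        # 2-D brute-force oracle minimizing SSE of the untransformed rate law
        P_grid = np.geomspace(1.0, 25.0, 300)
        k_grid = np.geomspace(0.2, 5.0, 300)
        phi_I, phi_O, k = series.phi_I, series.phi_O, series.k_obs
        pred = (
            series.AO_T
            * k_grid[None, :, None]
            * P_grid[:, None, None]
            / (phi_I[None, None, :] * P_grid[:, None, None] + phi_O[None, None, :])
        )
        sse = ((pred - k[None, None, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        nl = fit_nonlinear(series)
        assert abs(nl.P_O_I - P_grid[i]) / P_grid[i] < 0.02
        assert abs(nl.k_I - k_grid[j]) / k_grid[j] < 0.02

    def test_per_observation_policy_matches_constant_on_fixed_oil(self):
        s = exact_series()
        f1 = fit_reciprocal(s, phi_O_policy="constant")
        f2 = fit_reciprocal(s, phi_O_policy="per-observation")
        assert f2.P_O_I == pytest.approx(f1.P_O_I, rel=1e-6)
        assert f2.k_I == pytest.approx(f1.k_I, rel=1e-6)


class TestNonlinearFit:
    def test_matches_reciprocal_on_exact_data(self):
        s = exact_series()
        fr = fit_reciprocal(s)
        fn = fit_nonlinear(s)
        assert fn.P_O_I == pytest.approx(fr.P_O_I, rel=1e-6)
        assert fn.k_I == pytest.approx(fr.k_I, rel=1e-6)

    def test_lower_sse_than_reciprocal_under_additive_noise(self):
        rng = np.random.default_rng(3)
        levels = np.geomspace(0.005, 0.04, 8)
        P, k_I, AO_T = 5.0, 1.0, 0.004
        obs = tuple(
            (fi, 0.1, kobs_forward(P, make_composition(fi), AO_T, k_I) + e)
            for fi, e in zip(levels, rng.normal(0, 0.004, levels.size))
        )
        s = KineticSeries(observations=obs, AO_T=AO_T)

        def sse(fit):
            pred = np.array(
                [kobs_forward(fit.P_O_I, make_composition(fi), AO_T, fit.k_I) for fi in levels]
            )
            return float(np.sum((s.k_obs - pred) ** 2))

        assert sse(fit_nonlinear(s)) <= sse(fit_reciprocal(s)) + 1e-15

    def test_three_point_design_matches_algebraic_solution(self):
        # Any 3 consistent points determine the line exactly: solve the
        # 2x2 system from the first and last points as the oracle.
        s = exact_series(P=12.0, k_I=0.3, levels=(0.006, 0.015, 0.035))
        y = 1.0 / s.k_obs
        x = s.phi_I
        slope = (y[2] - y[0]) / (x[2] - x[0])
        intercept = y[0] - slope * x[0]
        P_alg = 0.1 * slope / intercept
        kI_alg = 1.0 / (slope * s.AO_T)
        fn = fit_nonlinear(s)
        assert fn.P_O_I == pytest.approx(P_alg, rel=1e-8)
        assert fn.k_I == pytest.approx(kI_alg, rel=1e-8)


class TestPartitionAlgebra:
    def test_binary_constant_is_the_ratio(self):
        assert partition_consistency(PartitionSet(P_O_I=5.0, P_W_I=10.0)) == pytest.approx(2.0)

    def test_equal_solubility_gives_unity(self):
        assert partition_consistency(PartitionSet(P_O_I=7.0, P_W_I=7.0)) == pytest.approx(1.0)

    def test_inconsistent_triple_raises(self):
        with pytest.raises(ConsistencyViolationError):
            partition_consistency(PartitionSet(P_O_I=5.0, P_W_I=10.0, P_W_O=3.0))

    def test_consistent_triple_passes(self):
        ps = PartitionSet(P_O_I=5.0, P_W_I=10.0, P_W_O=2.0)
        assert partition_consistency(ps) == pytest.approx(2.0)


@given(
    P=st.floats(min_value=0.1, max_value=1e3),
    k_I=st.floats(min_value=1e-3, max_value=1e3),
)
def test_forward_fit_round_trip_property(P, k_I):
    """Exact forward data from any (P, k_I) is recovered to 1e-8 relative."""
    fit = fit_reciprocal(exact_series(P=P, k_I=k_I))
    assert abs(fit.P_O_I - P) / P < 1e-8
    assert abs(fit.k_I - k_I) / k_I < 1e-8
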
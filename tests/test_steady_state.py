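"""Steady-state integration: convergence, conservation, cross-validation
against an independent integrator, and dose-response construction."""

import numpy as np
import pytest

from opposer.models import RateParameters, conservation_residuals
from opposer.steady_state import (
    CycleParameters,
    SteadyStateOptions,
    default_input_grid,
    dose_response,
    integrate_to_steady,
    single_cycle_dose_response,
)
from opposer.sweep import SamplingSpec, sample_parameters, row_to_params


@pytest.mark.parametrize("model", ["complex_complete", "michaelian", "ferrell"])
def test_zero_input_gives_inactive_steady_state(model, fig5_params):
    """Without input nothing activates A: the 'off' state is already steady."""
    res = integrate_to_steady(model, fig5_params.with_input(0.0))
    assert res.converged
    assert res["A_star"] == 0.0
    if model == "complex_complete":
        assert res["C3"] == 0.0 and res["B_star"] == 0.0


@pytest.mark.parametrize("model", ["complex_complete", "michaelian", "ferrell"])
@pytest.mark.parametrize("I_tot", [1e-3, 1.0, 50.0])
def test_implicit_march_matches_lsoda(model, I_tot, fig5_params):
    """The pseudo-transient engine and scipy's LSODA land on the same
    steady state from the same initial condition."""
    p = fig5_params.with_input(I_tot)
    a = integrate_to_steady(model, p)
    b = integrate_to_steady(model, p, options=SteadyStateOptions(method="lsoda"))
    assert a.converged and b.converged
    scale = np.maximum(np.abs(b.state), 1e-6)
    assert np.max(np.abs(a.state - b.state) / scale) < 1e-4


def test_reintegration_from_steady_state_is_stationary(fig5_params):
    p = fig5_params.with_input(0.7)
    first = integrate_to_steady("complex_complete", p)
    again = integrate_to_steady("complex_complete", p, y0=first.state.copy())
    assert again.converged
    scale = np.maximum(np.abs(first.state), 1e-12)
    assert np.max(np.abs(again.state - first.state) / scale) < 1e-6


def test_random_sets_conserve_and_stay_non_negative(rng):
    """Converged steady states satisfy all four conservation relations and
    componentwise non-negativity across random parameter magnitudes."""
    ensemble = sample_parameters(SamplingSpec(n_sets=30, seed=91))
    for _, row in ensemble.iterrows():
        p = row_to_params(row).with_input(float(10 ** rng.uniform(-3, 4)))
        res = integrate_to_steady("complex_complete", p, raise_on_failure=False)
        if not res.converged:
            continue
        assert np.min(res.state) >= 0.0
        totals = np.array([p.A_tot, p.B_tot, max(p.I_tot, 1e-300), p.E_tot])
        resid = np.abs(conservation_residuals(res.state, p))
        assert np.all(resid <= 1e-6 * totals * 10)


def test_dose_response_grid_validation(fig5_params):
    with pytest.raises(ValueError, match="strictly increasing"):
        dose_response("michaelian", fig5_params, [1.0, 1.0, 2.0])
    with pytest.raises(ValueError, match="unknown model"):
        dose_response("nope", fig5_params, [1.0, 2.0, 3.0])
    single = dose_response("michaelian", fig5_params, [1.0])
    assert len(single) == 1


def test_fig5_profiles_show_prozone_and_tracking(fig5_params):
    """Same regime, different kinetic frameworks: the Michaelian output is
    flat at the setpoint while the complex-complete free forms are monotone
    (A*) and biphasic/prozone (B*)."""
    grid = np.linspace(0.05, 5.0, 30)
    cc = dose_response("complex_complete", fig5_params, grid)
    mm = dose_response("michaelian", fig5_params, grid)
    astar = cc.column("A_star")
    bstar = cc.column("B_star")
    assert np.all(np.diff(astar) > 0)
    peak = int(np.argmax(bstar))
    assert 0 < peak < len(bstar) - 1
    assert bstar[-1] < 0.9 * bstar[peak]
    sigma = fig5_params.sigma
    inner = mm.column("A_star")[(grid > 0.3) & (grid < 2.0)]
    assert np.all(np.abs(inner - sigma) <= 0.01 * sigma)


def test_grid_refinement_preserves_existing_points(fig5_params):
    """Cold-start solving makes every grid point independent: refining the
    grid does not change the states at pre-existing inputs."""
    coarse = np.geomspace(1e-2, 1e1, 7)
    fine = np.unique(np.concatenate([coarse, np.geomspace(1e-2, 1e1, 13)]))
    a = dose_response("complex_complete", fig5_params, coarse).table
    b = dose_response("complex_complete", fig5_params, fine).table
    b_at_coarse = b[b["I_tot"].isin(coarse)].reset_index(drop=True)
    np.testing.assert_allclose(
        a[["A_star", "B_star", "C3"]].to_numpy(),
        b_at_coarse[["A_star", "B_star", "C3"]].to_numpy(),
        rtol=0, atol=1e-12,
    )


class TestSingleCycle:
    cyc = CycleParameters(k_A1=1, k_A2=1, K_A1=0.01, K_A2=0.01, A_tot=100)

    def test_without_enzyme_output_saturates(self):
        table = single_cycle_dose_response(self.cyc, 0.0, np.geomspace(1, 100, 5))
        # no deactivating enzyme: all protein converts for any positive input
        assert np.all(table["AS_star"] > 0.99 * self.cyc.A_tot)

    def test_half_maximum_scales_with_enzyme_abundance(self):
        """In the zero-order regime the output pool reaches half-maximum
        near I_tot = (k_A2/k_A1) x enzyme abundance."""
        grid = np.geomspace(0.1, 300, 90)
        halves = []
        for enzyme in (2.0, 10.0, 50.0):
            t = single_cycle_dose_response(self.cyc, enzyme, grid)
            y = t["AS_star"].to_numpy()
            j = int(np.flatnonzero(y >= 0.5 * y.max())[0])
            halves.append(grid[j])
        assert np.all(np.diff(halves) > 0)
        for half, enzyme in zip(halves, (2.0, 10.0, 50.0)):
            assert half == pytest.approx(enzyme, rel=0.5)

    def test_weaker_binding_requires_more_input(self):
        """Raising K_A1 (weaker input-enzyme binding) shifts the rise of the
        dose-response toward larger inputs."""
        grid = np.geomspace(1, 1000, 60)
        halves = []
        for K_A1 in (0.01, 1.0, 100.0):
            cyc = CycleParameters(k_A1=1, k_A2=1, K_A1=K_A1, K_A2=0.01, A_tot=100)
            t = single_cycle_dose_response(cyc, 20.0, grid)
            y = t["AS_star"].to_numpy()
            j = int(np.flatnonzero(y >= 0.5 * y.max())[0])
            halves.append(grid[j])
        assert halves[0] <= halves[1] <= halves[2]
        assert halves[2] > halves[0]

    def test_negative_enzyme_rejected(self):
        with pytest.raises(ValueError):
            single_cycle_dose_response(self.cyc, -1.0, [1.0, 2.0, 3.0])
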
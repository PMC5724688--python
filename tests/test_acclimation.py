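"""Photo-acclimation optimizer and nitrogen-reallocation strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canophot.acclimation import (
    NitrogenBudget,
    daily_carbon,
    optimize_acclimation,
    pmax_phi_frontier,
    reallocate_nitrogen,
)
from canophot.leafmodel import (
    DEFAULT_KINETICS,
    DEFAULT_POOLS,
    LightResponse,
    calibrate_linear_relations,
    nrh,
)


@pytest.fixture(scope="module")
def relations():
    return calibrate_linear_relations()


@pytest.fixture(scope="module")
def half_sine_day():
    hours = np.arange(0.25, 24.0, 0.5)
    shape = np.clip(np.sin((hours - 6.0) / 12.0 * np.pi), 0.0, None)
    return hours, shape


def test_daily_carbon_linear_regime_closed_form():
    """theta -> 1, P_max >> phi*Q, Rd = 0: uptake = phi * Q * daylight."""
    hours = np.arange(0.25, 24.0, 0.5)
    ppfd = np.where((hours > 7.0) & (hours < 17.0), 100.0, 0.0)  # 10 h
    resp = LightResponse(p_max=1e3, phi=0.05, theta=0.999, r_d=0.0)
    got = daily_carbon(resp, hours, ppfd)
    assert got == pytest.approx(0.05 * 100.0 * 36000.0 * 1e-6, rel=1e-3)


def test_daily_carbon_all_dark():
    hours = np.arange(0.25, 24.0, 0.5)
    resp = LightResponse(p_max=20.0, phi=0.05, theta=0.8, r_d=1.5)
    got = daily_carbon(resp, hours, np.zeros_like(hours))
    assert got == pytest.approx(-1.5 * 86400.0 * 1e-6)


def test_daily_carbon_quadrature_refinement(half_sine_day):
    """Half-sine course: coarse-step quadrature matches a fine-step oracle."""
    resp = LightResponse(p_max=25.0, phi=0.05, theta=0.8, r_d=1.0)
    hours = np.arange(0.125, 24.0, 0.25)
    shape = np.clip(np.sin((hours - 6.0) / 12.0 * np.pi), 0.0, None)
    coarse = daily_carbon(resp, hours, 1500.0 * shape)
    hours_f = np.arange(0.005, 24.0, 0.01)
    shape_f = np.clip(np.sin((hours_f - 6.0) / 12.0 * np.pi), 0.0, None)
    fine = daily_carbon(resp, hours_f, 1500.0 * shape_f)
    assert coarse == pytest.approx(fine, rel=1e-3)


def test_daily_carbon_rejects_bad_course():
    resp = LightResponse(p_max=20.0, phi=0.05)
    with pytest.raises(ValueError):
        daily_carbon(resp, [], [])
    with pytest.raises(ValueError):
        daily_carbon(resp, [0.0, 1.0, 5.0], [0.0, 0.0, 0.0])


def test_frontier_monotone_and_conserves_nitrogen(relations):
    budget = NitrogenBudget(0.85)
    frontier = pmax_phi_frontier(budget, relations, grid_size=40)
    p = np.array([f[0] for f in frontier])
    phi = np.array([f[1] for f in frontier])
    assert np.all(np.diff(p) > 0)
    assert np.all(np.diff(phi) < 0)
    for _, _, pools in frontier:
        assert DEFAULT_KINETICS.total_nitrogen(pools) == pytest.approx(
            0.85, abs=1e-6
        )


def test_frontier_scales_with_budget(relations):
    """Doubling the budget raises P_max at matched phi along the frontier."""
    lo = pmax_phi_frontier(NitrogenBudget(0.5), relations, grid_size=40)
    hi = pmax_phi_frontier(NitrogenBudget(1.0), relations, grid_size=40)
    phi_lo = np.array([f[1] for f in lo])
    p_lo = np.array([f[0] for f in lo])
    phi_hi = np.array([f[1] for f in hi])
    p_hi = np.array([f[0] for f in hi])
    shared = np.linspace(
        max(phi_lo.min(), phi_hi.min()), min(phi_lo.max(), phi_hi.max()), 9
    )[1:-1]
    interp_lo = np.interp(shared, phi_lo[::-1], p_lo[::-1])
    interp_hi = np.interp(shared, phi_hi[::-1], p_hi[::-1])
    assert np.all(interp_hi > interp_lo)


def test_optimizer_shifts_with_growth_light(relations, half_sine_day):
    """Low growth light favours harvesting (phi), high light capacity (P_max)."""
    hours, shape = half_sine_day
    budget = NitrogenBudget(0.85)
    dim = optimize_acclimation(budget, hours, 200.0 * shape, relations)
    bright = optimize_acclimation(budget, hours, 2000.0 * shape, relations)
    assert dim.phi_opt > bright.phi_opt
    assert dim.p_max_opt < bright.p_max_opt


def test_optimizer_boundary_under_constant_saturating_light(relations):
    hours = np.arange(0.25, 24.0, 0.5)
    res = optimize_acclimation(NitrogenBudget(0.85), hours,
                               np.full_like(hours, 8000.0), relations,
                               grid_size=20)
    frontier = pmax_phi_frontier(NitrogenBudget(0.85), relations, grid_size=20)
    assert res.p_max_opt == pytest.approx(frontier[-1][0])


def test_optimizer_matches_bruteforce_refinement(relations, half_sine_day, rng):
    """Coarse-grid optimum lies within one cell of a dense-grid search."""
    hours, shape = half_sine_day
    for _ in range(5):
        budget = NitrogenBudget(rng.uniform(0.4, 1.2))
        peak = rng.uniform(300.0, 2000.0)
        coarse = optimize_acclimation(budget, hours, peak * shape, relations,
                                      grid_size=50)
        dense = optimize_acclimation(budget, hours, peak * shape, relations,
                                     grid_size=2000)
        cell = (0.95 - 0.05) / 49  # coarse-grid spacing in allocation x
        x_c = _alloc_x(coarse, budget)
        x_d = _alloc_x(dense, budget)
        assert abs(x_c - x_d) <= cell + 1e-9
        assert dense.daily_carbon >= coarse.daily_carbon - 1e-9


def _alloc_x(result, budget):
    n_cap = DEFAULT_KINETICS.pool_nitrogen(result.pools)[:3].sum()
    return n_cap / budget.total_n


def test_reallocate_lhc_only_touches_only_antenna():
    target = 0.4 * DEFAULT_POOLS.total_chl
    out = reallocate_nitrogen(DEFAULT_POOLS, target, "lhc_only")
    for name in ("rubisco", "ce", "etcf", "psii", "psi"):
        assert getattr(out, name) == getattr(DEFAULT_POOLS, name)
    assert out.total_chl == pytest.approx(target)
    assert DEFAULT_KINETICS.total_nitrogen(out) < DEFAULT_KINETICS.total_nitrogen(
        DEFAULT_POOLS
    )


def test_reallocate_constant_n_uniform_boost():
    """Freed LHC nitrogen raises every other pool by one common factor."""
    target = 0.4 * DEFAULT_POOLS.total_chl
    out = reallocate_nitrogen(DEFAULT_POOLS, target, "constant_total_n")
    n0 = DEFAULT_KINETICS.total_nitrogen(DEFAULT_POOLS)
    assert DEFAULT_KINETICS.total_nitrogen(out) == pytest.approx(n0, rel=1e-6)
    assert out.total_chl == pytest.approx(target, rel=1e-9)
    factors = [getattr(out, n) / getattr(DEFAULT_POOLS, n)
               for n in ("rubisco", "ce", "etcf")]
    assert np.ptp(factors) < 1e-9
    assert factors[0] > 1.0


@given(
    rub=st.floats(0.5, 3.0),
    etcf=st.floats(0.2, 1.5),
    psii=st.floats(0.4, 1.5),
    n1=st.floats(8.0, 20.0),
    mult=st.floats(0.5, 0.95),
)
@settings(deadline=None, max_examples=150)
def test_reallocation_conserves_nitrogen_property(rub, etcf, psii, n1, mult):
    from canophot.leafmodel import EnzymePools

    pools = EnzymePools(
        rubisco=rub, ce=0.5 * rub, etcf=etcf, psii=psii, psi=1.4 * psii,
        lhcii=n1 * psii, lhci=n1 * 1.4 * psii,
    )
    out = reallocate_nitrogen(pools, mult * pools.total_chl, "constant_total_n")
    assert DEFAULT_KINETICS.total_nitrogen(out) == pytest.approx(
        DEFAULT_KINETICS.total_nitrogen(pools), rel=1e-6
    )
    assert out.total_chl == pytest.approx(mult * pools.total_chl, rel=1e-6)


def test_budget_validation():
    with pytest.raises(ValueError):
        NitrogenBudget(0.0)
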
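"""Reduced leaf model: energy partitioning, assimilation, NRH, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canophot.leafmodel import (
    DEFAULT_KINETICS,
    DEFAULT_POOLS,
    EnzymePools,
    LightResponse,
    calibrate_linear_relations,
    fit_nrh,
    leaf_assimilation,
    modify_chlorophyll,
    nrh,
    phi_incident,
    psii_partition,
    vmax,
)
from canophot.photosystems import optics_from_chl

DEFAULT_OPTICS = optics_from_chl(DEFAULT_POOLS.total_chl)


def test_vmax_is_product():
    assert vmax(3.5, 20.0) == pytest.approx(70.0)
    assert vmax(3.5, 0.0) == 0.0
    rng = np.random.default_rng(0)
    for _ in range(20):
        k, c = rng.uniform(0, 100, 2)
        assert vmax(k, c) == k * c


@given(q=st.floats(0.0, 2500.0))
@settings(deadline=None, max_examples=100)
def test_partition_fractions_sum_to_one(q):
    p = psii_partition(q, DEFAULT_OPTICS, DEFAULT_POOLS)
    total = p.f_photochemistry + p.f_heat + p.f_fluorescence
    assert total == pytest.approx(1.0, abs=1e-9)
    for f in (p.f_photochemistry, p.f_heat, p.f_fluorescence):
        assert 0.0 <= f <= 1.0


def test_photochemistry_fraction_decreases_with_light():
    qs = np.linspace(0.0, 2200.0, 23)
    fps = [psii_partition(float(q), DEFAULT_OPTICS, DEFAULT_POOLS).f_photochemistry
           for q in qs]
    assert fps[0] == pytest.approx(0.83, abs=0.01)  # dark-adapted yield
    assert np.all(np.diff(fps) < 0)


def test_smaller_antenna_higher_photochemistry_fraction():
    """At fixed incident light the reduced-antenna leaf runs more efficiently."""
    low = modify_chlorophyll(DEFAULT_POOLS, 227.7, "antenna_size")
    high = modify_chlorophyll(DEFAULT_POOLS, 741.5, "antenna_size")
    f_low = psii_partition(1500.0, optics_from_chl(227.7), low).f_photochemistry
    f_high = psii_partition(1500.0, optics_from_chl(741.5), high).f_photochemistry
    assert f_low > f_high


def test_photochemistry_flux_antenna_invariant_at_saturation():
    """Absolute photochemical flux is sink-limited, so ~equal across antennas."""
    fluxes = []
    for chl in (227.7, 419.5, 741.5):
        pools = modify_chlorophyll(DEFAULT_POOLS, chl, "antenna_size")
        optics = optics_from_chl(chl)
        p = psii_partition(2000.0, optics, pools)
        fluxes.append(p.f_photochemistry * 2000.0 * optics.absorbance * 0.5)
    assert (max(fluxes) - min(fluxes)) / np.mean(fluxes) < 0.10


def test_assimilation_dark_and_monotone():
    assert leaf_assimilation(0.0, DEFAULT_OPTICS, DEFAULT_POOLS, r_d=1.0) == (
        pytest.approx(-1.0)
    )
    qs = np.linspace(0.0, 2400.0, 25)
    a = leaf_assimilation(qs, DEFAULT_OPTICS, DEFAULT_POOLS)
    assert np.all(np.diff(a) > -1e-9)


def test_assimilation_capacity_scaling():
    """Doubling all pools at saturating light doubles gross assimilation."""
    doubled = DEFAULT_POOLS.scaled(2.0)
    a1 = leaf_assimilation(6000.0, DEFAULT_OPTICS, DEFAULT_POOLS, r_d=1.0)
    a2 = leaf_assimilation(6000.0, DEFAULT_OPTICS, doubled, r_d=1.0)
    assert (a2 + 1.0) == pytest.approx(2.0 * (a1 + 1.0), rel=0.01)


def test_saturated_assimilation_invariant_to_antenna():
    base = leaf_assimilation(4000.0, optics_from_chl(494.7), DEFAULT_POOLS)
    small = modify_chlorophyll(DEFAULT_POOLS, 300.0, "antenna_size")
    a_small = leaf_assimilation(4000.0, optics_from_chl(300.0), small)
    assert a_small == pytest.approx(base, rel=0.03)


def test_modify_chlorophyll_modes():
    target = 0.5 * DEFAULT_POOLS.total_chl
    ant = modify_chlorophyll(DEFAULT_POOLS, target, "antenna_size")
    assert ant.psii == DEFAULT_POOLS.psii and ant.psi == DEFAULT_POOLS.psi
    assert ant.total_chl == pytest.approx(target)
    assert ant.n1 < DEFAULT_POOLS.n1
    ps = modify_chlorophyll(DEFAULT_POOLS, target, "ps_number")
    assert ps.n1 == pytest.approx(DEFAULT_POOLS.n1)
    assert ps.psii == pytest.approx(0.5 * DEFAULT_POOLS.psii)
    assert ps.total_chl == pytest.approx(target)
    with pytest.raises(ValueError):
        modify_chlorophyll(DEFAULT_POOLS, 0.2 * DEFAULT_POOLS.total_chl,
                           "antenna_size")


def test_initial_slope_quadrants():
    """Antenna reduction raises the absorbed-light slope; fewer photosystems
    lower both slopes, and hit the incident-light slope harder than antenna
    reduction does."""
    qlow = np.array([10.0, 20.0, 30.0, 50.0])

    def slopes(pools):
        optics = optics_from_chl(pools.total_chl)
        a = leaf_assimilation(qlow, optics, pools)
        return (np.polyfit(qlow, a, 1)[0],
                np.polyfit(qlow * optics.absorbance, a, 1)[0])

    inc0, abs0 = slopes(DEFAULT_POOLS)
    target = 0.4 * DEFAULT_POOLS.total_chl
    inc_ant, abs_ant = slopes(modify_chlorophyll(DEFAULT_POOLS, target,
                                                 "antenna_size"))
    inc_ps, abs_ps = slopes(modify_chlorophyll(DEFAULT_POOLS, target,
                                               "ps_number"))
    assert abs_ant > abs0  # absorbed-basis slope rises with smaller antenna
    assert abs_ps < abs0  # but falls with fewer photosystems
    assert inc_ps < inc_ant < inc0  # incident slope least affected by antenna


def test_nrh_noiseless_recovery():
    q = np.array([25, 50, 100, 200, 350, 500, 700, 900, 1200, 1600, 2000.0])
    a = nrh(q, 25.0, 0.055, 0.8, 1.0)
    fit = fit_nrh(q, a)
    assert fit.p_max == pytest.approx(25.0, rel=0.005)
    assert fit.phi == pytest.approx(0.055, rel=0.005)
    assert fit.theta == pytest.approx(0.8, rel=0.01)
    assert fit.r_d == pytest.approx(1.0, rel=0.01)


def test_nrh_blackman_limit():
    q = np.linspace(0.0, 2000.0, 200)
    a = nrh(q, 20.0, 0.05, 0.9999, 0.0)
    blackman = np.minimum(0.05 * q, 20.0)
    away_from_kink = np.abs(q - 400.0) > 40.0  # the corner itself stays rounded
    np.testing.assert_allclose(a[away_from_kink], blackman[away_from_kink],
                               atol=0.05)
    np.testing.assert_allclose(a, blackman, atol=0.5)


def test_nrh_noisy_recovery():
    """P_max recovered within 5% on average under 5% Gaussian noise."""
    q = np.linspace(50.0, 2200.0, 12)
    truth = nrh(q, 25.0, 0.055, 0.8, 1.0)
    rng = np.random.default_rng(42)
    estimates = []
    for _ in range(100):
        noisy = truth * (1.0 + 0.05 * rng.standard_normal(len(q)))
        estimates.append(fit_nrh(q, noisy).p_max)
    estimates = np.array(estimates)
    assert np.median(np.abs(estimates / 25.0 - 1.0)) < 0.05


def test_nrh_needs_enough_points():
    with pytest.raises(ValueError):
        fit_nrh([100.0, 500.0], [5.0, 15.0])


def test_light_response_validation():
    with pytest.raises(ValueError):
        LightResponse(p_max=-1.0, phi=0.05)
    with pytest.raises(ValueError):
        LightResponse(p_max=20.0, phi=0.2)


@pytest.fixture(scope="module")
def relations():
    return calibrate_linear_relations()


def test_calibration_linearity(relations):
    assert relations.r2_pmax > 0.98
    assert relations.r2_phi > 0.98
    assert relations.a1 > 0 and relations.a4 > 0


def test_calibration_reconstructs_pmax(relations):
    """a1*Rubisco + b1 reproduces directly simulated P_max on held-out pools."""
    from dataclasses import replace

    for s in (0.75, 1.25):
        pools = replace(
            DEFAULT_POOLS,
            rubisco=DEFAULT_POOLS.rubisco * s,
            ce=DEFAULT_POOLS.ce * s,
            etcf=DEFAULT_POOLS.etcf * s,
        )
        optics = optics_from_chl(pools.total_chl)
        q = np.array([5, 10, 20, 40, 80, 150, 250, 400, 600, 900, 1300, 1800,
                      2400, 3000.0])
        sim = fit_nrh(q, leaf_assimilation(q, optics, pools))
        predicted = relations.a1 * pools.rubisco + relations.b1
        assert predicted == pytest.approx(sim.p_max, rel=0.02)


def test_phi_independent_of_capacity_pools():
    """Designed orthogonality: the low-light slope responds to the
    photosystem side, not to Rubisco."""
    from dataclasses import replace

    qlow = np.array([2.0, 5.0, 10.0])

    def slope(pools):
        optics = optics_from_chl(pools.total_chl)
        a = leaf_assimilation(qlow, optics, pools)
        return np.polyfit(qlow, a, 1)[0]

    s_rub = [
        slope(replace(DEFAULT_POOLS, rubisco=DEFAULT_POOLS.rubisco * s))
        for s in (0.7, 1.0, 1.3)
    ]
    s_psu = [
        slope(
            replace(
                DEFAULT_POOLS,
                psii=DEFAULT_POOLS.psii * s,
                psi=DEFAULT_POOLS.psi * s,
                lhcii=DEFAULT_POOLS.lhcii * s,
                lhci=DEFAULT_POOLS.lhci * s,
            )
        )
        for s in (0.7, 1.0, 1.3)
    ]
    assert np.ptp(s_psu) > 0
    assert np.ptp(s_rub) < 0.01 * np.ptp(s_psu)


def test_phi_incident_concave_in_chlorophyll():
    chls = np.linspace(100.0, 900.0, 30)
    n1 = DEFAULT_POOLS.n1
    r, t = optics_from_chl(chls)
    phis = phi_incident(1.0 - r - t, n1)
    assert np.all(np.diff(phis) > 0)
    assert np.all(np.diff(phis, 2) < 0)


def test_pools_validation():
    with pytest.raises(ValueError):
        EnzymePools(-1, 1, 1, 1, 1, 1, 1)
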
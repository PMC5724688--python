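"""Solar geometry, ray tracing, and canopy light statistics."""

import math

import numpy as np
import pytest

from canophot.canopy3d import assign_chlorophyll, build_canopy
from canophot.lightenv import (
    LightField,
    SolarState,
    diurnal_light,
    fit_extinction,
    layer_means,
    solar_course,
    solar_position,
    trace,
)
from canophot.photosystems import LeafOptics, optics_from_chl
from canophot.synthetic import exponential_lightfield, random_homogeneous_canopy


def _michalsky_style_zenith(latitude, day_of_year, hour):
    """Independent solar-position oracle (astronomical-almanac declination)."""
    # mean longitude / anomaly for a generic (non-leap) year, J2000-based
    n = day_of_year - 1 + hour / 24.0 + 9131.5  # days from J2000 to ~2025
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = math.radians(
        (280.460 + 0.9856474 * n + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g))
        % 360.0
    )
    eps = math.radians(23.439 - 0.0000004 * n)
    dec = math.asin(math.sin(eps) * math.sin(lam))
    h = math.radians(15.0 * (hour - 12.0))
    lat = math.radians(latitude)
    cos_z = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(h)
    return math.degrees(math.acos(cos_z))


def test_equator_equinox_noon_overhead():
    zen, _ = solar_position(0.0, 80, 12.0)
    assert zen < 1.5


def test_night_has_zero_irradiance():
    states = solar_course(31.0, 235, 0.5)
    for s in states:
        if s.zenith >= 90.0:
            assert s.direct_ppfd == 0.0 and s.diffuse_ppfd == 0.0


def test_zenith_against_independent_ephemeris():
    """Noon zenith at 31 N, DOY 235 agrees with an independent formulation.

    Both use local solar time, so the comparison isolates the declination
    model; agreement to 0.5 degree is required.
    """
    zen, _ = solar_position(31.0, 235, 12.0)
    oracle = _michalsky_style_zenith(31.0, 235, 12.0)
    assert abs(zen - oracle) < 0.5


def test_course_symmetric_about_noon_and_daylength():
    states = solar_course(31.0, 235, 0.5)
    day = [s for s in states if s.horizontal_ppfd > 0]
    assert 26 <= len(day) <= 30
    z = {round(s.hour, 2): s.zenith for s in states}
    assert z[9.25] == pytest.approx(z[14.75], abs=1e-6)


def test_single_facet_energy_split(single_facet, overhead_sun):
    res = trace(single_facet, LeafOptics(0.05, 0.05), overhead_sun,
                rays_per_m2=2e5, seed=1)
    # both triangles of the square facet see the full beam
    flux = np.average(res.incident, weights=single_facet.facet_area)
    absorbed = np.average(res.absorbed, weights=single_facet.facet_area)
    assert flux == pytest.approx(1000.0, rel=0.02)
    assert absorbed == pytest.approx(900.0, rel=0.02)


def test_two_layer_transmission(stacked_pair, overhead_sun):
    res = trace(
        stacked_pair,
        LeafOptics(0.1, 0.1),
        overhead_sun,
        rays_per_m2=2e5,
        max_bounces=1,
        seed=2,
    )
    upper = stacked_pair.facet_leaf_rank == 1
    lower = ~upper
    i_up = np.average(res.incident[upper], weights=stacked_pair.facet_area[upper])
    i_lo = np.average(res.incident[lower], weights=stacked_pair.facet_area[lower])
    assert i_up == pytest.approx(1000.0, rel=0.03)
    # layers span the periodic cell, so Lambertian transmission behaves as an
    # infinite slab: the lower layer sees the transmitted fraction 0.1 * I
    assert i_lo == pytest.approx(100.0, rel=0.08)


def test_energy_conservation_random_canopy(spherical_canopy, overhead_sun):
    res = trace(spherical_canopy, LeafOptics(0.05, 0.05), overhead_sun,
                rays_per_m2=1e5, seed=3)
    assert res.closure == pytest.approx(1.0, abs=0.01)


def test_unbiasedness_under_ray_density(spherical_canopy, overhead_sun):
    """Doubling the ray count leaves the canopy-mean flux unchanged."""
    lo = trace(spherical_canopy, LeafOptics(0.05, 0.05), overhead_sun,
               rays_per_m2=4e4, seed=4)
    hi = trace(spherical_canopy, LeafOptics(0.05, 0.05), overhead_sun,
               rays_per_m2=8e4, seed=5)
    w = spherical_canopy.facet_area
    m_lo = np.average(lo.incident, weights=w)
    m_hi = np.average(hi.incident, weights=w)
    assert m_lo == pytest.approx(m_hi, rel=0.03)


def test_trace_reproducible_for_fixed_seed(spherical_canopy, overhead_sun):
    a = trace(spherical_canopy, LeafOptics(0.05, 0.05), overhead_sun,
              rays_per_m2=2e4, seed=11)
    b = trace(spherical_canopy, LeafOptics(0.05, 0.05), overhead_sun,
              rays_per_m2=2e4, seed=11)
    np.testing.assert_array_equal(a.incident, b.incident)


def test_trace_rejects_bad_optics(single_facet, overhead_sun):
    with pytest.raises(ValueError):
        trace(single_facet, (np.array([0.7] * 2), np.array([0.5] * 2)),
              overhead_sun, rays_per_m2=1e3)


def test_extinction_fit_recovers_generator(spherical_canopy):
    field = exponential_lightfield(spherical_canopy, k=0.5, i0=1000.0)
    fit = fit_extinction(field, spherical_canopy, 0)
    assert fit.k == pytest.approx(0.5, abs=0.01)
    assert fit.r_squared > 0.999


def test_extinction_spherical_oracle(spherical_canopy, overhead_sun):
    """Fitted k within 15% of the turbid-medium value G/cos(z) = 0.5."""
    res = trace(spherical_canopy, LeafOptics(0.025, 0.025), overhead_sun,
                rays_per_m2=1e5, seed=6)
    field = LightField(
        times=np.array([12.0]),
        incident=res.incident[:, None],
        absorbed=res.absorbed[:, None],
        above_canopy=np.array([1000.0]),
    )
    fit = fit_extinction(field, spherical_canopy, 0)
    assert fit.k == pytest.approx(0.5, rel=0.15)


def test_extinction_increases_with_absorbance(spherical_canopy, overhead_sun):
    """Scattering leaves let light deeper: lower absorbance, smaller k."""
    ks = []
    for refl, tr in [(0.02, 0.02), (0.12, 0.12), (0.22, 0.22)]:
        res = trace(spherical_canopy, LeafOptics(refl, tr), overhead_sun,
                    rays_per_m2=5e4, seed=7)
        field = LightField(
            times=np.array([12.0]), incident=res.incident[:, None],
            absorbed=res.absorbed[:, None], above_canopy=np.array([1000.0]),
        )
        ks.append(fit_extinction(field, spherical_canopy, 0).k)
    assert ks[0] > ks[1] > ks[2]


def test_layer_means_uniform_field_and_binning(spherical_canopy):
    n = spherical_canopy.n_facets
    field = LightField(
        times=np.array([12.0]),
        incident=np.full((n, 1), 500.0),
        absorbed=np.full((n, 1), 450.0),
        above_canopy=np.array([1000.0]),
    )
    top, bottom = layer_means(field, spherical_canopy, 0.2, time_index=0)
    assert top == pytest.approx(bottom)
    with pytest.raises(ValueError):
        layer_means(field, spherical_canopy, 0.6)


def test_layer_means_binning_definition():
    from canophot.synthetic import stacked_facets_canopy

    mesh = stacked_facets_canopy(n_layers=10, area=0.09, top_height=1.0,
                                 spacing=0.09)
    ppfd = np.repeat(np.arange(10, 0, -1) * 100.0, 2)[:, None]
    field = LightField(
        times=np.array([12.0]), incident=ppfd.astype(float),
        absorbed=0.9 * ppfd, above_canopy=np.array([1000.0]),
    )
    top, bottom = layer_means(field, mesh, 0.2, time_index=0)
    assert top == pytest.approx(950.0)  # mean of the top two layers
    assert bottom == pytest.approx(150.0)


def test_diurnal_field_closed_form_single_facet(single_facet):
    """Horizontal facet: absorbed curve tracks cos(z)*direct + diffuse."""
    optics = LeafOptics(0.05, 0.05)
    field = diurnal_light(single_facet, optics, 31.0, 235, time_step_h=2.0,
                          rays_per_m2=1e5, seed=0)
    day = field.above_canopy > 0
    area = single_facet.facet_area
    measured = np.average(field.incident[:, day], weights=area, axis=0)
    np.testing.assert_allclose(measured, field.above_canopy[day], rtol=0.06)
    # zero-LAI limit: soil gets everything when the canopy is removed
    assert np.count_nonzero(day) >= 5


def test_zero_light_course_all_dark(single_facet):
    field = diurnal_light(single_facet, LeafOptics(0.05, 0.05), 80.0, 355,
                          time_step_h=2.0, rays_per_m2=1e4, seed=0)
    assert np.all(field.above_canopy == 0.0)
    assert np.all(field.incident == 0.0)


def test_soil_receives_everything_under_sparse_canopy(overhead_sun):
    mesh = random_homogeneous_canopy(lai=0.02, n_facets=10, seed=1)
    res = trace(mesh, LeafOptics(0.05, 0.05), overhead_sun, rays_per_m2=5e4,
                seed=1)
    assert res.soil_absorbed / res.injected > 0.95


def test_default_canopy_energy_closure(small_canopy_spec, overhead_sun):
    mesh = assign_chlorophyll(build_canopy(small_canopy_spec, seed=0),
                              "uniform", 494.7)
    res = trace(mesh, optics_from_chl(mesh.facet_chl), overhead_sun,
                rays_per_m2=5e4, seed=0)
    assert res.closure == pytest.approx(1.0, abs=0.01)
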
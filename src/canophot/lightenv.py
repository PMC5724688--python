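"""Solar geometry, sky irradiance, and ray-traced canopy light fields.

Solar position uses Spencer's Fourier series for declination with the local
solar hour angle (inputs are local solar time, so no equation-of-time term
is needed).  Clear-sky PAR follows a one-parameter atmospheric
transmittance model: beam-normal PPFD = S0 * tau^m with air mass
m = 1/cos(zenith), plus a diffuse component 0.3 * (1 - tau^m) * S0 * cos(z)
on the horizontal (diffuse fraction grows with zenith).  The diffuse sky is
a standard-overcast-sky (SOC) radiance distribution, L(theta) prop.
(1 + 2 cos theta) / 3.

The tracer launches direct rays from a plane above the canopy and diffuse
rays from SOC-sampled directions, with periodic lateral tiling of the plot;
see :mod:`canophot._tracer` for the kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _tracer
from .canopy3d import CanopyMesh
from .photosystems import LeafOptics

#: extraterrestrial PAR photon flux on a plane normal to the beam
PPFD_EXTRATERRESTRIAL = 2550.0  # umol m-2 s-1
DEFAULT_TRANSMITTANCE = 0.75
DIFFUSE_COEFF = 0.3


@dataclass(frozen=True)
class SolarState:
    latitude: float
    day_of_year: int
    hour: float  # local solar time
    zenith: float  # degrees
    azimuth: float  # degrees from north, clockwise
    direct_ppfd: float  # beam-normal, umol m-2 s-1
    diffuse_ppfd: float  # horizontal, umol m-2 s-1

    @property
    def horizontal_ppfd(self) -> float:
        """Total PPFD on a horizontal plane above the canopy."""
        mu = math.cos(math.radians(self.zenith))
        return max(mu, 0.0) * self.direct_ppfd + self.diffuse_ppfd

    @property
    def sun_direction(self) -> np.ndarray:
        """Unit vector pointing toward the sun (x east, y north, z up)."""
        z = math.radians(self.zenith)
        a = math.radians(self.azimuth)
        return np.array(
            [math.sin(z) * math.sin(a), math.sin(z) * math.cos(a), math.cos(z)]
        )


def declination(day_of_year: int) -> float:
    """Solar declination in radians (Spencer 1971 Fourier series)."""
    g = 2.0 * math.pi * (day_of_year - 1) / 365.0
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def solar_position(latitude: float, day_of_year: int, hour: float) -> tuple:
    """(zenith, azimuth) in degrees for local solar time ``hour``."""
    lat = math.radians(latitude)
    dec = declination(day_of_year)
    h = math.radians(15.0 * (hour - 12.0))
    cos_z = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(h)
    cos_z = min(1.0, max(-1.0, cos_z))
    zen = math.degrees(math.acos(cos_z))
    az = math.degrees(
        math.atan2(math.sin(h), math.cos(h) * math.sin(lat) - math.tan(dec) * math.cos(lat))
    ) + 180.0
    return zen, az % 360.0


def clear_sky_ppfd(
    zenith_deg: float,
    transmittance: float = DEFAULT_TRANSMITTANCE,
    s0: float = PPFD_EXTRATERRESTRIAL,
) -> tuple:
    """(beam-normal direct, horizontal diffuse) PPFD; zero at/below horizon."""
    mu = math.cos(math.radians(zenith_deg))
    if mu <= 1e-3:
        return 0.0, 0.0
    m = min(1.0 / mu, 40.0)
    tb = transmittance**m
    direct = s0 * tb
    diffuse = DIFFUSE_COEFF * (1.0 - tb) * s0 * mu
    return direct, diffuse


def solar_course(
    latitude: float,
    day_of_year: int,
    time_step_h: float,
    transmittance: float = DEFAULT_TRANSMITTANCE,
) -> list:
    """Diurnal sequence of solar states at step-centred local solar times."""
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must lie in [-90, 90]")
    if not 1 <= day_of_year <= 366:
        raise ValueError("day_of_year must lie in [1, 366]")
    if time_step_h <= 0:
        raise ValueError("time_step_h must be > 0")
    hours = np.arange(time_step_h / 2.0, 24.0, time_step_h)
    out = []
    for hour in hours:
        zen, az = solar_position(latitude, day_of_year, float(hour))
        direct, diffuse = clear_sky_ppfd(zen, transmittance)
        out.append(
            SolarState(latitude, day_of_year, float(hour), zen, az, direct, diffuse)
        )
    return out


@dataclass
class TraceResult:
    """Single-time-step tracing output; fluxes are per unit leaf area."""

    incident: np.ndarray  # (F,) umol m-2 s-1
    absorbed: np.ndarray  # (F,) umol m-2 s-1
    soil_absorbed: float  # umol s-1 over the plot cell
    escaped: float
    lost: float
    injected: float

    @property
    def closure(self) -> float:
        """(leaf + soil + escaped) / injected; 1 up to the bounce cutoff."""
        leaf = self.absorbed_energy
        return (leaf + self.soil_absorbed + self.escaped) / self.injected

    absorbed_energy: float = 0.0  # filled by trace()


def _soc_inverse_cdf(n: int = 512) -> tuple:
    theta = np.linspace(0.0, np.pi / 2.0, n)
    pdf = (1.0 + 2.0 * np.cos(theta)) * np.cos(theta) * np.sin(theta)
    cdf = np.cumsum(pdf)
    cdf -= cdf[0]
    cdf /= cdf[-1]
    return cdf, theta


_SOC_CDF, _SOC_THETA = _soc_inverse_cdf()


def _facet_optics_arrays(mesh: CanopyMesh, optics) -> tuple:
    n = mesh.n_facets
    if isinstance(optics, LeafOptics):
        return (np.full(n, optics.reflectance), np.full(n, optics.transmittance))
    refl, trans = optics
    refl = np.broadcast_to(np.asarray(refl, dtype=float), (n,)).copy()
    trans = np.broadcast_to(np.asarray(trans, dtype=float), (n,)).copy()
    if np.any(refl < 0) or np.any(trans < 0) or np.any(refl + trans >= 1.0):
        raise ValueError("non-physical optics: need r, t >= 0 and r + t < 1")
    return refl, trans


class TracerScene:
    """Prepared geometry (triangle arrays + acceleration grid) for a mesh."""

    def __init__(self, mesh: CanopyMesh):
        self.mesh = mesh
        v, t = mesh.vertices, mesh.triangles
        xmin, xmax, ymin, ymax = mesh.ground_bounds
        self.lx, self.ly = xmax - xmin, ymax - ymin
        shift = np.array([xmin, ymin, 0.0])
        self.v0 = np.ascontiguousarray(v[t[:, 0]] - shift)
        self.v1 = np.ascontiguousarray(v[t[:, 1]] - shift)
        self.v2 = np.ascontiguousarray(v[t[:, 2]] - shift)
        self.normals = np.ascontiguousarray(mesh.facet_normal)
        self.z_top = float(v[:, 2].max()) + 1e-3
        (self.cell_start, self.cell_tri, self.cell_offx, self.cell_offy,
         self.gx, self.gy) = _tracer.build_grid(v - shift, t, (0.0, self.lx, 0.0, self.ly))


def trace(
    mesh: CanopyMesh,
    optics,
    sun: SolarState,
    rays_per_m2: float,
    max_bounces: int = 3,
    seed: int = 0,
    soil_reflectance: float = 0.0,
    energy_cutoff_frac: float = 0.01,
    scene: TracerScene | None = None,
) -> TraceResult:
    """Per-facet incident and absorbed PPFD for one solar state.

    ``optics`` is a single :class:`LeafOptics` or a (reflectance,
    transmittance) pair of per-facet arrays.
    """
    if mesh.n_facets == 0:
        raise ValueError("mesh is empty")
    if rays_per_m2 <= 0:
        raise ValueError("rays_per_m2 must be > 0")
    refl, trans = _facet_optics_arrays(mesh, optics)
    if scene is None:
        scene = TracerScene(mesh)
    area = mesh.ground_area
    mu = math.cos(math.radians(sun.zenith))
    e_dir = max(mu, 0.0) * sun.direct_ppfd * area  # umol s-1 through the cell
    e_dif = sun.diffuse_ppfd * area
    zero = TraceResult(
        incident=np.zeros(mesh.n_facets),
        absorbed=np.zeros(mesh.n_facets),
        soil_absorbed=0.0, escaped=0.0, lost=0.0, injected=0.0,
    )
    if e_dir + e_dif <= 0.0:
        return zero

    rng = np.random.default_rng(np.uint32(seed) + 7919 * sun.day_of_year + int(sun.hour * 100))
    n_total = max(int(rays_per_m2 * area), 16)
    n_dir = int(round(n_total * e_dir / (e_dir + e_dif)))
    n_dif = n_total - n_dir
    origins, dirs, weights = [], [], []
    if n_dir > 0 and e_dir > 0:
        o = np.empty((n_dir, 3))
        o[:, 0] = rng.uniform(0.0, scene.lx, n_dir)
        o[:, 1] = rng.uniform(0.0, scene.ly, n_dir)
        o[:, 2] = scene.z_top
        d = -sun.sun_direction  # from sun toward ground
        origins.append(o)
        dirs.append(np.tile(d, (n_dir, 1)))
        weights.append(np.full(n_dir, e_dir / n_dir))
    if n_dif > 0 and e_dif > 0:
        o = np.empty((n_dif, 3))
        o[:, 0] = rng.uniform(0.0, scene.lx, n_dif)
        o[:, 1] = rng.uniform(0.0, scene.ly, n_dif)
        o[:, 2] = scene.z_top
        u = rng.uniform(0.0, 1.0, n_dif)
        theta = np.interp(u, _SOC_CDF, _SOC_THETA)
        phi = rng.uniform(0.0, 2.0 * np.pi, n_dif)
        d = np.stack(
            [
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                -np.cos(theta),
            ],
            axis=1,
        )
        origins.append(o)
        dirs.append(d)
        weights.append(np.full(n_dif, e_dif / n_dif))
    if not weights:
        return zero
    origins = np.concatenate(origins)
    dirs = np.concatenate(dirs)
    weights = np.concatenate(weights)
    injected = float(weights.sum())
    cutoff = energy_cutoff_frac * injected / len(weights)

    inc_e, abs_e, soil, escaped, lost = _tracer.trace_rays(
        origins, dirs, weights,
        scene.v0, scene.v1, scene.v2, scene.normals, refl, trans,
        scene.cell_start, scene.cell_tri, scene.cell_offx, scene.cell_offy,
        scene.lx, scene.ly, scene.gx, scene.gy, scene.z_top,
        max_bounces, cutoff, soil_reflectance, seed + 1,
    )
    res = TraceResult(
        incident=inc_e / mesh.facet_area,
        absorbed=abs_e / mesh.facet_area,
        soil_absorbed=float(soil),
        escaped=float(escaped),
        lost=float(lost),
        injected=injected,
    )
    res.absorbed_energy = float(abs_e.sum())
    return res


@dataclass
class LightField:
    """Per-facet, per-time-step light over a diurnal course."""

    times: np.ndarray  # (T,) hours
    incident: np.ndarray  # (F, T) umol m-2 s-1
    absorbed: np.ndarray  # (F, T)
    above_canopy: np.ndarray  # (T,) horizontal PPFD
    solar_states: list = field(default_factory=list)
    budgets: list = field(default_factory=list)  # per-step (injected, soil, escaped, lost)

    @property
    def time_step_h(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 24.0

    def daily_incident_mol(self) -> np.ndarray:
        """Per-facet daily incident light integral, mol m-2 d-1."""
        return self.incident.sum(axis=1) * self.time_step_h * 3600.0 * 1e-6

    def daily_absorbed_mol(self) -> np.ndarray:
        return self.absorbed.sum(axis=1) * self.time_step_h * 3600.0 * 1e-6

    def to_frame(self) -> pd.DataFrame:
        """Long-format (facet_id, time, incident_ppfd, absorbed_ppfd)."""
        n_f, n_t = self.incident.shape
        return pd.DataFrame(
            {
                "facet_id": np.repeat(np.arange(n_f), n_t),
                "time_h": np.tile(self.times, n_f),
                "incident_ppfd": self.incident.ravel(),
                "absorbed_ppfd": self.absorbed.ravel(),
            }
        )


def diurnal_light(
    mesh: CanopyMesh,
    optics,
    latitude: float,
    day_of_year: int,
    time_step_h: float = 0.5,
    rays_per_m2: float = 1e5,
    seed: int = 0,
    transmittance: float = DEFAULT_TRANSMITTANCE,
    **trace_kwargs,
) -> LightField:
    """Trace the full diurnal course (night steps are zero)."""
    states = solar_course(latitude, day_of_year, time_step_h, transmittance)
    scene = TracerScene(mesh)
    n_f = mesh.n_facets
    n_t = len(states)
    incident = np.zeros((n_f, n_t))
    absorbed = np.zeros((n_f, n_t))
    above = np.zeros(n_t)
    budgets = []
    for j, st in enumerate(states):
        above[j] = st.horizontal_ppfd
        if above[j] <= 0.0:
            budgets.append((0.0, 0.0, 0.0, 0.0))
            continue
        res = trace(
            mesh, optics, st, rays_per_m2, seed=seed + j, scene=scene, **trace_kwargs
        )
        incident[:, j] = res.incident
        absorbed[:, j] = res.absorbed
        budgets.append((res.injected, res.soil_absorbed, res.escaped, res.lost))
    return LightField(
        times=np.array([s.hour for s in states]),
        incident=incident,
        absorbed=absorbed,
        above_canopy=above,
        solar_states=states,
        budgets=budgets,
    )


@dataclass(frozen=True)
class ExtinctionFit:
    k: float
    r_squared: float
    i0: float


def _cumlai_order(mesh: CanopyMesh):
    order = np.argsort(-mesh.facet_centroid_height, kind="stable")
    area = mesh.facet_area[order]
    cum = (np.cumsum(area) - 0.5 * area) / mesh.ground_area
    return order, cum


def fit_extinction(
    field: LightField,
    mesh: CanopyMesh,
    time_index: int,
    n_bins: int = 10,
    use: str = "incident",
) -> ExtinctionFit:
    """Beer's-law extinction coefficient from the traced light profile.

    Facets are ordered by height and binned by cumulative LAI from the top
    (Beer's law is defined on downward cumulative leaf area); bin-mean PPFD
    is fitted as I(L) = I0 exp(-kL) by least squares on the log scale.
    """
    ppfd = getattr(field, use)[:, time_index]
    if field.above_canopy[time_index] <= 0:
        raise ValueError("extinction fit requires a daylit time step")
    order, cum = _cumlai_order(mesh)
    vals = ppfd[order]
    area = mesh.facet_area[order]
    lai = cum[-1] + 0.5 * area[-1] / mesh.ground_area
    edges = np.linspace(0.0, lai, n_bins + 1)
    idx = np.clip(np.digitize(cum, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if not np.any(sel):
            continue
        m = np.average(vals[sel], weights=area[sel])
        if m <= 0:
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(m)
    if len(means) < 3:
        raise ValueError("fewer than 3 usable LAI bins for extinction fit")
    reg = stats.linregress(centers, np.log(means))
    return ExtinctionFit(k=-float(reg.slope), r_squared=float(reg.rvalue**2),
                         i0=float(np.exp(reg.intercept)))


def layer_means(
    field: LightField,
    mesh: CanopyMesh,
    fraction: float,
    time_index: int | None = None,
) -> tuple:
    """Area-weighted mean incident PPFD in the top and bottom LAI layers.

    ``fraction`` of cumulative LAI (facets ordered by height) defines each
    layer; with ``time_index`` None the daylight-mean field is used.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    if time_index is None:
        day = field.above_canopy > 0
        if not np.any(day):
            raise ValueError("no daylit steps in field")
        ppfd = field.incident[:, day].mean(axis=1)
    else:
        ppfd = field.incident[:, time_index]
    order, cum = _cumlai_order(mesh)
    area = mesh.facet_area[order]
    lai = mesh.lai
    top = cum <= fraction * lai
    bottom = cum >= (1.0 - fraction) * lai
    if not np.any(top) or not np.any(bottom):
        raise ValueError("empty canopy layer")
    vals = ppfd[order]
    return (
        float(np.average(vals[top], weights=area[top])),
        float(np.average(vals[bottom], weights=area[bottom])),
    )
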
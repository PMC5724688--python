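"""Parametric 3D construction of a cereal canopy as a triangle mesh.

A stand is a rectangular grid of plants; each plant carries several whorls
(tillers) of leaf blades.  A blade is a longitudinal strip of quads (two
triangles each) following a parabolic-width outline and a droop set by a
dimensionless curvature parameter: the local inclination decreases linearly
from the base angle along the blade, so curvature 0 gives a straight blade
and larger values let the tip bend below horizontal.

Leaf-rank, along-blade position, area, and chlorophyll are stored per facet
so downstream light, nitrogen, and enzyme bookkeeping can address individual
leaf patches.  The LAI scaling factor acts on blade width (never on leaf
count), preserving rank structure and angles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LeafBladeSpec:
    """One leaf blade; rank 1 is the flag leaf, ranks increase downward."""

    rank: int
    base_height: float  # m
    base_azimuth: float  # degrees, clockwise from +y (north)
    base_inclination: float  # degrees from horizontal
    length: float  # m
    max_width: float  # m
    curvature: float = 0.6  # dimensionless droop
    segments: int = 8

    def __post_init__(self):
        if self.length <= 0 or self.max_width <= 0:
            raise ValueError("blade length and max_width must be > 0")
        if not 0.0 <= self.base_inclination <= 90.0:
            raise ValueError("base_inclination must lie in [0, 90] degrees")
        if self.segments < 2:
            raise ValueError("segments must be >= 2")

    @property
    def blade_area(self) -> float:
        """Analytic one-sided area of the blade surface (m^2)."""
        # width profile w(s) = max_width * (1 - s^2); integral = 2/3
        return self.length * self.max_width * (2.0 / 3.0)


@dataclass(frozen=True)
class CanopySpec:
    plants_x: int
    plants_y: int
    row_spacing: float  # m, along x
    plant_spacing: float  # m, along y
    leaves_per_plant: tuple = field(default_factory=tuple)
    angle_factor: float = 1.0
    height_factor: float = 1.0
    lai_factor: float = 1.0
    position_jitter: float = 0.05  # fraction of spacing
    azimuth_jitter_deg: float = 8.0

    def __post_init__(self):
        if self.plants_x * self.plants_y < 1:
            raise ValueError("need at least one plant")
        if self.row_spacing <= 0 or self.plant_spacing <= 0:
            raise ValueError("spacings must be > 0")
        if min(self.angle_factor, self.height_factor, self.lai_factor) <= 0:
            raise ValueError("architecture factors must be > 0")
        if len(self.leaves_per_plant) == 0:
            raise ValueError("leaves_per_plant must not be empty")
        object.__setattr__(self, "leaves_per_plant", tuple(self.leaves_per_plant))

    @property
    def ground_area(self) -> float:
        return (self.plants_x * self.row_spacing) * (self.plants_y * self.plant_spacing)

    def target_lai(self) -> float:
        """Ground-area-normalised one-sided leaf area implied by the spec."""
        per_plant = sum(b.blade_area for b in self.leaves_per_plant)
        n_plants = self.plants_x * self.plants_y
        return n_plants * per_plant * self.lai_factor / self.ground_area


@dataclass
class CanopyMesh:
    """Triangulated leaf surfaces with per-facet metadata.

    ``ground_bounds`` is (xmin, xmax, ymin, ymax) of the periodic plot cell;
    facet centroids are stored with x/y wrapped into the cell (the tracer
    tiles the plot periodically) and the true z.
    """

    vertices: np.ndarray  # (V, 3) float
    triangles: np.ndarray  # (F, 3) int
    facet_leaf_rank: np.ndarray  # (F,) int
    facet_s: np.ndarray  # (F,) along-blade fraction in [0, 1]
    ground_bounds: tuple  # (xmin, xmax, ymin, ymax)
    facet_chl: np.ndarray | None = None  # (F,) umol m-2

    def __post_init__(self):
        v, t = self.vertices, self.triangles
        e1 = v[t[:, 1]] - v[t[:, 0]]
        e2 = v[t[:, 2]] - v[t[:, 0]]
        cross = np.cross(e1, e2)
        self.facet_area = 0.5 * np.linalg.norm(cross, axis=1)
        if np.any(self.facet_area <= 0):
            raise ValueError("degenerate facet with zero area")
        self.facet_normal = cross / (2.0 * self.facet_area[:, None])
        centroid = v[t].mean(axis=1)
        xmin, xmax, ymin, ymax = self.ground_bounds
        lx, ly = xmax - xmin, ymax - ymin
        centroid[:, 0] = xmin + np.mod(centroid[:, 0] - xmin, lx)
        centroid[:, 1] = ymin + np.mod(centroid[:, 1] - ymin, ly)
        self.facet_centroid = centroid

    @property
    def n_facets(self) -> int:
        return len(self.triangles)

    @property
    def ground_area(self) -> float:
        xmin, xmax, ymin, ymax = self.ground_bounds
        return (xmax - xmin) * (ymax - ymin)

    @property
    def lai(self) -> float:
        return float(self.facet_area.sum() / self.ground_area)

    @property
    def facet_centroid_height(self) -> np.ndarray:
        return self.facet_centroid[:, 2]


def _blade_strip(blade: LeafBladeSpec, base_xy, azimuth_deg, height_scale, width_scale):
    """Vertices/faces of one blade as a curved longitudinal strip."""
    n = blade.segments
    s = np.linspace(0.0, 1.0, n + 1)
    theta0 = np.radians(blade.base_inclination)
    # droop: inclination declines linearly along the blade, floor at -60 deg
    theta = np.maximum(theta0 * (1.0 - 1.6 * blade.curvature * s), np.radians(-60.0))
    az = np.radians(azimuth_deg)
    u_h = np.array([np.sin(az), np.cos(az)])  # horizontal heading
    lat = np.array([np.cos(az), -np.sin(az)])  # lateral (horizontal, unit)

    ds = blade.length / n
    # integrate the centreline with segment-mean inclination
    theta_mid = 0.5 * (theta[:-1] + theta[1:])
    dh = np.cos(theta_mid) * ds
    dz = np.sin(theta_mid) * ds
    horiz = np.concatenate([[0.0], np.cumsum(dh)])
    vert = np.concatenate([[0.0], np.cumsum(dz)])
    cx = base_xy[0] + u_h[0] * horiz
    cy = base_xy[1] + u_h[1] * horiz
    cz = blade.base_height * height_scale + vert

    half_w = 0.5 * blade.max_width * width_scale * (1.0 - s**2)
    half_w[-1] = max(half_w[-1], 1e-4 * blade.max_width)  # avoid degenerate tip
    left = np.stack([cx - lat[0] * half_w, cy - lat[1] * half_w, cz], axis=1)
    right = np.stack([cx + lat[0] * half_w, cy + lat[1] * half_w, cz], axis=1)

    verts = np.empty((2 * (n + 1), 3))
    verts[0::2] = left
    verts[1::2] = right
    faces, seg_s = [], []
    for i in range(n):
        a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
        faces.append((a, b, c))
        faces.append((b, d, c))
        mid = 0.5 * (s[i] + s[i + 1])
        seg_s.extend([mid, mid])
    return verts, np.array(faces, dtype=np.int64), np.array(seg_s)


def build_canopy(spec: CanopySpec, seed: int = 0) -> CanopyMesh:
    """Construct the stand mesh; pure function of (spec, seed)."""
    rng = np.random.default_rng(seed)
    verts_all, faces_all, ranks_all, s_all = [], [], [], []
    offset = 0
    n_leaves = len(spec.leaves_per_plant)
    for ix in range(spec.plants_x):
        for iy in range(spec.plants_y):
            px = (ix + 0.5) * spec.row_spacing
            py = (iy + 0.5) * spec.plant_spacing
            px += rng.uniform(-1, 1) * spec.position_jitter * spec.row_spacing
            py += rng.uniform(-1, 1) * spec.position_jitter * spec.plant_spacing
            for blade in spec.leaves_per_plant:
                incl = float(np.clip(blade.base_inclination * spec.angle_factor, 0.0, 90.0))
                b = replace(blade, base_inclination=incl)
                azim = blade.base_azimuth + rng.normal(0.0, spec.azimuth_jitter_deg)
                v, f, seg_s = _blade_strip(
                    b,
                    (px, py),
                    azim,
                    spec.height_factor,
                    spec.lai_factor,
                )
                verts_all.append(v)
                faces_all.append(f + offset)
                ranks_all.append(np.full(len(f), blade.rank, dtype=np.int64))
                s_all.append(seg_s)
                offset += len(v)
    bounds = (0.0, spec.plants_x * spec.row_spacing, 0.0, spec.plants_y * spec.plant_spacing)
    _ = n_leaves
    return CanopyMesh(
        vertices=np.concatenate(verts_all),
        triangles=np.concatenate(faces_all),
        facet_leaf_rank=np.concatenate(ranks_all),
        facet_s=np.concatenate(s_all),
        ground_bounds=bounds,
    )


def apply_architecture_factors(
    spec: CanopySpec, angle_factor: float, height_factor: float, lai_factor: float
) -> CanopySpec:
    """Fold architecture factors into blade parameters (factors reset to 1).

    Inclinations scale with clamping to [0, 90] degrees; heights scale with
    height_factor; LAI scaling acts on blade width, preserving length,
    angles and leaf count.
    """
    if min(angle_factor, height_factor, lai_factor) <= 0:
        raise ValueError("factors must be > 0")
    blades = tuple(
        replace(
            b,
            base_inclination=float(np.clip(b.base_inclination * angle_factor, 0.0, 90.0)),
            base_height=b.base_height * height_factor,
            max_width=b.max_width * lai_factor,
        )
        for b in spec.leaves_per_plant
    )
    return replace(spec, leaves_per_plant=blades)


# Default vertical chlorophyll profile: relative value at blade base and tip
# per leaf rank; declines with rank and from base to tip, the qualitative
# shape of measured paddy gradients (no cultivar-specific values implied).
DEFAULT_CHL_PROFILE = {
    1: (1.10, 0.90),
    2: (1.05, 0.85),
    3: (0.98, 0.78),
    4: (0.90, 0.70),
    5: (0.82, 0.62),
}


def assign_chlorophyll(
    mesh: CanopyMesh,
    mode: str = "uniform",
    mean_chl: float = 494.7,
    profile: dict | None = None,
) -> CanopyMesh:
    """Set per-facet chlorophyll; profiled mode rescales to the target mean.

    ``profile`` maps leaf rank -> (relative value at blade base, at tip);
    the relative value varies linearly along the blade.  After assignment
    the area-weighted mean is rescaled to exactly ``mean_chl``.
    """
    if mean_chl <= 0:
        raise ValueError("mean_chl must be > 0")
    if mode == "uniform":
        chl = np.full(mesh.n_facets, float(mean_chl))
    elif mode == "profiled":
        table = DEFAULT_CHL_PROFILE if profile is None else profile
        rel = np.empty(mesh.n_facets)
        for rank in np.unique(mesh.facet_leaf_rank):
            if int(rank) not in table:
                raise KeyError(f"chlorophyll profile missing leaf rank {int(rank)}")
            base, tip = table[int(rank)]
            sel = mesh.facet_leaf_rank == rank
            rel[sel] = base + (tip - base) * mesh.facet_s[sel]
        w_mean = np.average(rel, weights=mesh.facet_area)
        chl = rel * (mean_chl / w_mean)
    else:
        raise ValueError("mode must be 'uniform' or 'profiled'")
    out = dataclasses.replace(mesh, facet_chl=chl)
    return out


def facet_table(mesh: CanopyMesh) -> pd.DataFrame:
    """Per-facet metadata as a tidy table (sidecar for OBJ export)."""
    return pd.DataFrame(
        {
            "facet_id": np.arange(mesh.n_facets),
            "leaf_rank": mesh.facet_leaf_rank,
            "blade_s": mesh.facet_s,
            "area_m2": mesh.facet_area,
            "centroid_z_m": mesh.facet_centroid_height,
            "chl_umol_m2": mesh.facet_chl if mesh.facet_chl is not None else np.nan,
        }
    )


def export_obj(mesh: CanopyMesh, obj_path, csv_path=None) -> None:
    """Write Wavefront OBJ triangles plus a per-facet metadata CSV."""
    with open(obj_path, "w") as fh:
        fh.write("# canophot canopy mesh\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
    if csv_path is not None:
        facet_table(mesh).to_csv(csv_path, index=False)


def import_obj(obj_path, csv_path, ground_bounds) -> CanopyMesh:
    """Rebuild a mesh from an OBJ file and its metadata sidecar."""
    verts, faces = [], []
    with open(obj_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(x.split("/")[0]) - 1 for x in parts[1:4]])
    meta = pd.read_csv(csv_path)
    chl = meta["chl_umol_m2"].to_numpy()
    return CanopyMesh(
        vertices=np.asarray(verts, dtype=float),
        triangles=np.asarray(faces, dtype=np.int64),
        facet_leaf_rank=meta["leaf_rank"].to_numpy(dtype=np.int64),
        facet_s=meta["blade_s"].to_numpy(dtype=float),
        ground_bounds=tuple(ground_bounds),
        facet_chl=None if np.all(np.isnan(chl)) else chl,
    )


def default_rice_blades(tillers: int = 7, segments: int = 8) -> tuple:
    """Blade set for one plant of a booting-stage rice-like stand.

    Illustrative rank geometry (the source stand's measured dimensions are
    not published): five ranks per tiller, flag leaf steepest and highest.
    """
    rank_params = [
        # rank, base_height, inclination, length, max_width
        (1, 0.85, 75.0, 0.30, 0.017),
        (2, 0.70, 65.0, 0.38, 0.019),
        (3, 0.55, 55.0, 0.44, 0.020),
        (4, 0.40, 45.0, 0.42, 0.020),
        (5, 0.28, 40.0, 0.36, 0.019),
    ]
    blades = []
    for k in range(tillers):
        az0 = 360.0 * k / tillers
        for rank, h, incl, length, width in rank_params:
            blades.append(
                LeafBladeSpec(
                    rank=rank,
                    base_height=h,
                    base_azimuth=az0 + 137.5 * rank,  # phyllotactic spread
                    base_inclination=incl,
                    length=length,
                    max_width=width,
                    curvature=0.6,
                    segments=segments,
                )
            )
    return tuple(blades)


def default_canopy_spec(
    plants_x: int = 3, plants_y: int = 3, tillers: int = 7, segments: int = 8
) -> CanopySpec:
    """Default stand: 3x3 plants at 0.25 x 0.20 m (20 plants m-2)."""
    return CanopySpec(
        plants_x=plants_x,
        plants_y=plants_y,
        row_spacing=0.25,
        plant_spacing=0.20,
        leaves_per_plant=default_rice_blades(tillers=tillers, segments=segments),
    )
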
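"""Toy canopies for testing: single facets, stacks, and turbid-medium stands.

These generators produce :class:`~canophot.canopy3d.CanopyMesh` objects with
exactly known geometry so tracer and statistics code can be checked against
closed forms (energy splits, Beer's-law decay with a spherical leaf-angle
distribution, binning definitions).
"""

from __future__ import annotations

import numpy as np

from .canopy3d import CanopyMesh
from .lightenv import LightField


def _square_facets(centers, normals, side):
    """Two triangles per square facet centred at ``centers`` facing ``normals``."""
    n = len(centers)
    verts = np.empty((4 * n, 3))
    tris = np.empty((2 * n, 3), dtype=np.int64)
    for i, (c, nv) in enumerate(zip(centers, normals)):
        nv = nv / np.linalg.norm(nv)
        helper = np.array([0.0, 0.0, 1.0]) if abs(nv[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        t1 = np.cross(nv, helper)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(nv, t1)
        h = side / 2.0
        base = 4 * i
        verts[base + 0] = c - h * t1 - h * t2
        verts[base + 1] = c + h * t1 - h * t2
        verts[base + 2] = c + h * t1 + h * t2
        verts[base + 3] = c - h * t1 + h * t2
        tris[2 * i] = (base + 0, base + 1, base + 2)
        tris[2 * i + 1] = (base + 0, base + 2, base + 3)
    return verts, tris


def single_facet_canopy(
    area: float = 0.01,
    height: float = 0.5,
    ground_side: float = 1.0,
    normal=(0.0, 0.0, 1.0),
) -> CanopyMesh:
    """One square leaf facet of the given one-sided area over square ground."""
    side = float(np.sqrt(area))
    center = np.array([[ground_side / 2.0, ground_side / 2.0, height]])
    verts, tris = _square_facets(center, np.array([normal], dtype=float), side)
    return CanopyMesh(
        vertices=verts,
        triangles=tris,
        facet_leaf_rank=np.ones(len(tris), dtype=np.int64),
        facet_s=np.full(len(tris), 0.5),
        ground_bounds=(0.0, ground_side, 0.0, ground_side),
    )


def stacked_facets_canopy(
    n_layers: int = 2,
    area: float = 0.04,
    top_height: float = 1.0,
    spacing: float = 0.2,
    ground_side: float = 1.0,
) -> CanopyMesh:
    """Horizontal square facets stacked vertically (rank = layer index)."""
    side = float(np.sqrt(area))
    centers = np.array(
        [
            [ground_side / 2.0, ground_side / 2.0, top_height - i * spacing]
            for i in range(n_layers)
        ]
    )
    normals = np.tile([0.0, 0.0, 1.0], (n_layers, 1))
    verts, tris = _square_facets(centers, normals, side)
    ranks = np.repeat(np.arange(1, n_layers + 1), 2)
    return CanopyMesh(
        vertices=verts,
        triangles=tris,
        facet_leaf_rank=ranks.astype(np.int64),
        facet_s=np.full(len(tris), 0.5),
        ground_bounds=(0.0, ground_side, 0.0, ground_side),
    )


def random_homogeneous_canopy(
    lai: float = 3.0,
    n_facets: int = 2000,
    height: float = 1.0,
    ground_side: float = 1.0,
    seed: int = 0,
    angle_distribution: str = "spherical",
) -> CanopyMesh:
    """Turbid-medium-like stand: small random facets, uniform in the volume.

    With ``spherical`` leaf-angle distribution the mean projection G = 0.5,
    so black leaves attenuate a vertical beam with extinction 0.5 per unit
    cumulative LAI.
    """
    rng = np.random.default_rng(seed)
    total_area = lai * ground_side * ground_side
    facet_area = total_area / n_facets
    side = float(np.sqrt(facet_area))
    centers = np.empty((n_facets, 3))
    centers[:, 0] = rng.uniform(0.0, ground_side, n_facets)
    centers[:, 1] = rng.uniform(0.0, ground_side, n_facets)
    centers[:, 2] = rng.uniform(0.05, height, n_facets)
    if angle_distribution == "spherical":
        # uniform normals on the upper hemisphere
        u = rng.uniform(0.0, 1.0, n_facets)
        phi = rng.uniform(0.0, 2.0 * np.pi, n_facets)
        cos_t = u
        sin_t = np.sqrt(1.0 - cos_t**2)
        normals = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
    elif angle_distribution == "horizontal":
        normals = np.tile([0.0, 0.0, 1.0], (n_facets, 1))
    else:
        raise ValueError("angle_distribution must be 'spherical' or 'horizontal'")
    verts, tris = _square_facets(centers, normals, side)
    return CanopyMesh(
        vertices=verts,
        triangles=tris,
        facet_leaf_rank=np.ones(len(tris), dtype=np.int64),
        facet_s=np.full(len(tris), 0.5),
        ground_bounds=(0.0, ground_side, 0.0, ground_side),
    )


def exponential_lightfield(mesh: CanopyMesh, k: float = 0.5, i0: float = 1000.0,
                           absorbance: float = 0.9) -> LightField:
    """Synthetic single-step field with exact Beer's-law decay on the mesh.

    PPFD of each facet is i0 * exp(-k * L) at its cumulative-LAI depth L;
    used to check that the extinction fit recovers its generator.
    """
    order = np.argsort(-mesh.facet_centroid_height, kind="stable")
    area = mesh.facet_area[order]
    cum = (np.cumsum(area) - 0.5 * area) / mesh.ground_area
    ppfd = np.empty(mesh.n_facets)
    ppfd[order] = i0 * np.exp(-k * cum)
    return LightField(
        times=np.array([12.0]),
        incident=ppfd[:, None],
        absorbed=absorbance * ppfd[:, None],
        above_canopy=np.array([i0]),
    )
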
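"""Vertical nitrogen distribution through the canopy from its light profile.

Leaf nitrogen per area follows the light-driven gradient

    N_LA = (N_LA_flag - n_b) * (I_l / I_lfl)**b + n_b

where I_l is the daily incident PPFD integral of a facet, I_lfl its value at
the middle of the flag-leaf layer, n_b the basal leaf nitrogen, and the
dimensionless exponent b the ratio of the nitrogen and light extinction
coefficients.  b is derived from green area index, default power form
b = beta * GAI**(-alpha) (the gradient weakens in dense stands); a linear
form beta * GAI - alpha is retained as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .canopy3d import CanopyMesh
from .lightenv import LightField


@dataclass(frozen=True)
class NitrogenParams:
    nla_flag: float = 1.55  # g N m-2 leaf, flag leaf
    n_b: float = 0.40  # g N m-2 leaf, basal
    beta: float = 0.8
    alpha: float = 0.45
    gai: float | None = None  # green area index; None -> use mesh LAI
    form: str = "power"
    use_absorbed: bool = False  # gradient on incident light by default

    def __post_init__(self):
        if not self.nla_flag > self.n_b >= 0:
            raise ValueError("require nla_flag > n_b >= 0")


@dataclass
class NitrogenProfile:
    nla_per_facet: np.ndarray  # (F,) g N m-2 leaf
    total_canopy_n: float  # g N m-2 ground
    b: float
    i_flag: float  # flag-layer daily light integral, mol m-2 d-1


def b_from_gai(gai: float, beta: float, alpha: float, form: str = "power") -> float:
    """Light/nitrogen extinction ratio from green area index (clamped >= 0)."""
    if gai <= 0:
        raise ValueError("gai must be > 0")
    if form == "power":
        b = beta * gai ** (-alpha)
    elif form == "linear":
        b = beta * gai - alpha
    else:
        raise ValueError("form must be 'power' or 'linear'")
    return max(b, 0.0)


def _flag_layer_reference(mesh: CanopyMesh, daily_light: np.ndarray) -> float:
    """Mean daily light of the middle-height tercile of flag-leaf facets."""
    sel = mesh.facet_leaf_rank == mesh.facet_leaf_rank.min()
    z = mesh.facet_centroid_height[sel]
    light = daily_light[sel]
    area = mesh.facet_area[sel]
    lo, hi = np.quantile(z, [1.0 / 3.0, 2.0 / 3.0])
    mid = (z >= lo) & (z <= hi)
    if not np.any(mid):
        mid = np.ones_like(z, dtype=bool)
    return float(np.average(light[mid], weights=area[mid]))


def nitrogen_profile(
    field: LightField, mesh: CanopyMesh, params: NitrogenParams
) -> NitrogenProfile:
    """Per-facet leaf nitrogen from the diurnal light field.

    Values are clipped to [n_b, nla_flag]; only light ratios enter, so the
    profile is invariant to uniform rescaling of the field.
    """
    daily = field.daily_absorbed_mol() if params.use_absorbed else field.daily_incident_mol()
    i_flag = _flag_layer_reference(mesh, daily)
    if i_flag <= 0:
        raise ValueError("flag-leaf layer receives no light; cannot scale profile")
    gai = params.gai if params.gai is not None else mesh.lai
    b = b_from_gai(gai, params.beta, params.alpha, params.form)
    ratio = np.clip(daily / i_flag, 0.0, 1.0)
    nla = (params.nla_flag - params.n_b) * ratio**b + params.n_b
    total = float(np.sum(nla * mesh.facet_area) / mesh.ground_area)
    return NitrogenProfile(nla_per_facet=nla, total_canopy_n=total, b=b, i_flag=i_flag)
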
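"""YAML configuration loading/saving for simulation runs.

The YAML schema mirrors :class:`~canophot.canopysim.SimConfig`; only the
keys present are overridden, everything else keeps the documented default.
Canopy geometry may be given either as explicit blades or via the
``default_stand`` shorthand (plants, tillers, segments).
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .canopy3d import CanopySpec, LeafBladeSpec, default_canopy_spec
from .canopysim import SimConfig
from .nitrogen import NitrogenParams

_SIMPLE_KEYS = (
    "latitude",
    "day_of_year",
    "time_step_h",
    "mean_chl",
    "chl_distribution",
    "chl_multiplier",
    "n_strategy",
    "rays_per_m2",
    "max_bounces",
    "soil_reflectance",
    "photo_n_fraction",
    "theta",
    "r_d",
    "ci",
    "acclimation_grid",
)


def _canopy_from_dict(d: dict) -> CanopySpec:
    if "default_stand" in d:
        ds = d["default_stand"]
        spec = default_canopy_spec(
            plants_x=ds.get("plants_x", 3),
            plants_y=ds.get("plants_y", 3),
            tillers=ds.get("tillers", 7),
            segments=ds.get("segments", 8),
        )
    else:
        blades = tuple(LeafBladeSpec(**b) for b in d["leaves_per_plant"])
        spec = CanopySpec(
            plants_x=d["plants_x"],
            plants_y=d["plants_y"],
            row_spacing=d["row_spacing"],
            plant_spacing=d["plant_spacing"],
            leaves_per_plant=blades,
        )
    factors = {
        k: d[k] for k in ("angle_factor", "height_factor", "lai_factor") if k in d
    }
    return replace(spec, **factors) if factors else spec


def load_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = SimConfig()
    updates = {k: raw[k] for k in _SIMPLE_KEYS if k in raw}
    if "canopy" in raw:
        updates["canopy"] = _canopy_from_dict(raw["canopy"])
    if "nitrogen" in raw:
        updates["nitrogen"] = NitrogenParams(**raw["nitrogen"])
    return replace(cfg, **updates) if updates else cfg


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
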
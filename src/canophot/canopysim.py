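"""End-to-end canopy photosynthesis pipeline and scenario engine.

Stages (run per scenario, sharing the growth-light stage):

1. build the 3D stand and assign leaf chlorophyll (uniform or measured-like
   profile);
2. ray-trace the diurnal light field with chlorophyll-dependent optics;
3. distribute leaf nitrogen down the canopy from the light profile;
4. photo-acclimate each facet (optimal capacity/harvesting nitrogen split
   for its own light course and budget);
5. apply the scenario's chlorophyll multiplier via the antenna-size route
   with the chosen nitrogen strategy, re-trace light with the modified
   optics, evaluate the mechanistic leaf model per facet and time step, and
   integrate to daily canopy CO2 uptake A_c, canopy photosynthetic nitrogen,
   and nitrogen use efficiency NUE = A_c / N.

Canopy "photosynthetic nitrogen" counts the seven protein pools only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .acclimation import _capacity_shares
from .canopy3d import (
    CanopyMesh,
    CanopySpec,
    apply_architecture_factors,
    assign_chlorophyll,
    build_canopy,
    default_canopy_spec,
)
from .leafmodel import (
    DEFAULT_CI,
    DEFAULT_KINETICS,
    DEFAULT_PARTITION,
    DEFAULT_POOLS,
    DEFAULT_RD,
    GAMMA_STAR,
    KM_CO2,
    EnzymePools,
    KineticParams,
    LinearRelations,
    PartitionParams,
    _solve_open_fraction,
    calibrate_linear_relations,
    phi_incident,
)
from .lightenv import LightField, diurnal_light
from .nitrogen import NitrogenParams, nitrogen_profile
from .photosystems import CHL_PER_LHC, CORE_CHL_PSI, CORE_CHL_PSII, optics_from_chl


@dataclass
class SimConfig:
    """Full configuration of one canopy photosynthesis run."""

    canopy: CanopySpec = field(default_factory=default_canopy_spec)
    latitude: float = 31.0  # degrees N
    day_of_year: int = 235
    time_step_h: float = 0.5
    mean_chl: float = 494.7  # umol m-2
    chl_distribution: str = "uniform"  # or "measured_like"
    chl_multiplier: float = 1.0
    n_strategy: str = "lhc_only"  # or "constant_total_n"
    rays_per_m2: float = 1e5
    max_bounces: int = 3
    soil_reflectance: float = 0.0
    nitrogen: NitrogenParams = field(default_factory=NitrogenParams)
    photo_n_fraction: float = 0.55  # photosynthetic share of leaf N
    kinetics: KineticParams = field(default_factory=lambda: DEFAULT_KINETICS)
    base_pools: EnzymePools = field(default_factory=lambda: DEFAULT_POOLS)
    partition: PartitionParams = field(default_factory=lambda: DEFAULT_PARTITION)
    theta: float = 0.8
    r_d: float = DEFAULT_RD
    ci: float = DEFAULT_CI
    acclimation_grid: int = 30

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return enc(self)


@dataclass
class PoolArrays:
    """Per-facet enzyme pools as flat arrays (vectorised leaf model input)."""

    rubisco: np.ndarray
    ce: np.ndarray
    etcf: np.ndarray
    psii: np.ndarray
    psi: np.ndarray
    lhcii: np.ndarray
    lhci: np.ndarray

    _FIELDS = ("rubisco", "ce", "etcf", "psii", "psi", "lhcii", "lhci")

    @property
    def total_chl(self) -> np.ndarray:
        return (
            CORE_CHL_PSII * self.psii
            + CORE_CHL_PSI * self.psi
            + CHL_PER_LHC * (self.lhcii + self.lhci)
        )

    def nitrogen(self, kinetics: KineticParams) -> np.ndarray:
        return (
            (self.rubisco + self.ce + self.etcf) * kinetics.n_frac_protein
            + self.psii * kinetics.g_n_per_umol_psii
            + self.psi * kinetics.g_n_per_umol_psi
            + (self.lhcii + self.lhci) * kinetics.g_n_per_umol_lhc
        )

    def row(self, i: int) -> EnzymePools:
        return EnzymePools(*(float(getattr(self, f)[i]) for f in self._FIELDS))

    def copy(self) -> "PoolArrays":
        return PoolArrays(*(getattr(self, f).copy() for f in self._FIELDS))


def acclimate_profile(
    budgets: np.ndarray,
    hours: np.ndarray,
    incident: np.ndarray,
    relations: LinearRelations,
    kinetics: KineticParams = DEFAULT_KINETICS,
    base_pools: EnzymePools = DEFAULT_POOLS,
    grid_size: int = 30,
    theta: float = 0.8,
    r_d: float = DEFAULT_RD,
    chunk: int = 1024,
) -> tuple:
    """Vectorised per-facet acclimation over the allocation frontier.

    Returns (PoolArrays, p_max_opt, phi_opt) with one entry per facet.
    """
    from .leafmodel import nrh

    budgets = np.asarray(budgets, dtype=float)
    n_f = budgets.shape[0]
    dt = float(hours[1] - hours[0]) if len(hours) > 1 else 24.0
    base_cap_n, base_psu_n = _capacity_shares(base_pools, kinetics)
    base_chl = base_pools.total_chl
    xs = np.linspace(0.05, 0.95, grid_size)
    out = {f: np.empty(n_f) for f in PoolArrays._FIELDS}
    p_max_all = np.empty(n_f)
    phi_all = np.empty(n_f)
    for lo in range(0, n_f, chunk):
        hi = min(lo + chunk, n_f)
        b = budgets[lo:hi, None]  # (f, 1)
        s_cap = xs[None, :] * b / base_cap_n  # (f, X)
        s_psu = (1.0 - xs[None, :]) * b / base_psu_n
        rub = base_pools.rubisco * s_cap
        p_max = np.maximum(relations.a1 * rub + relations.b1, 1e-6)
        # exact concave quantum-yield map (see acclimation module notes)
        chl = base_chl * s_psu
        refl, trans = optics_from_chl(chl.ravel())
        absorb = (1.0 - refl - trans).reshape(chl.shape)
        phi = np.clip(phi_incident(absorb, base_pools.n1), 1e-4, 0.124)
        a = nrh(
            incident[lo:hi, None, :], p_max[..., None], phi[..., None], theta, r_d
        )
        dc = a.sum(axis=-1) * dt  # relative daily carbon, (f, X)
        j = np.argmax(dc, axis=1)
        rows = np.arange(hi - lo)
        for name in ("rubisco", "ce", "etcf"):
            out[name][lo:hi] = getattr(base_pools, name) * s_cap[rows, j]
        for name in ("psii", "psi", "lhcii", "lhci"):
            out[name][lo:hi] = getattr(base_pools, name) * s_psu[rows, j]
        p_max_all[lo:hi] = p_max[rows, j]
        phi_all[lo:hi] = phi[rows, j]
    return PoolArrays(**out), p_max_all, phi_all


def pools_for_canopy(
    budgets: np.ndarray,
    facet_chl: np.ndarray,
    kinetics: KineticParams = DEFAULT_KINETICS,
    base_pools: EnzymePools = DEFAULT_POOLS,
    capacity_floor: float = 0.10,
) -> PoolArrays:
    """Chlorophyll-constrained nitrogen allocation for every facet.

    The photosystem complex (PSII, PSI, LHC at the base antenna size) is
    sized to match the facet's assigned chlorophyll; the remaining nitrogen
    budget goes to the capacity pools in base proportions.  Where the
    photosystem side alone would exceed the budget (deeply shaded leaves),
    chlorophyll is trimmed so at least ``capacity_floor`` of the budget
    stays in the capacity pools — areal chlorophyll of shade leaves drops
    before the carbon machinery vanishes.
    """
    budgets = np.asarray(budgets, dtype=float)
    base_cap_n, base_psu_n = _capacity_shares(base_pools, kinetics)
    s_psu = np.asarray(facet_chl, dtype=float) / base_pools.total_chl
    s_psu = np.minimum(s_psu, (1.0 - capacity_floor) * budgets / base_psu_n)
    cap_n = budgets - s_psu * base_psu_n
    s_cap = cap_n / base_cap_n
    return PoolArrays(
        rubisco=base_pools.rubisco * s_cap,
        ce=base_pools.ce * s_cap,
        etcf=base_pools.etcf * s_cap,
        psii=base_pools.psii * s_psu,
        psi=base_pools.psi * s_psu,
        lhcii=base_pools.lhcii * s_psu,
        lhci=base_pools.lhci * s_psu,
    )


def reallocate_profile(
    pools: PoolArrays,
    target_chl: np.ndarray,
    strategy: str,
    kinetics: KineticParams = DEFAULT_KINETICS,
    max_iter: int = 100,
) -> PoolArrays:
    """Vectorised antenna-route chlorophyll change for all facets."""
    pa = pools.copy()
    target = np.asarray(target_chl, dtype=float)

    ratio0 = pa.psi / pa.psii

    def solve_antenna(pa, strict):
        core = CORE_CHL_PSII + ratio0 * CORE_CHL_PSI
        n1 = (target / pa.psii - core) / (CHL_PER_LHC * (1.0 + ratio0))
        if strict and np.any(n1 < -1e-9):
            worst = float((pa.psii * core - target).max())
            raise ValueError(
                f"target chlorophyll infeasible in antenna mode (short by up to "
                f"{worst:.2f} umol m-2 of the core-only minimum)"
            )
        n1 = np.maximum(n1, 0.0)
        pa.lhcii = n1 * pa.psii
        pa.lhci = n1 * pa.psi
        return pa

    if strategy == "lhc_only":
        return solve_antenna(pa, strict=True)
    if strategy != "constant_total_n":
        raise ValueError("strategy must be 'lhc_only' or 'constant_total_n'")
    pa = solve_antenna(pa, strict=True)  # target must be feasible to start
    n_target = pools.nitrogen(kinetics)
    # photosystems may not outgrow the chlorophyll target (n1 >= 0 boundary):
    # pin them at the core-only ceiling and let capacity pools take the rest
    psii_cap = target / (CORE_CHL_PSII + ratio0 * CORE_CHL_PSI)
    for _ in range(max_iter):
        delta = n_target - pa.nitrogen(kinetics)
        if np.all(np.abs(delta) < 1e-9 * n_target):
            return pa
        free_ps = pa.psii < psii_cap - 1e-12
        n_other = (
            (pa.rubisco + pa.ce + pa.etcf) * kinetics.n_frac_protein
            + np.where(
                free_ps,
                pa.psii * kinetics.g_n_per_umol_psii
                + pa.psi * kinetics.g_n_per_umol_psi,
                0.0,
            )
        )
        factor = 1.0 + delta / n_other
        if np.any(factor <= 0):
            raise ValueError("infeasible target: non-LHC pools would vanish")
        for name in ("rubisco", "ce", "etcf"):
            setattr(pa, name, getattr(pa, name) * factor)
        ps_factor = np.where(free_ps, factor, 1.0)
        pa.psii = np.minimum(pa.psii * ps_factor, psii_cap)
        pa.psi = ratio0 * pa.psii
        pa = solve_antenna(pa, strict=False)
    raise RuntimeError("nitrogen redistribution did not converge")


def assimilation_field(
    incident: np.ndarray,
    absorbance: np.ndarray,
    pools: PoolArrays,
    kinetics: KineticParams = DEFAULT_KINETICS,
    partition: PartitionParams = DEFAULT_PARTITION,
    ci: float = DEFAULT_CI,
    r_d: float = DEFAULT_RD,
) -> np.ndarray:
    """Net assimilation (F, T) from per-facet pools and incident PPFD."""
    vcmax = np.minimum(kinetics.kcat_rubisco * pools.rubisco, kinetics.kcat_ce * pools.ce)
    j_max = kinetics.kcat_etcf * pools.etcf
    j_rub = vcmax * (4.0 * ci + 8.0 * GAMMA_STAR) / (ci - GAMMA_STAR)
    sink = np.minimum(j_max, j_rub)
    absorbed = incident * absorbance[:, None]
    i_psii = absorbed * partition.psii_light_share / pools.psii[:, None]
    n1 = np.where(pools.psii > 0, pools.lhcii / np.maximum(pools.psii, 1e-30), 0.0)
    sigma = (CORE_CHL_PSII + CHL_PER_LHC * n1) / partition.antenna_chl_ref
    k_r = np.minimum(sink / pools.psii, partition.k_r_max)
    q = _solve_open_fraction(i_psii, sigma[:, None], k_r[:, None], partition)
    k_npq = partition.k_npq_max * (1.0 - q)
    denom = (
        q * partition.k_p
        + sigma[:, None] * (partition.k_f + partition.k_d)
        + k_npq
    )
    f_p = q * partition.k_p / denom
    j = absorbed * partition.psii_light_share * f_p
    w_j = j * (ci - GAMMA_STAR) / (4.0 * ci + 8.0 * GAMMA_STAR)
    w_c = vcmax[:, None] * (ci - GAMMA_STAR) / (ci + KM_CO2)
    return np.minimum(w_c, w_j) - r_d


@dataclass
class CanopyResult:
    a_c_daily: float  # mol CO2 m-2 ground d-1
    canopy_photo_n: float  # g N m-2 ground
    nue: float  # mol CO2 (g N)-1 d-1
    per_facet: pd.DataFrame
    chl_multiplier: float = 1.0
    n_strategy: str = "default"


class CanopySimulation:
    """Pipeline with a shared growth-light stage and per-scenario runs."""

    def __init__(self, config: SimConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self._growth = None

    # -- stage 1-4: default stand, growth light, nitrogen, acclimation -----

    def growth_stage(self):
        if self._growth is not None:
            return self._growth
        cfg = self.config
        mesh = build_canopy(cfg.canopy, seed=self.seed)
        mode = "uniform" if cfg.chl_distribution == "uniform" else "profiled"
        mesh = assign_chlorophyll(mesh, mode=mode, mean_chl=cfg.mean_chl)
        refl, trans = optics_from_chl(mesh.facet_chl)
        field = diurnal_light(
            mesh,
            (refl, trans),
            cfg.latitude,
            cfg.day_of_year,
            cfg.time_step_h,
            cfg.rays_per_m2,
            seed=self.seed,
            max_bounces=cfg.max_bounces,
            soil_reflectance=cfg.soil_reflectance,
        )
        if np.any(field.above_canopy > 0):
            nprof = nitrogen_profile(field, mesh, cfg.nitrogen)
        else:
            # no daylight (polar night): no gradient information, uniform N
            from .nitrogen import NitrogenProfile

            nla = np.full(mesh.n_facets, cfg.nitrogen.nla_flag)
            nprof = NitrogenProfile(
                nla_per_facet=nla,
                total_canopy_n=float(np.sum(nla * mesh.facet_area) / mesh.ground_area),
                b=0.0,
                i_flag=0.0,
            )
        budgets = cfg.photo_n_fraction * nprof.nla_per_facet
        relations = calibrate_linear_relations(
            cfg.kinetics, cfg.base_pools, r_d=cfg.r_d,
            partition_params=cfg.partition,
        )
        # acclimation constrained to the assigned (measured-type) chlorophyll:
        # the photosystem side matches facet chl, capacity pools take the rest
        pools0 = pools_for_canopy(
            budgets, mesh.facet_chl, cfg.kinetics, cfg.base_pools
        )
        p_max0 = np.maximum(relations.a1 * pools0.rubisco + relations.b1, 1e-6)
        refl0, trans0 = optics_from_chl(pools0.total_chl)
        n1_0 = np.where(pools0.psii > 0, pools0.lhcii / np.maximum(pools0.psii, 1e-30), 0.0)
        phi0 = phi_incident(1.0 - refl0 - trans0, n1_0, cfg.ci, cfg.partition)
        self._growth = {
            "mesh": mesh,
            "field": field,
            "nprofile": nprof,
            "budgets": budgets,
            "relations": relations,
            "pools": pools0,
            "p_max": p_max0,
            "phi": phi0,
        }
        return self._growth

    # -- stage 5: scenario ---------------------------------------------------

    def scenario(
        self, chl_multiplier: float = 1.0, n_strategy: str = "default"
    ) -> CanopyResult:
        if chl_multiplier <= 0:
            raise ValueError("chl_multiplier must be > 0")
        cfg = self.config
        g = self.growth_stage()
        mesh: CanopyMesh = g["mesh"]
        pools0: PoolArrays = g["pools"]
        if chl_multiplier == 1.0 or n_strategy == "default":
            pools = pools0.copy()
        else:
            pools = reallocate_profile(
                pools0, chl_multiplier * pools0.total_chl, n_strategy, cfg.kinetics
            )
        chl = pools.total_chl
        refl, trans = optics_from_chl(chl)
        field = diurnal_light(
            mesh,
            (refl, trans),
            cfg.latitude,
            cfg.day_of_year,
            cfg.time_step_h,
            cfg.rays_per_m2,
            seed=self.seed,
            max_bounces=cfg.max_bounces,
            soil_reflectance=cfg.soil_reflectance,
        )
        absorbance = 1.0 - refl - trans
        a = assimilation_field(
            field.incident,
            absorbance,
            pools,
            cfg.kinetics,
            cfg.partition,
            cfg.ci,
            cfg.r_d,
        )
        dt = field.time_step_h
        daily_a = a.sum(axis=1) * dt * 3600.0 * 1e-6  # mol m-2 leaf d-1
        area = mesh.facet_area
        a_c = float(np.sum(daily_a * area) / mesh.ground_area)
        n_per_facet = pools.nitrogen(cfg.kinetics)
        photo_n = float(np.sum(n_per_facet * area) / mesh.ground_area)
        nue = a_c / photo_n
        per_facet = pd.DataFrame(
            {
                "facet_id": np.arange(mesh.n_facets),
                "leaf_rank": mesh.facet_leaf_rank,
                "area_m2": area,
                "centroid_z_m": mesh.facet_centroid_height,
                "chl_umol_m2": chl,
                "nla_g_m2": g["nprofile"].nla_per_facet,
                "photo_n_g_m2": n_per_facet,
                "daily_incident_mol": field.daily_incident_mol(),
                "daily_absorbed_mol": field.daily_absorbed_mol(),
                "daily_a_mol": daily_a,
                "rubisco_g_m2": pools.rubisco,
                "ce_g_m2": pools.ce,
                "etcf_g_m2": pools.etcf,
                "psii_umol_m2": pools.psii,
                "psi_umol_m2": pools.psi,
                "lhcii_umol_m2": pools.lhcii,
                "lhci_umol_m2": pools.lhci,
            }
        )
        return CanopyResult(
            a_c_daily=a_c,
            canopy_photo_n=photo_n,
            nue=nue,
            per_facet=per_facet,
            chl_multiplier=chl_multiplier,
            n_strategy=n_strategy,
        )

    def scenario_field(self, chl_multiplier=1.0, n_strategy="default") -> LightField:
        """Diurnal light field with the scenario's optics (for diagnostics)."""
        cfg = self.config
        g = self.growth_stage()
        pools = (
            g["pools"].copy()
            if chl_multiplier == 1.0 or n_strategy == "default"
            else reallocate_profile(
                g["pools"], chl_multiplier * g["pools"].total_chl, n_strategy,
                cfg.kinetics,
            )
        )
        refl, trans = optics_from_chl(pools.total_chl)
        return diurnal_light(
            g["mesh"], (refl, trans), cfg.latitude, cfg.day_of_year,
            cfg.time_step_h, cfg.rays_per_m2, seed=self.seed,
            max_bounces=cfg.max_bounces, soil_reflectance=cfg.soil_reflectance,
        )


def run_pipeline(config: SimConfig, seed: int = 0) -> CanopyResult:
    """Single-scenario convenience wrapper around :class:`CanopySimulation`."""
    sim = CanopySimulation(config, seed=seed)
    strategy = config.n_strategy if config.chl_multiplier != 1.0 else "default"
    return sim.scenario(config.chl_multiplier, strategy)


DEFAULT_MULTIPLIERS = (0.4, 0.6, 0.8, 1.0, 1.2)


def run_chl_sweep(
    config: SimConfig,
    multipliers=DEFAULT_MULTIPLIERS,
    strategies=("lhc_only", "constant_total_n"),
    seed: int = 0,
) -> pd.DataFrame:
    """Chlorophyll-multiplier x nitrogen-strategy sweep (one distribution).

    Reports absolute and relative-to-default A_c and NUE per cell.
    """
    if np.any(np.asarray(multipliers) <= 0):
        raise ValueError("multipliers must be > 0")
    sim = CanopySimulation(config, seed=seed)
    default = sim.scenario(1.0, "default")
    rows = []
    for strategy in strategies:
        for m in multipliers:
            res = default if m == 1.0 else sim.scenario(m, strategy)
            rows.append(
                {
                    "chl_multiplier": m,
                    "strategy": strategy,
                    "distribution": config.chl_distribution,
                    "a_c_mol_m2_d": res.a_c_daily,
                    "photo_n_g_m2": res.canopy_photo_n,
                    "nue_mol_gN_d": res.nue,
                    "rel_a_c": res.a_c_daily / default.a_c_daily - 1.0,
                    "rel_nue": res.nue / default.nue - 1.0,
                }
            )
    return pd.DataFrame(rows)


def run_architecture_sweep(
    config: SimConfig,
    angle_factors=(0.5, 1.0, 1.5),
    height_factors=(0.5, 1.0, 1.5),
    lai_factors=(0.5, 1.0, 1.5),
    latitudes=(45.0, 40.0, 31.0, 18.0),
    chl_multiplier: float = 0.4,
    strategy: str = "constant_total_n",
    seed: int = 0,
) -> pd.DataFrame:
    """Cross architecture factors with latitudes; flag cells where the
    reduced-chlorophyll scenario loses canopy photosynthesis."""
    rows = []
    for lat in latitudes:
        for af in angle_factors:
            for hf in height_factors:
                for lf in lai_factors:
                    spec = apply_architecture_factors(config.canopy, af, hf, lf)
                    cfg = replace(config, canopy=spec, latitude=lat)
                    sim = CanopySimulation(cfg, seed=seed)
                    base = sim.scenario(1.0, "default")
                    mod = sim.scenario(chl_multiplier, strategy)
                    rows.append(
                        {
                            "latitude": lat,
                            "angle_factor": af,
                            "height_factor": hf,
                            "lai_factor": lf,
                            "lai": sim.growth_stage()["mesh"].lai,
                            "a_c_default": base.a_c_daily,
                            "a_c_modified": mod.a_c_daily,
                            "rel_benefit": mod.a_c_daily / base.a_c_daily - 1.0,
                            "benefit_positive": mod.a_c_daily >= base.a_c_daily,
                        }
                    )
    return pd.DataFrame(rows)


def report(results: dict, outdir, config: SimConfig | None = None, seed: int = 0):
    """Write result tables plus a reproducibility manifest.

    ``results`` maps a name to a DataFrame or :class:`CanopyResult`.
    """
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if not results:
        raise ValueError("no results to report")
    for name, obj in results.items():
        path = out / f"{name}.csv"
        frame = obj.per_facet if isinstance(obj, CanopyResult) else obj
        frame.to_csv(path, index=False)
        written.append(path.name)
    manifest = {
        "seed": seed,
        "files": written,
        "canophot_version": __version__,
        "numpy_version": np.__version__,
        "python": platform.python_version(),
    }
    if config is not None:
        cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
        manifest["config"] = config.to_dict()
        manifest["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out / "manifest.json"
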
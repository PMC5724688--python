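"""Photo-acclimation: optimal nitrogen split between capacity and harvesting.

For a leaf with a fixed photosynthetic-nitrogen budget and a known diurnal
growth-light course, nitrogen is swept along a one-dimensional frontier
between the capacity pools (Rubisco + CE + ETCF, co-scaled so the three
linear P_max relations stay jointly consistent) and the photosystem complex
(PSII + PSI + LHCII + LHCI at fixed antenna size).  Each split implies a
(P_max, phi) pair: P_max through the calibrated linear relations, phi
through the exact concave absorbance/antenna map (a linear phi relation
extrapolated below its calibration range under-penalises shedding
photosystems and drives the optimum to a degenerate chlorophyll-free
boundary; the concave map restores interior optima).  The pair maximising
daily carbon uptake is selected, ties broken toward the lower P_max
(minimal capacity investment).

Also implements the two antenna-reduction nitrogen strategies: removing LHC
nitrogen outright (``lhc_only``) or conserving total photosynthetic nitrogen
by redistributing the freed nitrogen over all other pools in proportion to
their existing nitrogen shares (``constant_total_n``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .leafmodel import (
    DEFAULT_KINETICS,
    DEFAULT_POOLS,
    EnzymePools,
    KineticParams,
    LightResponse,
    LinearRelations,
    nrh,
)
from .photosystems import antenna_size_for_chl

PHI_MAX = 0.124  # hard physical ceiling used to clip frontier phi values


@dataclass(frozen=True)
class NitrogenBudget:
    """Nitrogen available to the photosynthetic apparatus, g N m-2 leaf."""

    total_n: float

    def __post_init__(self):
        if self.total_n <= 0:
            raise ValueError("total_n must be > 0")


@dataclass
class AcclimationResult:
    p_max_opt: float
    phi_opt: float
    pools: EnzymePools
    daily_carbon: float  # mol CO2 m-2 d-1


def daily_carbon(resp: LightResponse, hours, ppfd) -> float:
    """Daily carbon uptake (mol CO2 m-2 d-1) over a uniform diurnal course.

    Uniform-step quadrature of the NRH response; the course must cover a
    full day (night steps contribute -Rd).
    """
    hours = np.asarray(hours, dtype=float)
    ppfd = np.asarray(ppfd, dtype=float)
    if hours.size == 0:
        raise ValueError("empty diurnal course")
    if hours.size > 1:
        steps = np.diff(hours)
        if not np.allclose(steps, steps[0]):
            raise ValueError("diurnal course must have a uniform time step")
        dt = float(steps[0])
    else:
        dt = 24.0
    a = nrh(ppfd, resp.p_max, resp.phi, resp.theta, resp.r_d)
    return float(a.sum() * dt * 3600.0 * 1e-6)


def _capacity_shares(base_pools: EnzymePools, kinetics: KineticParams):
    n = kinetics.pool_nitrogen(base_pools)
    cap_n = n[0] + n[1] + n[2]
    psu_n = n[3] + n[4] + n[5] + n[6]
    return cap_n, psu_n


def pmax_phi_frontier(
    budget: NitrogenBudget,
    relations: LinearRelations,
    kinetics: KineticParams = DEFAULT_KINETICS,
    base_pools: EnzymePools = DEFAULT_POOLS,
    grid_size: int = 30,
    x_range=(0.05, 0.95),
):
    """(P_max, phi, pools) along the capacity/harvesting allocation sweep.

    x is the fraction of the budget in the capacity pools; within each side
    the base-pool proportions (and antenna size) are preserved, so every
    frontier point carries exactly the budgeted nitrogen.
    """
    from .leafmodel import phi_incident
    from .photosystems import optics_from_chl

    base_cap_n, base_psu_n = _capacity_shares(base_pools, kinetics)
    xs = np.linspace(x_range[0], x_range[1], grid_size)
    out = []
    for x in xs:
        s_cap = x * budget.total_n / base_cap_n
        s_psu = (1.0 - x) * budget.total_n / base_psu_n
        pools = EnzymePools(
            rubisco=base_pools.rubisco * s_cap,
            ce=base_pools.ce * s_cap,
            etcf=base_pools.etcf * s_cap,
            psii=base_pools.psii * s_psu,
            psi=base_pools.psi * s_psu,
            lhcii=base_pools.lhcii * s_psu,
            lhci=base_pools.lhci * s_psu,
        )
        p_max = relations.a1 * pools.rubisco + relations.b1
        if p_max <= 0:
            continue  # allocation below the P_max relation's feasible range
        phi = float(
            np.clip(
                phi_incident(optics_from_chl(pools.total_chl).absorbance, pools.n1),
                1e-4,
                PHI_MAX,
            )
        )
        out.append((p_max, phi, pools))
    if not out:
        raise ValueError("nitrogen budget infeasible: no frontier point with P_max > 0")
    return out


def optimize_acclimation(
    budget: NitrogenBudget,
    hours,
    ppfd,
    relations: LinearRelations,
    kinetics: KineticParams = DEFAULT_KINETICS,
    base_pools: EnzymePools = DEFAULT_POOLS,
    grid_size: int = 30,
    theta: float = 0.8,
    r_d: float = 1.0,
) -> AcclimationResult:
    """Frontier point maximising daily carbon for the given light course."""
    if grid_size < 10:
        raise ValueError("grid_size must be >= 10")
    frontier = pmax_phi_frontier(
        budget, relations, kinetics, base_pools, grid_size=grid_size
    )
    best = None
    for p_max, phi, pools in frontier:
        resp = LightResponse(p_max=p_max, phi=phi, theta=theta, r_d=r_d)
        dc = daily_carbon(resp, hours, ppfd)
        # ties (within 1e-12) break toward lower capacity investment
        if best is None or dc > best[0] + 1e-12 or (
            abs(dc - best[0]) <= 1e-12 and p_max < best[1]
        ):
            best = (dc, p_max, phi, pools)
    dc, p_max, phi, pools = best
    return AcclimationResult(p_max_opt=p_max, phi_opt=phi, pools=pools, daily_carbon=dc)


def reallocate_nitrogen(
    pools: EnzymePools,
    target_chl: float,
    strategy: str = "lhc_only",
    kinetics: KineticParams = DEFAULT_KINETICS,
    max_iter: int = 100,
) -> EnzymePools:
    """Antenna-route chlorophyll change with one of two nitrogen strategies.

    ``lhc_only``: LHCII/LHCI adjust to the target, all other pools are
    untouched (total nitrogen changes by the LHC delta).
    ``constant_total_n``: the freed LHC nitrogen is redistributed over the
    other five pools in proportion to their nitrogen shares; because PSII
    and PSI carry chlorophyll, the antenna size is re-solved after each
    redistribution until both the chlorophyll target and nitrogen
    conservation hold (relative error < 1e-9).
    """
    if strategy == "lhc_only":
        from .leafmodel import modify_chlorophyll

        return modify_chlorophyll(pools, target_chl, mode="antenna_size")
    if strategy != "constant_total_n":
        raise ValueError("strategy must be 'lhc_only' or 'constant_total_n'")

    n_target = kinetics.total_nitrogen(pools)
    ratio0 = pools.psi / pools.psii
    # n1 >= 0 boundary: photosystems may not outgrow the chlorophyll target
    from .photosystems import CHL_PER_LHC, CORE_CHL_PSI, CORE_CHL_PSII

    psii_cap = target_chl / (CORE_CHL_PSII + ratio0 * CORE_CHL_PSI)
    n1 = antenna_size_for_chl(target_chl, pools.psii, ratio=ratio0)
    current = replace(pools, lhcii=n1 * pools.psii, lhci=n1 * pools.psi)
    for _ in range(max_iter):
        delta = n_target - kinetics.total_nitrogen(current)
        if abs(delta) < 1e-9 * n_target:
            return current
        n_groups = kinetics.pool_nitrogen(current)
        free_ps = current.psii < psii_cap - 1e-12
        n_other = n_groups[:3].sum() + (n_groups[3:5].sum() if free_ps else 0.0)
        factor = 1.0 + delta / n_other
        if factor <= 0:
            raise ValueError("infeasible target: non-LHC pools would vanish")
        ps_factor = factor if free_ps else 1.0
        psii = min(current.psii * ps_factor, psii_cap)
        psi = ratio0 * psii
        n1 = max(
            (target_chl / psii - (CORE_CHL_PSII + ratio0 * CORE_CHL_PSI))
            / (CHL_PER_LHC * (1.0 + ratio0)),
            0.0,
        )
        current = replace(
            current,
            rubisco=current.rubisco * factor,
            ce=current.ce * factor,
            etcf=current.etcf * factor,
            psii=psii,
            psi=psi,
            lhcii=n1 * psii,
            lhci=n1 * psi,
        )
    raise RuntimeError("nitrogen redistribution did not converge")
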
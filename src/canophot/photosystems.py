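"""Chlorophyll bookkeeping between photosystem composition and leaf optics.

The chlorophyll complement of a leaf is accounted per photosystem II unit:
PSII and PSI carry fixed core antennas (37 and 95 chlorophylls) plus ``n1``
peripheral light-harvesting complex (LHC) units of 14 chlorophylls each, on
both photosystems.  With a PSI/PSII stoichiometry ``rho`` the areal
chlorophyll concentration is

    Chl = [PSII] * ((37 + 14 n1) + rho * (95 + 14 n1))

which for the default rho = 1.4 collapses to [PSII] * (170 + 33.6 n1).
"Antenna size" manipulations change n1 at fixed photosystem number; the
inverse map is exact.

Leaf-level optics: broadband PAR reflectance/transmittance are
spectrum-weighted means of per-wavelength values, and a saturating
absorbance-vs-chlorophyll curve stands in for the instrument-fitted optics
(calibrated so a healthy rice leaf at 494.7 umol Chl m-2 absorbs ~0.90 of
PAR).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

CORE_CHL_PSII = 37
CORE_CHL_PSI = 95
CHL_PER_LHC = 14
DEFAULT_PSI_PSII_RATIO = 1.4

#: calibration anchor: mean flag-leaf chlorophyll of the default stand
DEFAULT_MEAN_CHL = 494.7  # umol m-2


@dataclass(frozen=True)
class AntennaConfig:
    """Photosystem/antenna composition per unit leaf area."""

    psii_conc: float  # umol PSII m-2
    n1: float  # LHC units per photosystem
    psi_psii_ratio: float = DEFAULT_PSI_PSII_RATIO
    core_chl_psii: int = CORE_CHL_PSII
    core_chl_psi: int = CORE_CHL_PSI
    chl_per_lhc: int = CHL_PER_LHC

    def __post_init__(self):
        if self.psii_conc < 0:
            raise ValueError("psii_conc must be >= 0")
        if self.n1 < 0:
            raise ValueError("n1 must be >= 0")


@dataclass(frozen=True)
class LeafOptics:
    """Broadband PAR reflectance/transmittance of a leaf blade."""

    reflectance: float
    transmittance: float

    def __post_init__(self):
        if self.reflectance < 0 or self.transmittance < 0:
            raise ValueError("reflectance and transmittance must be >= 0")
        if self.reflectance + self.transmittance >= 1.0:
            raise ValueError("reflectance + transmittance must be < 1")

    @property
    def absorbance(self) -> float:
        return 1.0 - self.reflectance - self.transmittance


def total_chlorophyll(cfg: AntennaConfig) -> float:
    """Areal chlorophyll (umol m-2) implied by an antenna configuration."""
    per_psii = cfg.core_chl_psii + cfg.chl_per_lhc * cfg.n1
    per_psi = cfg.core_chl_psi + cfg.chl_per_lhc * cfg.n1
    return cfg.psii_conc * (per_psii + cfg.psi_psii_ratio * per_psi)


def antenna_size_for_chl(
    target_chl: float,
    psii_conc: float,
    ratio: float = DEFAULT_PSI_PSII_RATIO,
    core_chl_psii: int = CORE_CHL_PSII,
    core_chl_psi: int = CORE_CHL_PSI,
    chl_per_lhc: int = CHL_PER_LHC,
) -> float:
    """Invert the chlorophyll accounting for the LHC count ``n1``.

    Exact algebraic inverse of :func:`total_chlorophyll` at fixed photosystem
    number.  Raises if the target lies below the core-only minimum.
    """
    if psii_conc <= 0:
        raise ValueError("psii_conc must be > 0 to invert")
    core_min = psii_conc * (core_chl_psii + ratio * core_chl_psi)
    if target_chl < core_min - 1e-9:
        raise ValueError(
            f"target chlorophyll {target_chl:.3f} below core-only minimum "
            f"{core_min:.3f} umol m-2 (n1 cannot be negative)"
        )
    n1 = (target_chl / psii_conc - (core_chl_psii + ratio * core_chl_psi)) / (
        chl_per_lhc * (1.0 + ratio)
    )
    return max(n1, 0.0)


def broadband_optics(spectral_r, spectral_t, solar_spectrum) -> LeafOptics:
    """PAR-band optics as spectrum-weighted means of per-wavelength values."""
    r = np.asarray(spectral_r, dtype=float)
    t = np.asarray(spectral_t, dtype=float)
    s = np.asarray(solar_spectrum, dtype=float)
    if not (r.shape == t.shape == s.shape):
        raise ValueError("spectral arrays must have identical length")
    if np.any((r < 0) | (r > 1) | (t < 0) | (t > 1)):
        raise ValueError("spectral r/t values must lie in [0, 1]")
    if np.any(s < 0) or s.sum() == 0:
        raise ValueError("spectrum must be non-negative and not all zero")
    w = s / s.sum()
    return LeafOptics(float(np.dot(w, r)), float(np.dot(w, t)))


def _chl_half_sat(a_max: float, a_ref: float, chl_ref: float) -> float:
    # solve a_ref = a_max * (1 - exp(-chl_ref / chl0)) for chl0
    if not 0 < a_ref < a_max:
        raise ValueError("need 0 < a_ref < a_max for calibration")
    return -chl_ref / math.log1p(-a_ref / a_max)


def optics_from_chl(
    chl,
    a_max: float = 0.96,
    a_ref: float = 0.90,
    chl_ref: float = DEFAULT_MEAN_CHL,
    reflect_fraction: float = 0.5,
):
    """Leaf optics from areal chlorophyll via a saturating absorbance curve.

    a(chl) = a_max * (1 - exp(-chl / chl0)) with chl0 set so that
    a(chl_ref) = a_ref; the unabsorbed fraction is split between
    reflectance and transmittance by ``reflect_fraction`` (default 1:1).

    Accepts a scalar (returns :class:`LeafOptics`) or an array (returns a
    ``(reflectance, transmittance)`` array pair).
    """
    chl0 = _chl_half_sat(a_max, a_ref, chl_ref)
    arr = np.asarray(chl, dtype=float)
    if np.any(arr < 0):
        raise ValueError("chlorophyll must be >= 0")
    a = a_max * (1.0 - np.exp(-arr / chl0))
    a = np.maximum(a, 1e-9)  # a pigment-free blade still isn't a pure scatterer
    r = (1.0 - a) * reflect_fraction
    t = (1.0 - a) * (1.0 - reflect_fraction)
    if np.ndim(chl) == 0:
        return LeafOptics(float(r), float(t))
    return r, t


# SPAD-502 style exponential calibration; validity documented for
# readings up to ~60 (dense rice flag leaves).
SPAD_C0 = 99.0  # umol m-2
SPAD_C1 = 0.042  # per SPAD unit
SPAD_VALID_MAX = 60.0


def spad_to_chl(spad, c0: float = SPAD_C0, c1: float = SPAD_C1):
    """Chlorophyll (umol m-2) from a SPAD reading (monotone, chl(0)=0)."""
    arr = np.asarray(spad, dtype=float)
    if np.any(arr < 0):
        raise ValueError("SPAD readings must be >= 0")
    if np.any(arr > SPAD_VALID_MAX):
        warnings.warn("SPAD reading outside documented calibration range")
    out = c0 * np.expm1(c1 * arr)
    return float(out) if np.ndim(spad) == 0 else out


def chl_to_spad(chl, c0: float = SPAD_C0, c1: float = SPAD_C1):
    """Inverse SPAD calibration; round-trips with :func:`spad_to_chl`."""
    arr = np.asarray(chl, dtype=float)
    if np.any(arr < 0):
        raise ValueError("chlorophyll must be >= 0")
    out = np.log1p(arr / c0) / c1
    return float(out) if np.ndim(chl) == 0 else out
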
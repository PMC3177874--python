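"""Light-use-efficiency NPP: monthly production from EVI and irradiance.

Monthly NPP (g C m^-2 month^-1) is the product of surface solar irradiance
Sr (MJ m^-2 month^-1, on the PAR scale to which the efficiency applies), the
satellite greenness index EVI, a constant maximum light-use efficiency e_max
(0.55 g C MJ^-1), and two unitless stress scalars:

    NPP = Sr * EVI * e_max * T * W

T penalizes departure from a per-cell optimum temperature Topt, itself read
off the climatology as the mean air temperature of the greenest month.  W is
the moisture scalar 0.5 + 0.5 * EET/PET, floored at 0.5 so drought throttles
but never fully shuts down production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LueParams",
    "derive_topt",
    "temperature_stress",
    "moisture_stress",
    "monthly_npp",
]


@dataclass
class LueParams:
    e_max: float = 0.55  # g C per MJ PAR-scale irradiance
    topt_bounds: tuple[float, float] = (0.0, 35.0)  # degC clamp on Topt

    def __post_init__(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if self.topt_bounds[0] > self.topt_bounds[1]:
            raise ValueError("topt_bounds must be ordered")


def derive_topt(
    evi_climatology: np.ndarray,
    temp_climatology: np.ndarray,
    params: LueParams | None = None,
) -> np.ndarray:
    """Optimum temperature per cell from 12-month climatologies.

    Topt is the climatological mean air temperature of the month of maximum
    EVI (ties go to the earliest month), clamped to ``topt_bounds``.  Cells
    that are all-NaN in either climatology yield NaN.
    """
    params = params or LueParams()
    evi = np.asarray(evi_climatology, dtype=float)
    temp = np.asarray(temp_climatology, dtype=float)
    if evi.shape != temp.shape or evi.shape[0] != 12:
        raise ValueError("climatologies must both have 12 leading months")
    invalid = np.isnan(evi).all(axis=0) | np.isnan(temp).all(axis=0)
    evi_f = np.where(np.isnan(evi), -np.inf, evi)
    peak = np.argmax(evi_f, axis=0)  # first max -> earliest month on ties
    topt = np.take_along_axis(temp, peak[None, ...], axis=0)[0]
    topt = np.clip(topt, *params.topt_bounds)
    return np.where(invalid, np.nan, topt)


def temperature_stress(t_month, topt) -> np.ndarray:
    """Unitless temperature stress scalar in [0, 1].

    An asymmetric double-logistic in (T - Topt) — a steep cold-side cutoff
    and a gentler warm-side rolloff — normalized by its value at T = Topt so
    the scalar is 1 at the optimum, falls off monotonically beyond a few
    degrees of departure, and drops below 0.05 by 25 degC of cold departure.
    """
    t = np.asarray(t_month, dtype=float)
    opt = np.asarray(topt, dtype=float)

    def raw(tt):
        cold = 1.0 / (1.0 + np.exp(0.25 * (opt - 10.0 - tt)))
        warm = 1.0 / (1.0 + np.exp(0.3 * (tt - 10.0 - opt)))
        return cold * warm

    scal = raw(t) / raw(opt)
    return np.clip(scal, 0.0, 1.0)


def moisture_stress(eet, pet) -> np.ndarray:
    """W = 0.5 + 0.5 * EET/PET; no atmospheric demand (PET = 0) gives W = 1."""
    eet = np.asarray(eet, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if np.any(eet < -1e-12) or np.any(pet < -1e-12):
        raise ValueError("eet and pet must be nonnegative")
    if np.any(eet > pet + 1e-9):
        raise ValueError("eet cannot exceed pet")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pet > 0, eet / np.maximum(pet, 1e-300), 1.0)
    return 0.5 + 0.5 * np.clip(ratio, 0.0, 1.0)


def monthly_npp(sr, evi, t_scalar, w_scalar, params: LueParams | None = None) -> np.ndarray:
    """Monthly NPP, g C m^-2 month^-1; negative EVI (water/snow) fixes nothing."""
    params = params or LueParams()
    sr = np.asarray(sr, dtype=float)
    if np.any(sr < 0):
        raise ValueError("solar irradiance must be nonnegative")
    evi_prod = np.clip(np.asarray(evi, dtype=float), 0.0, 1.0)
    return sr * evi_prod * params.e_max * np.asarray(t_scalar) * np.asarray(w_scalar)
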
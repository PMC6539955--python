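"""IC50 estimation from viability-versus-concentration data.

Viability measured in an MTT-style assay (absorbance relative to vehicle
wells) is modelled with the four-parameter logistic (4PL)

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)**hill)

fit by least squares on a log-concentration grid with multiple hill-slope
starts.  The reported IC50 is the *absolute-50%* read-out: the concentration
at which the fitted curve crosses viability 0.5 (half the vehicle level),
inverted in closed form from the fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitError, RangeError

__all__ = [
    "DoseResponsePoint",
    "DoseResponseFit",
    "normalize_viability",
    "four_pl",
    "fit_dose_response",
    "ic50_from_fit",
]

_HILL_STARTS = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class DoseResponsePoint:
    concentration: float  # μM, >= 0
    viability: float      # fraction of vehicle control


@dataclass(frozen=True)
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float   # μM; midpoint of the fitted logistic
    hill: float
    sse: float
    n_points: int
    warning: str | None = None


def normalize_viability(raw_signal: Sequence[float] | np.ndarray, vehicle_mean: float) -> np.ndarray:
    """Scale raw per-well absorbance by the vehicle-well mean.

    Vehicle wells map to 1.0 on average; a zero signal maps to 0.0.
    """
    if vehicle_mean <= 0:
        raise DomainError(f"vehicle_mean must be positive, got {vehicle_mean}")
    return np.asarray(raw_signal, dtype=float) / vehicle_mean


def four_pl(conc: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def fit_dose_response(points: Sequence[DoseResponsePoint]) -> DoseResponseFit:
    """Least-squares 4PL fit over the positive-concentration points.

    Zero-concentration wells are assumed already consumed by normalization
    and are excluded (the logistic is fit on a log grid).  Requires at least
    five distinct positive concentrations and a non-constant response.  The
    midpoint is constrained to the positive concentration range of the data.
    """
    conc = np.array([p.concentration for p in points], dtype=float)
    viab = np.array([p.viability for p in points], dtype=float)
    if (conc < 0).any():
        raise DomainError("negative concentration")
    pos = conc > 0
    conc, viab = conc[pos], viab[pos]
    if len(np.unique(conc)) < 5:
        raise FitError("need >= 5 distinct positive concentrations")
    if np.ptp(viab) < 1e-12:
        raise FitError("no response: viability constant across concentrations")

    warning = None
    # dose-dependent *increase* means no measurable inhibition
    if np.corrcoef(np.log(conc), viab)[0, 1] > 0:
        warning = "no inhibition: viability increases with concentration"

    lo_c, hi_c = conc.min(), conc.max()
    span = viab.max() - viab.min()
    bounds_lo = [viab.max() - 0.5 * span, viab.min() - 1.5 * span, np.log10(lo_c), 0.05]
    bounds_hi = [viab.max() + 1.5 * span, viab.min() + 0.5 * span, np.log10(hi_c), 20.0]

    def residuals(theta: np.ndarray) -> np.ndarray:
        top, bottom, log_ic50, hill = theta
        return four_pl(conc, top, bottom, 10.0 ** log_ic50, hill) - viab

    best = None
    log_mid = float(np.log10(np.sqrt(lo_c * hi_c)))
    for hill0 in _HILL_STARTS:
        theta0 = np.array([viab.max(), viab.min(), log_mid, hill0])
        theta0 = np.clip(theta0, bounds_lo, bounds_hi)
        try:
            sol = least_squares(residuals, theta0, bounds=(bounds_lo, bounds_hi))
        except Exception:  # singular jacobian etc.; other starts may succeed
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("4PL fit failed to converge from all starts")

    top, bottom, log_ic50, hill = best.x
    sse = float(2.0 * best.cost)
    flat_sse = float(((viab - viab.mean()) ** 2).sum())
    if sse > flat_sse + 1e-9:
        raise FitError(
            f"4PL fit worse than flat-line model (sse {sse:.4g} > {flat_sse:.4g})"
        )
    if bottom >= top and warning is None:
        raise FitError("degenerate fit: bottom >= top")
    return DoseResponseFit(
        top=float(top),
        bottom=float(bottom),
        ic50=float(10.0 ** log_ic50),
        hill=float(hill),
        sse=sse,
        n_points=len(conc),
        warning=warning,
    )


def ic50_from_fit(fit: DoseResponseFit, level: float = 0.5) -> float:
    """Concentration at which the fitted curve crosses an absolute viability
    level (default 0.5 — half the vehicle signal).

    Closed-form inversion of the 4PL; for the symmetric case (top = 1,
    bottom = 0, level = 0.5) this equals the fitted midpoint exactly.
    """
    if not (fit.bottom < level < fit.top):
        raise RangeError(
            f"fitted curve spans ({fit.bottom:.3f}, {fit.top:.3f}); "
            f"never crosses {level}"
        )
    return float(fit.ic50 * ((fit.top - level) / (level - fit.bottom)) ** (1.0 / fit.hill))
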
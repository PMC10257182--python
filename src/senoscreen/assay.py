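"""Validation-plate quantification: viability, IC50 fits, senolytic index.

Validation screens measure per-well nuclei counts for control
(proliferating) and senescent cultures across a dose series.  Counts are
normalised to the vehicle (DMSO) mean, fitted to a log-inhibitor vs
normalised-response curve with variable slope (four-parameter logistic with
the top plateau constrained to 100%), and summarised by the IC50.  The
senolytic index SI = IC50(control) / IC50(senescent) quantifies selectivity:
SI > 1 means senescent cells die at lower doses than controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseFit",
    "SenolyticIndex",
    "four_pl",
    "half_log_doses",
    "normalise_to_vehicle",
    "fit_dose_response",
    "senolytic_index",
]


def four_pl(dose, ic50: float, hill: float, top: float = 100.0,
            bottom: float = 0.0) -> np.ndarray:
    """Log-inhibitor vs response, variable slope:

    ``response = bottom + (top − bottom) / (1 + 10^((log10 IC50 − log10 dose)·hill))``

    A declining (inhibition) curve has ``hill < 0`` under this sign
    convention; at ``dose = IC50`` the response is midway between the
    plateaus regardless of slope.
    """
    dose = np.asarray(dose, dtype=float)
    expo = (np.log10(ic50) - np.log10(dose)) * hill
    return bottom + (top - bottom) / (1.0 + 10.0 ** expo)


def half_log_doses(top_dose: float = 10_000.0, n: int = 10) -> np.ndarray:
    """A half-log (√10-spaced) dose series descending from ``top_dose``.

    The default starts at 10 µM (in nM units) — the standard 10-point
    validation design.
    """
    return top_dose / (10 ** (0.5 * np.arange(n)))


def normalise_to_vehicle(counts, vehicle_counts) -> np.ndarray:
    """Express nuclei counts as % of the vehicle-well mean (linear in counts)."""
    counts = np.asarray(counts, dtype=float)
    vmean = float(np.mean(vehicle_counts))
    if vmean <= 0:
        raise ValueError(f"vehicle mean must be positive, got {vmean}")
    return 100.0 * counts / vmean


@dataclass
class DoseResponseFit:
    """A fitted dose-response curve (top plateau fixed)."""

    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    extrapolated: bool   # IC50 outside the tested dose range
    dose_unit: str = "nM"

    def predict(self, dose) -> np.ndarray:
        return four_pl(dose, self.ic50, self.hill, self.top, self.bottom)


def fit_dose_response(doses, responses, top_fixed: float = 100.0,
                      dose_unit: str = "nM") -> DoseResponseFit:
    """Ordinary-least-squares fit of the variable-slope inhibition curve.

    Fits (log10 IC50, hill, bottom) with the top plateau fixed at
    ``top_fixed`` and bottom bounded to [0, top].  Multi-start
    initialisation covers both slope signs and several IC50 positions
    across the tested range, so the fit does not depend on a lucky guess.
    Non-convergence (including a flat response with no decline to fit) is
    reported through the ``converged`` flag rather than an exception.
    The fit is scale-equivariant: rescaling all doses rescales the IC50 by
    the same factor.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")

    ld = np.log10(doses)
    lo, hi = ld.min(), ld.max()
    top = float(top_fixed)

    def residuals(theta):
        lic50, hill, bottom = theta
        return four_pl(doses, 10.0 ** lic50, hill, top, bottom) - responses

    bounds = ([lo - 3.0, -10.0, 0.0], [hi + 3.0, 10.0, top])
    b0 = float(np.clip(responses.min(), 0.0, top))
    starts = [
        (l0, h0, b0)
        for l0 in np.linspace(lo, hi, 5)
        for h0 in (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0)
    ]
    best = None
    for theta0 in starts:
        try:
            res = least_squares(residuals, theta0, bounds=bounds, method="trf")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res

    if best is None:
        return DoseResponseFit(float("nan"), float("nan"), top, float("nan"),
                               float("inf"), False, False, dose_unit)
    lic50, hill, bottom = best.x
    ic50 = float(10.0 ** lic50)
    rss = float(2.0 * best.cost)
    # a fit with no meaningful decline (plateaus within 10% of each other)
    # carries no IC50 information
    converged = (top - bottom) > 10.0
    extrapolated = not (doses.min() <= ic50 <= doses.max())
    return DoseResponseFit(ic50=ic50, hill=float(hill), top=top,
                           bottom=float(bottom), rss=rss, converged=converged,
                           extrapolated=extrapolated, dose_unit=dose_unit)


@dataclass
class SenolyticIndex:
    """SI = IC50(control) / IC50(senescent); SI > 1 = senescence-selective."""

    si: float
    ic50_control: float
    ic50_senescent: float
    dose_unit: str


def senolytic_index(fit_control: DoseResponseFit,
                    fit_senescent: DoseResponseFit) -> SenolyticIndex:
    """Selectivity ratio of two converged dose-response fits (same units)."""
    if fit_control.dose_unit != fit_senescent.dose_unit:
        raise ValueError(
            f"dose-unit mismatch: {fit_control.dose_unit} vs {fit_senescent.dose_unit}"
        )
    if not (fit_control.converged and fit_senescent.converged):
        raise ValueError("both fits must have converged to form a senolytic index")
    return SenolyticIndex(
        si=fit_control.ic50 / fit_senescent.ic50,
        ic50_control=fit_control.ic50,
        ic50_senescent=fit_senescent.ic50,
        dose_unit=fit_control.dose_unit,
    )
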
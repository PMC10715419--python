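"""Dose-response fitting and circulating-concentration arithmetic.

Viability curves are fitted with the four-parameter logistic (4PL)

    y(x) = bottom + (top - bottom) / (1 + (x / IC50)^hill)

by least squares on log-dose, with a multi-start over hill-slope signs to
avoid the canonical 4PL local-minimum trap. IC50 is the dose at the curve
midpoint, in the units of the input doses (micromolar here).

Circulating concentrations of uremic solutes are estimated by scaling a
published healthy reference interval by the relative MS intensity ratio
between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class DoseResponse:
    """Replicate-level viability measurements across a dose series."""

    compound: str
    doses: np.ndarray       # micromolar, strictly positive
    responses: np.ndarray   # viability fraction (vehicle-normalized)
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.size != self.responses.size:
            raise ValueError("doses and responses differ in length")
        if (self.doses <= 0).any():
            raise ValueError("doses must be strictly positive")

    @property
    def n_distinct_doses(self) -> int:
        return int(np.unique(self.doses).size)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"compound": self.compound, "dose_uM": self.doses,
             "replicate": self.replicates if self.replicates is not None
             else np.arange(1, self.doses.size + 1),
             "response": self.responses}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, compound: str | None = None) -> "DoseResponse":
        df = pd.read_csv(path)
        if compound is not None:
            df = df[df["compound"] == compound]
        if df.empty:
            raise ValueError(f"no rows for compound {compound!r} in {path}")
        return cls(
            compound=compound or str(df["compound"].iloc[0]),
            doses=df["dose_uM"].to_numpy(),
            responses=df["response"].to_numpy(),
            replicates=df["replicate"].to_numpy() if "replicate" in df else None,
        )


@dataclass
class CurveFit:
    top: float
    bottom: float
    hill: float
    ic50: float
    sse: float
    converged: bool

    def predict(self, doses) -> np.ndarray:
        x = np.asarray(doses, dtype=float)
        return four_param_logistic(x, self.top, self.bottom, self.hill, self.ic50)


def four_param_logistic(x, top: float, bottom: float, hill: float, ic50: float):
    """4PL response at dose x; equals (top + bottom)/2 at x = IC50."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (np.log(x) - np.log(ic50))))


def normalize_to_vehicle(responses, vehicle_responses) -> np.ndarray:
    """Express raw absorbances as viability fractions of the vehicle mean."""
    vehicle = np.asarray(vehicle_responses, dtype=float)
    if vehicle.size == 0 or vehicle.mean() <= 0:
        raise ValueError("vehicle control mean must be positive")
    return np.asarray(responses, dtype=float) / vehicle.mean()


def fit_four_param_logistic(dr: DoseResponse) -> CurveFit:
    """Least-squares 4PL fit with multi-start over hill slopes.

    Starts from hill in {+-0.5, +-1, +-2} with IC50 at the geometric mean
    of the doses, top/bottom at the observed extremes; the best start by
    SSE wins. IC50 is optimized on the log scale so it stays positive, and
    is bounded to within two decades of the tested dose range (an IC50 far
    outside the assay window is not identifiable from the data). Top and
    bottom are bounded by the observed response range with 50% headroom;
    viability assays cannot go below zero. A fit is flagged non-converged
    when no start terminates cleanly; the best parameters found are still
    returned.
    """
    if dr.n_distinct_doses < 4:
        raise ValueError("4PL fitting requires >= 4 distinct doses")
    x = dr.doses
    y = dr.responses
    logx = np.log(x)

    def residuals(theta):
        top, bottom, hill, log_ic50 = theta
        return bottom + (top - bottom) / (1.0 + np.exp(hill * (logx - log_ic50))) - y

    span = max(float(y.max() - y.min()), 1e-6)
    lo_resp = min(0.0, float(y.min()))
    hi_resp = float(y.max()) + 0.5 * span
    two_decades = np.log(100.0)
    bounds = (
        [lo_resp, lo_resp, -10.0, float(logx.min()) - two_decades],
        [hi_resp, hi_resp, 10.0, float(logx.max()) + two_decades],
    )
    top0 = float(y.max())
    bottom0 = max(float(y.min()), lo_resp)
    log_ic50_0 = float(logx.mean())  # geometric mean of doses
    best = None
    any_converged = False
    for hill0 in (0.5, -0.5, 1.0, -1.0, 2.0, -2.0):
        res = least_squares(
            residuals, x0=[top0, bottom0, hill0, log_ic50_0],
            bounds=bounds, method="trf", max_nfev=5000,
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        sse = float(2 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res.x, res.success)
        any_converged = any_converged or res.success
    sse, theta, success = best
    top, bottom, hill, log_ic50 = theta
    if bottom > top:  # canonical orientation: mirror hill sign
        top, bottom, hill = bottom, top, -hill
    return CurveFit(top=float(top), bottom=float(bottom), hill=float(hill),
                    ic50=float(np.exp(log_ic50)), sse=sse,
                    converged=bool(any_converged and success))


def scale_concentration(
    relative_ratio: float, reference_range: tuple[float, float]
) -> tuple[float, float]:
    """Scale a healthy-plasma concentration interval (uM) by a relative
    intensity ratio: e.g. a 12-fold elevated compound with a 5-15 uM
    reference range circulates at an estimated 60-180 uM."""
    if relative_ratio <= 0:
        raise ValueError("relative ratio must be positive")
    lo, hi = reference_range
    if lo > hi:
        raise ValueError("reference range must satisfy low <= high")
    return (lo * relative_ratio, hi * relative_ratio)
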
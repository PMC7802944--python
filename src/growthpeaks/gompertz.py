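"""Modified (Zwietering) Gompertz fits of log-transformed growth curves.

The model for the log-relative population is

    y(t) = A * exp(-exp(mu*e/A * (lam - t) + 1)),

where ``A`` is the asymptote of log(n/n0), ``mu`` the maximum specific growth
rate (the steepest slope of y) and ``lam`` the lag time (the time-axis
intercept of the tangent at the steepest point).  The natural logarithm is
used by default — the factor e in the exponent presumes it — with base 10
available for comparison with log10-plotted data (A, mu are then in decades).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .derivatives import Curve
from .errors import InvalidInputError

__all__ = ["GompertzFit", "gompertz_value", "fit_gompertz"]

_MAX_NFEV = 2000
_TOL = 1e-10


@dataclass(frozen=True)
class GompertzFit:
    A: float
    mu: float
    lam: float
    se_A: float
    se_mu: float
    se_lam: float
    window: tuple[float, float]  # fitted time range, hr
    n_points: int
    converged: bool
    message: str = ""


def gompertz_value(t, A: float, mu: float, lam: float):
    """Evaluate the modified Gompertz curve; total on A > 0."""
    if A <= 0:
        raise InvalidInputError("Gompertz asymptote A must be > 0")
    t = np.asarray(t, dtype=float)
    return A * np.exp(-np.exp(mu * math.e / A * (lam - t) + 1.0))


def _initial_guess(times: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # Zwietering geometry: A from the plateau, mu from the steepest forward
    # difference, lam from the time-axis intercept of the tangent there.
    A0 = max(float(y.max()), 1e-6)
    slopes = np.diff(y) / np.diff(times)
    i = int(np.argmax(slopes))
    mu0 = max(float(slopes[i]), 1e-6)
    lam0 = float(times[i] - y[i] / mu0)
    return A0, mu0, lam0


def fit_gompertz(
    curve: Curve,
    od_ceiling: float | None = None,
    log_base: str = "e",
) -> GompertzFit:
    """Fit the Gompertz model to the log-ratio of a raw growth curve.

    ``curve`` holds the raw population proxy (cell number or corrected OD);
    the fit is performed on log(v(t)/v(0)).  When ``od_ceiling`` is given,
    points with v > od_ceiling are discarded first (the partial-fit protocol
    for plate-reader OD corrupted by multiple scattering at high density).

    Returns a :class:`GompertzFit`; when the optimizer fails the fit is
    returned with ``converged=False`` and NaN parameters rather than raising.
    """
    if log_base not in ("e", "10"):
        raise InvalidInputError(f"log_base must be 'e' or '10', got {log_base!r}")
    times = curve.times
    values = curve.values
    if values[0] <= 0:
        raise InvalidInputError("first curve value must be > 0 to form the log-ratio")
    if od_ceiling is not None:
        keep = values <= od_ceiling
        times, values = times[keep], values[keep]
    if np.any(values <= 0):
        raise InvalidInputError("curve values must be > 0 to form the log-ratio")
    if times.size < 8:
        raise InvalidInputError(
            f"need at least 8 points after truncation, got {times.size}"
        )
    y = np.log(values / values[0])
    if log_base == "10":
        y = y / math.log(10.0)

    guess = _initial_guess(times, y)
    window = (float(times[0]), float(times[-1]))
    try:
        params, cov = curve_fit(
            lambda t, A, mu, lam: A * np.exp(-np.exp(mu * math.e / A * (lam - t) + 1.0)),
            times,
            y,
            p0=guess,
            bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            method="trf",
            maxfev=_MAX_NFEV,
            xtol=_TOL,
            ftol=_TOL,
            gtol=_TOL,
        )
    except RuntimeError as exc:  # optimizer exhausted its budget
        nan = float("nan")
        return GompertzFit(
            A=nan, mu=nan, lam=nan, se_A=nan, se_mu=nan, se_lam=nan,
            window=window, n_points=int(times.size), converged=False,
            message=str(exc),
        )
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(cov))
    ses = np.where(np.isfinite(ses), ses, 0.0)
    return GompertzFit(
        A=float(params[0]),
        mu=float(params[1]),
        lam=float(params[2]),
        se_A=float(ses[0]),
        se_mu=float(ses[1]),
        se_lam=float(ses[2]),
        window=window,
        n_points=int(times.size),
        converged=True,
    )
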
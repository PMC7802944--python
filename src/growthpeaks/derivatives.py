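"""Uniform-grid curves, forward-difference derivatives and Hann smoothing.

The derivative estimator is the plain forward difference

    (dv/dt)|_i = (v_{i+1} - v_i) / (t_{i+1} - t_i),

assigned to the left grid point t_i; the second derivative is the estimator
applied twice.  Smoothing convolves with a Hann (raised-cosine) window
normalized to unit sum, so constant curves pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidInputError

__all__ = ["Curve", "forward_diff", "hanning_smooth"]

_SPACING_RTOL = 1e-9


@dataclass(frozen=True)
class Curve:
    """A scalar time series on a uniformly spaced, strictly increasing grid.

    ``order`` counts how many times a derivative has been taken (0 for raw
    data); ``label`` is carried through transformations for provenance.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    order: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise InvalidInputError("times and values must be 1-D and equally long")
        if times.size == 0:
            raise InvalidInputError("curve must contain at least one point")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise InvalidInputError("times and values must be finite")
        if times.size >= 2:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise InvalidInputError("times must be strictly increasing")
            h = steps[0]
            if np.any(np.abs(steps - h) > _SPACING_RTOL * max(abs(h), 1.0)):
                raise InvalidInputError("time grid must be uniformly spaced")

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        if len(self) < 2:
            raise InvalidInputError("spacing undefined for a single-point curve")
        return float(self.times[1] - self.times[0])

    def window(self, t0: float, t1: float) -> "Curve":
        """Restrict to times t0 <= t <= t1 (inclusive)."""
        mask = (self.times >= t0) & (self.times <= t1)
        if not mask.any():
            raise InvalidInputError(
                f"window [{t0}, {t1}] does not intersect the time range "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        return replace(self, times=self.times[mask], values=self.values[mask])


def forward_diff(curve: Curve) -> Curve:
    """Forward-difference derivative on the left grid t_0 ... t_{len-2}."""
    if len(curve) < 2:
        raise InvalidInputError("forward difference needs at least 2 points")
    dv = np.diff(curve.values) / np.diff(curve.times)
    label = f"d({curve.label})/dt" if curve.label else ""
    return Curve(times=curve.times[:-1], values=dv, label=label, order=curve.order + 1)


def _hann_kernel(window: int) -> np.ndarray:
    # w_j = 0.5*(1 - cos(2*pi*j/(window-1))), zero at both endpoints,
    # normalized to unit sum.
    j = np.arange(window)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * j / (window - 1)))
    return w / w.sum()


def hanning_smooth(curve: Curve, window: int = 11, edge: str = "reflect") -> Curve:
    """Convolve with a unit-sum Hann window of ``window`` (odd) points.

    ``edge`` selects boundary handling: ``"reflect"`` pads by reflection
    (default), ``"truncate"`` renormalizes the kernel over the part of the
    window that overlaps the data.
    """
    window = int(window)
    if window % 2 == 0 or window < 3 or window > len(curve):
        raise InvalidInputError(
            f"window must be odd and within [3, {len(curve)}], got {window}"
        )
    if edge not in ("reflect", "truncate"):
        raise InvalidInputError(f"edge must be 'reflect' or 'truncate', got {edge!r}")
    kernel = _hann_kernel(window)
    half = window // 2
    v = curve.values
    if edge == "reflect":
        padded = np.pad(v, half, mode="reflect")
        smoothed = np.convolve(padded, kernel, mode="valid")
    else:
        full = np.convolve(v, kernel, mode="same")
        norm = np.convolve(np.ones_like(v), kernel, mode="same")
        smoothed = full / norm
    return replace(curve, values=smoothed)
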
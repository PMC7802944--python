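"""Synthetic plate-reader datasets with known ground truth.

The generator simulates the growth/GFP kinetics on the instrument sampling
grid (default 10-min readings for 16 h, 97 points per well) and pushes them
through a measurement model:

* OD: a saturating monotone map ``OD_raw = OD_max*(1 - exp(-od_scale*n/OD_max))
  + baseline`` standing in for multiple scattering — linear at low density,
  flattening at high density — plus an optional early-time Gaussian bump
  emulating nanoparticle interference, all in raw (short path length) units.
  This map is a declared test harness: the real OD-to-cell-number relation
  under multiple scattering is instrument-specific and is deliberately not
  modeled mechanistically.
* FL: linear in the fluorescent protein count plus a baseline.
* Noise: multiplicative lognormal per reading with coefficient of variation
  ``noise_cv``, independent across wells and time points, plus an optional
  additive Gaussian floor; all randomness from one seeded generator, so the
  same seed and parameters reproduce the dataset bitwise.

The ground-truth record carries the noiseless kinetics (trajectory and
noiseless per-channel curves) and the derivative-peak locations and Gompertz
parameters computed from them on the same sampling grid, which is what the
recovery tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .derivatives import Curve, forward_diff
from .errors import InvalidInputError
from .gompertz import fit_gompertz
from .model import (
    DEFAULT_GFP,
    DEFAULT_GROWTH,
    GfpParams,
    GrowthParams,
    InitialState,
    Trajectory,
    default_initial_state,
    simulate,
)
from .peaks import find_peak
from .plate_io import LONG_COLUMNS, PlateDataset

__all__ = ["MeasurementModel", "GroundTruth", "generate_dataset"]


@dataclass(frozen=True)
class MeasurementModel:
    """Optics and noise mapping model states to plate-reader readings.

    Defaults give a pathlength-corrected stationary OD of about 1.25 with the
    map within a few percent of linear below the usual Gompertz ceiling
    (corrected OD 1.0) while still flattening visibly near carrying capacity.
    """

    od_scale: float = 2.9e-10  # raw OD per cell
    od_saturation: float = 4.0  # OD_max of the saturating map, raw OD units
    fl_scale: float = 1e-8  # FL counts per fluorescent protein
    baseline_od: float = 0.0  # additive raw-OD offset
    baseline_fl: float = 0.0  # additive FL offset
    noise_cv: float = 0.02  # multiplicative noise CV per reading
    noise_floor: float = 0.0  # SD of optional additive Gaussian noise
    artifact_amplitude: float = 0.0  # early-time OD bump (raw OD units)
    artifact_center: float = 1.0  # hr
    artifact_width: float = 0.5  # hr (Gaussian SD)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_scale <= 0 or self.fl_scale <= 0:
            raise InvalidInputError("od_scale and fl_scale must be > 0")
        if self.od_saturation <= 0:
            raise InvalidInputError("od_saturation must be > 0")
        if self.noise_cv < 0 or self.noise_floor < 0:
            raise InvalidInputError("noise parameters must be >= 0")
        if self.artifact_width <= 0:
            raise InvalidInputError("artifact_width must be > 0")

    def od_map(self, n: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Noiseless raw OD for cell numbers ``n`` at ``times``."""
        od_max = self.od_saturation
        od = od_max * (1.0 - np.exp(-self.od_scale * np.asarray(n) / od_max))
        od = od + self.baseline_od
        if self.artifact_amplitude:
            od = od + self.artifact_amplitude * np.exp(
                -0.5 * ((np.asarray(times) - self.artifact_center) / self.artifact_width) ** 2
            )
        return od

    def fl_map(self, pf: np.ndarray) -> np.ndarray:
        return self.fl_scale * np.asarray(pf) + self.baseline_fl


@dataclass
class GroundTruth:
    """Noiseless kinetics and their summaries on the sampling grid.

    ``tau_p``/``tau_pf`` are the forward-difference peak locations of n and pf
    (the same estimator the analysis pipeline applies to measured curves);
    ``lam``/``mu`` come from the Gompertz fit of ln(n/n0) over the full grid.
    """

    trajectory: Trajectory
    od_true: np.ndarray  # noiseless raw OD (pre path-length correction)
    fl_true: np.ndarray
    tau_p: float
    tau_pf: float
    lam: float
    mu: float


def generate_dataset(
    growth: GrowthParams = DEFAULT_GROWTH,
    gfp: GfpParams = DEFAULT_GFP,
    init: InitialState | None = None,
    meas: MeasurementModel = MeasurementModel(),
    n_replicates: int = 3,
    interval: float = 1.0 / 6.0,
    duration: float = 16.0,
    condition: str = "condition",
) -> tuple[PlateDataset, GroundTruth]:
    """Simulate, distort and replicate one condition's OD600 + FL wells."""
    if interval <= 0 or duration < interval:
        raise InvalidInputError("need interval > 0 and duration >= interval")
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    if init is None:
        init = default_initial_state(growth)
    traj = simulate(growth, gfp, init=init, t_end=duration, dt=interval)
    times = traj.times
    od_true = meas.od_map(traj.n, times)
    fl_true = meas.fl_map(traj.pf)

    n_curve = Curve(times, traj.n, label="n")
    pf_curve = Curve(times, traj.pf, label="pf")
    truth = GroundTruth(
        trajectory=traj,
        od_true=od_true,
        fl_true=fl_true,
        tau_p=find_peak(forward_diff(n_curve)).tau,
        tau_pf=find_peak(forward_diff(forward_diff(pf_curve))).tau,
        lam=fit_gompertz(n_curve).lam,
        mu=fit_gompertz(n_curve).mu,
    )

    rng = np.random.default_rng(meas.seed)
    rows = []
    for rep in range(n_replicates):
        well = f"{condition}-{rep + 1}"
        for channel, clean in (("OD600", od_true), ("FL", fl_true)):
            values = clean.copy()
            if meas.noise_cv > 0:
                values = values * np.exp(rng.normal(0.0, meas.noise_cv, size=values.size))
            if meas.noise_floor > 0:
                values = values + rng.normal(0.0, meas.noise_floor, size=values.size)
            rows.append(
                pd.DataFrame(
                    {
                        "well": well,
                        "condition": condition,
                        "channel": channel,
                        "time_hr": times,
                        "value": values,
                    }
                )
            )
    data = (
        pd.concat(rows, ignore_index=True)[LONG_COLUMNS]
        .sort_values(["channel", "well", "time_hr"], kind="mergesort")
        .reset_index(drop=True)
    )
    return PlateDataset(data=data, interval=float(interval)), truth
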
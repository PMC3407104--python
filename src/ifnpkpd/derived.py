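"""Secondary pharmacokinetic quantities computed from fitted parameters
and simulated trajectories: mean transit time, half-life, and AUC."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory

__all__ = ["DerivedReport", "mean_transit_time", "half_life", "auc"]


@dataclass(frozen=True)
class DerivedReport:
    """One derived quantity with its units and provenance."""

    quantity: str
    value: float
    units: str
    inputs: dict

    def to_dict(self) -> dict:
        return {"quantity": self.quantity, "value": self.value,
                "units": self.units, "inputs": dict(self.inputs)}


def mean_transit_time(k_tran: float, n_transit: int = 3) -> float:
    """Mean traversal time (h) of the hepatic synthesis delay.

    The chain has ``n_transit`` identical first-order stages at rate
    ``k_tran`` and the synthesis-driving step adds one more, so
    MTT = (n_transit + 1)/k_tran.
    """
    if not k_tran > 0:
        raise ValueError(f"k_tran must be positive, got {k_tran!r}")
    if not (isinstance(n_transit, (int, np.integer)) and n_transit >= 0):
        raise ValueError(f"n_transit must be a nonnegative integer, got {n_transit!r}")
    return (n_transit + 1) / k_tran


def half_life(k: float) -> float:
    """First-order half-life t1/2 = ln 2 / k (h for k in 1/h)."""
    if not k > 0:
        raise ValueError(f"rate constant must be positive, got {k!r}")
    return math.log(2.0) / k


def auc(trajectory: Trajectory, compartment: str, t0: float, t1: float) -> float:
    """Trapezoidal area under one compartment's series over [t0, t1].

    Endpoints inside a grid interval are included by linear interpolation.
    Units: (compartment units)·h.
    """
    if compartment not in trajectory.states:
        raise KeyError(
            f"unknown compartment {compartment!r}; available: {trajectory.names}"
        )
    t = trajectory.t
    if not (t[0] <= t0 < t1 <= t[-1]):
        raise ValueError(
            f"[{t0}, {t1}] must lie within the trajectory span [{t[0]}, {t[-1]}]"
        )
    y = trajectory.states[compartment]
    inner = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inner], [t1]))
    yy = np.concatenate(([np.interp(t0, t, y)], y[inner], [np.interp(t1, t, y)]))
    return float(np.trapezoid(yy, tt))
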
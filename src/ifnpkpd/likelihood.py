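"""Observations and the log-scale proportional-error likelihood.

Measurements follow a proportional (constant-CV) error model,
Y_obs = Y_pred·(1+ε) with Var(ε) = ω², and are fitted after logarithmic
transformation.  The objective is the extended-least-squares −2·log
likelihood on the log scale, up to the constant N·log 2π:

    MVOF = Σ_j [ log ω²_r(j) + (log Y_obs,j − log Y_pred,j)² / ω²_r(j) ]

with one residual variance ω²_r per response type (a shared-ω² mode is
available).  Only MVOF differences are ever interpreted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSES",
    "RESPONSE_COMPARTMENT",
    "Observation",
    "Dataset",
    "ErrorModel",
    "neg2ll",
    "profile_omega2",
    "OMEGA2_FLOOR",
]

# response type -> measurement units
RESPONSES: dict[str, str] = {
    "mRNA_liver": "gene-expression units",
    "protein_liver": "pg/mg protein",
    "protein_serum": "pg/mL",
    "protein_brain": "pg/mg protein",
    "ISG15_liver": "gene-expression units",
    "OAS_liver": "gene-expression units",
    "ISG15_brain": "gene-expression units",
    "OAS_brain": "gene-expression units",
}

# response type -> model compartment carrying its prediction
RESPONSE_COMPARTMENT: dict[str, str] = {
    "mRNA_liver": "mRNA",
    "protein_liver": "liver",
    "protein_serum": "serum",
    "protein_brain": "brain",
    "ISG15_liver": "ISG15_liver",
    "OAS_liver": "OAS_liver",
    "ISG15_brain": "ISG15_brain",
    "OAS_brain": "OAS_brain",
}

_COLUMNS = ["molecule", "response", "time_h", "value", "experiment", "animal"]
_KEY = ["molecule", "response", "time_h", "animal", "experiment"]

# floor on the profiled residual variance; keeps the objective finite on
# (near-)exact fits and makes noise-free recovery extremely sharp
OMEGA2_FLOOR = 1e-14


@dataclass(frozen=True)
class Observation:
    """One measurement from one animal at one time."""

    molecule: str
    response: str
    time_h: float
    value: float
    experiment: str = ""
    animal: str = ""

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if not (math.isfinite(self.value) and self.value > 0):
            raise ValueError("value must be strictly positive (log transform)")
        if self.time_h < 0:
            raise ValueError("time_h must be nonnegative")


class Dataset:
    """Tidy collection of observations backed by a pandas DataFrame.

    Columns: molecule, response, time_h, value, experiment, animal.
    Values must be strictly positive; non-positive rows are rejected at
    load with a count (no imputation).  Duplicate
    (molecule, response, time_h, animal, experiment) keys are an error.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in _COLUMNS[:4] if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset is missing required columns: {missing}")
        for optional in ("experiment", "animal"):
            if optional not in frame.columns:
                frame[optional] = ""
        frame = frame[_COLUMNS]
        if len(frame) == 0:
            raise ValueError("dataset contains no observations")
        unknown = sorted(set(frame["response"]) - set(RESPONSES))
        if unknown:
            raise ValueError(f"unknown response types: {unknown}")
        frame["time_h"] = frame["time_h"].astype(float)
        frame["value"] = frame["value"].astype(float)
        if (frame["time_h"] < 0).any():
            raise ValueError("negative observation times")
        bad = ~np.isfinite(frame["value"]) | (frame["value"] <= 0)
        if bad.any():
            n_bad = int(bad.sum())
            warnings.warn(
                f"rejected {n_bad} observation(s) with non-positive or non-finite "
                "values (log-scale fitting requires positive data)",
                UserWarning,
                stacklevel=2,
            )
            frame = frame[~bad]
            if len(frame) == 0:
                raise ValueError("no positive observations remain after filtering")
        dup = frame.duplicated(subset=_KEY)
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicated (molecule, response, time, animal, "
                "experiment) keys"
            )
        self.frame = frame.reset_index(drop=True)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_observations(cls, observations: Iterable[Observation]) -> "Dataset":
        rows = [vars(o) for o in observations]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        return cls(pd.read_csv(path, dtype={"experiment": str, "animal": str}))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # -- views --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def responses(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["response"].unique()))

    @property
    def molecules(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["molecule"].unique()))

    def subset(self, molecule: str | None = None,
               responses: Iterable[str] | None = None) -> "Dataset":
        frame = self.frame
        if molecule is not None:
            frame = frame[frame["molecule"] == molecule]
        if responses is not None:
            frame = frame[frame["response"].isin(list(responses))]
        if len(frame) == 0:
            raise ValueError(
                f"no observations for molecule={molecule!r}, responses={responses!r}"
            )
        return Dataset(frame)

    def observations(self) -> list[Observation]:
        return [Observation(**row) for row in self.frame.to_dict("records")]


@dataclass
class ErrorModel:
    """Per-response residual variance ω² on the proportional/log scale."""

    omega2: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for resp, w2 in self.omega2.items():
            if not (math.isfinite(w2) and w2 > 0):
                raise ValueError(f"omega2[{resp!r}] must be > 0, got {w2!r}")

    def __getitem__(self, response: str) -> float:
        return float(self.omega2[response])


def profile_omega2(log_residuals: np.ndarray) -> float:
    """Profiled (closed-form ML) ω²: the mean squared log residual, floored."""
    return max(float(np.mean(np.square(log_residuals))), OMEGA2_FLOOR)


def neg2ll(dataset: Dataset, predictions, error: ErrorModel) -> float:
    """Extended-least-squares −2·log-likelihood on log-transformed data.

    ``predictions`` must be aligned row-by-row with ``dataset.frame``.
    A non-positive prediction at any observation makes the objective +inf
    (with a warning naming the offending responses) rather than raising,
    so optimizers can recover from pathological parameter regions.
    """
    predictions = np.asarray(predictions, dtype=float)
    frame = dataset.frame
    if predictions.shape != (len(frame),):
        raise ValueError("predictions must align with the dataset rows")
    bad = ~np.isfinite(predictions) | (predictions <= 0)
    if bad.any():
        warnings.warn(
            "non-positive model predictions at observations of "
            f"{sorted(frame.loc[bad, 'response'].unique())}; objective set to +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    resid = np.log(frame["value"].to_numpy()) - np.log(predictions)
    total = 0.0
    for resp, idx in frame.groupby("response").indices.items():
        w2 = error[resp]
        r = resid[idx]
        total += r.size * math.log(w2) + float(np.dot(r, r)) / w2
    return total
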
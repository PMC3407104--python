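"""Synthetic study generation emulating the mouse sampling design.

The emulated design: a plasmid bolus at t = 0 (unit dose); liver, serum
and brain sampled destructively at 6, 9, 13, 24 and 48 h with 6-8 animals
per point and group (drawn from two pooled studies), plus an extra serum
series at 1, 3 and 7 h with 3 animals per group from a third study.  Each
animal contributes every response measured at its single terminal time.

Observation noise is proportional: Y = Y_pred·exp(eta) with eta normal and
the log-scale variance chosen so the coefficient of variation equals the
requested omega (a log-normal realization of the Y_pred·(1+eps) error
model, which keeps observations positive for log-scale fitting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dynamics
from .fitting import (
    DEFAULT_GRID_STEP,
    SequentialConfig,
    SequentialFit,
    StageFailure,
    sequential_fit,
)
from .likelihood import RESPONSES, RESPONSE_COMPARTMENT, Dataset
from .params import ISGParams, KineticParameterSet

__all__ = ["StudyDesign", "generate_study", "recovery_experiment", "RecoveryReport"]

ISGKey = tuple[str, str, str]  # (molecule, gene, organ)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling times, group sizes, emitted responses and noise levels."""

    organ_times: tuple[float, ...] = (6.0, 9.0, 13.0, 24.0, 48.0)
    early_serum_times: tuple[float, ...] = (1.0, 3.0, 7.0)
    n_per_point: int | None = None  # None -> seeded uniform draw in {6, 7, 8}
    n_early: int = 3
    responses: tuple[str, ...] = (
        "mRNA_liver", "protein_liver", "protein_serum", "protein_brain",
    )
    omega: float | Mapping[str, float] = 0.2
    experiment_scale_sd: float = 0.0  # optional inter-experiment log-scale factor
    animal_effect_sd: float = 0.0     # optional animal-level log-normal effect

    def __post_init__(self) -> None:
        for times, label in ((self.organ_times, "organ_times"),
                             (self.early_serum_times, "early_serum_times")):
            arr = np.asarray(times, dtype=float)
            if arr.size and (np.any(arr <= 0) or np.any(np.diff(arr) <= 0)):
                raise ValueError(f"{label} must be positive and strictly increasing")
        if self.n_per_point is not None and self.n_per_point < 1:
            raise ValueError("n_per_point must be >= 1")
        if self.n_early < 1:
            raise ValueError("n_early must be >= 1")
        if not self.responses:
            raise ValueError("at least one response must be emitted")
        unknown = set(self.responses) - set(RESPONSES)
        if unknown:
            raise ValueError(f"unknown responses: {sorted(unknown)}")
        for resp in set(self.responses) | {"protein_serum"}:
            if self.omega_for(resp) < 0:
                raise ValueError("omega must be nonnegative")

    def omega_for(self, response: str) -> float:
        if isinstance(self.omega, Mapping):
            return float(self.omega.get(response, 0.0))
        return float(self.omega)

    def group_size(self, rng: np.random.Generator) -> int:
        if self.n_per_point is not None:
            return self.n_per_point
        return int(rng.integers(6, 9))


def _mean_profiles(params: KineticParameterSet,
                   isg: Mapping[ISGKey, ISGParams],
                   grid: np.ndarray) -> dict[str, np.ndarray]:
    """Response -> mean series on the fine grid for one molecule."""
    traj = dynamics.propagate(params, grid)
    out = {
        "mRNA_liver": traj["mRNA"],
        "protein_liver": traj["liver"],
        "protein_serum": traj["serum"],
        "protein_brain": traj["brain"],
    }
    for (mol, gene, organ), p in isg.items():
        if mol != params.molecule:
            continue
        driver = traj["liver"] if organ == "liver" else traj["brain"]
        out[f"{gene}_{organ}"] = dynamics.turnover_response(grid, driver, p)
    return out


def generate_study(
    params: Mapping[str, KineticParameterSet] | KineticParameterSet,
    design: StudyDesign = StudyDesign(),
    isg: Mapping[ISGKey, ISGParams] | None = None,
    seed: int | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
) -> Dataset:
    """Simulate one synthetic study as a tidy observation dataset.

    ``params`` maps molecule label -> kinetic parameter set (a single set
    is accepted); ``isg`` optionally maps (molecule, gene, organ) ->
    turnover parameters for ISG responses named in the design.  A fixed
    seed makes the output bit-reproducible.
    """
    if isinstance(params, KineticParameterSet):
        params = {params.molecule: params}
    isg = dict(isg or {})
    rng = np.random.default_rng(seed)
    all_times = tuple(design.organ_times) + tuple(design.early_serum_times)
    t_max = max(all_times)
    n_steps = int(math.ceil(t_max / grid_step))
    grid = np.linspace(0.0, n_steps * grid_step, n_steps + 1)

    rows: list[dict] = []
    scale_cache: dict[str, float] = {}

    def experiment_scale(exp: str) -> float:
        if design.experiment_scale_sd <= 0:
            return 1.0
        if exp not in scale_cache:
            scale_cache[exp] = float(
                np.exp(rng.normal(0.0, design.experiment_scale_sd)))
        return scale_cache[exp]

    for mol in sorted(params):
        profiles = _mean_profiles(params[mol], isg, grid)
        missing = [r for r in design.responses if r not in profiles]
        if missing:
            raise ValueError(
                f"no ISG parameters supplied for responses {missing} of {mol}"
            )
        emitted = list(design.responses)
        for t in design.organ_times:
            n = design.group_size(rng)
            for i in range(n):
                animal = f"{mol}-{t:g}h-{i + 1}"
                exp = f"main-{1 + i % 2}"
                eta_a = (rng.normal(0.0, design.animal_effect_sd)
                         if design.animal_effect_sd > 0 else 0.0)
                for resp in emitted:
                    mean = float(np.interp(t, grid, profiles[resp]))
                    omega = design.omega_for(resp)
                    sigma = math.sqrt(math.log1p(omega**2))
                    eta = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                    rows.append({
                        "molecule": mol, "response": resp, "time_h": t,
                        "value": mean * math.exp(eta + eta_a)
                        * experiment_scale(exp),
                        "experiment": exp, "animal": animal,
                    })
        if "protein_serum" in design.responses:
            for t in design.early_serum_times:
                for i in range(design.n_early):
                    animal = f"{mol}-early-{t:g}h-{i + 1}"
                    mean = float(np.interp(t, grid, profiles["protein_serum"]))
                    omega = design.omega_for("protein_serum")
                    sigma = math.sqrt(math.log1p(omega**2))
                    eta = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                    rows.append({
                        "molecule": mol, "response": "protein_serum", "time_h": t,
                        "value": mean * math.exp(eta) * experiment_scale("early"),
                        "experiment": "early", "animal": animal,
                    })
    return Dataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# recovery experiments


@dataclass
class RecoveryReport:
    """Aggregated parameter-recovery results over seeded replicates."""

    truth: dict[str, float]
    estimates: dict[str, list[float]]
    se: dict[str, list[float]]
    n_replicates: int
    n_failures: int
    failures: list[str] = field(default_factory=list)

    def median_estimate(self, key: str) -> float:
        return float(np.median(self.estimates[key]))

    def median_relative_error(self, key: str) -> float:
        est = np.asarray(self.estimates[key])
        return float(np.median(np.abs(est - self.truth[key]) / abs(self.truth[key])))

    def coverage(self, key: str, width: float = 2.0) -> float:
        """Fraction of replicates whose +/- width·SE interval covers truth."""
        est = np.asarray(self.estimates[key])
        se = np.asarray(self.se[key])
        ok = np.isfinite(se)
        if not ok.any():
            return math.nan
        covered = np.abs(est[ok] - self.truth[key]) <= width * se[ok]
        return float(np.mean(covered))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.truth):
            if not self.estimates.get(key):
                continue
            rows.append({
                "parameter": key,
                "truth": self.truth[key],
                "median_estimate": self.median_estimate(key),
                "median_rel_error": self.median_relative_error(key),
                "coverage_2se": self.coverage(key),
                "n": len(self.estimates[key]),
            })
        return pd.DataFrame(rows)


def _flatten_truth(params: Mapping[str, KineticParameterSet],
                   isg: Mapping[ISGKey, ISGParams]) -> dict[str, float]:
    mols = sorted(params)
    out: dict[str, float] = {}
    first = params[mols[0]]
    for name in ("k_nunc", "k_int", "k_s1", "k_s2", "k_deg"):
        out[name] = getattr(first.transcription, name)
    for mol in mols:
        flat = params[mol].flat()
        for name in ("k_s", "k_d", "k_tran", "k_ls", "k_sl", "k_sp", "k_ps"):
            if name in flat:
                out[f"{mol}.{name}"] = flat[name]
        out[f"{mol}.k_sb"] = flat["k_sb"]
        out[f"{mol}.k_e"] = flat["k_e"]
    seen_shared: set[tuple[str, str]] = set()
    for (mol, gene, organ), p in isg.items():
        tag = f"{gene}_{organ}"
        if organ == "liver":
            if (gene, organ) not in seen_shared:
                out[f"{tag}.k_s_isg"] = p.k_s_isg
                out[f"{tag}.k_d_isg"] = p.k_d_isg
                if p.ifn50 is not None:
                    out[f"{tag}.ifn50"] = p.ifn50
                seen_shared.add((gene, organ))
        else:
            out[f"{tag}.k_s_isg:{mol}"] = p.k_s_isg
            out[f"{tag}.k_d_isg"] = p.k_d_isg
    return out


def _starts_from_truth(params: Mapping[str, KineticParameterSet],
                       isg: Mapping[ISGKey, ISGParams],
                       stages: Sequence[str],
                       rng: np.random.Generator,
                       perturbation: float) -> dict:
    """Per-stage starting values: truth perturbed symmetrically in log space."""

    def jit(v: float) -> float:
        return float(v * np.exp(rng.normal(0.0, perturbation)))

    starts: dict = {}
    mols = sorted(params)
    if "transcription" in stages:
        tr = params[mols[0]].transcription
        starts["transcription"] = {
            n: jit(getattr(tr, n)) for n in ("k_nunc", "k_int", "k_s1", "k_s2", "k_deg")
        }
    if "protein" in stages:
        starts["protein"] = {}
        for mol in mols:
            flat = params[mol].flat()
            names = ["k_s", "k_d", "k_ls", "k_sl"]
            if params[mol].protein.n_transit > 0:
                names.append("k_tran")
            if params[mol].protein.has_peripheral:
                names += ["k_sp", "k_ps"]
            starts["protein"][mol] = {n: jit(flat[n]) for n in names}
    if "brain" in stages:
        starts["brain"] = {
            mol: {"k_sb": jit(params[mol].protein.k_sb),
                  "k_e": jit(params[mol].brain.k_e)}
            for mol in mols
        }
    if "isg" in stages:
        starts["isg"] = {}
        for (mol, gene, organ), p in isg.items():
            key = (gene, organ)
            entry = starts["isg"].setdefault(key, {})
            entry["k_d_isg"] = jit(p.k_d_isg)
            if organ == "liver":
                entry.setdefault("k_s_isg", jit(p.k_s_isg))
                if p.ifn50 is not None:
                    entry.setdefault("ifn50", jit(p.ifn50))
            else:
                entry[f"k_s_isg:{mol}"] = jit(p.k_s_isg)
    return starts


def _collect(fit: SequentialFit, report: RecoveryReport) -> None:
    values: dict[str, float] = {}
    ses: dict[str, float] = {}

    def add(key: str, fitres) -> None:
        for name, value in fitres.estimates.items():
            full = f"{key}{name}" if key else name
            values[full] = float(value)
            ses[full] = float((fitres.se or {}).get(name, math.nan))

    if fit.transcription:
        add("", fit.transcription)
    # protein and brain may point at the same joint fit; the dict
    # accumulation keeps one entry per parameter either way
    for mol, f in fit.protein.items():
        add(f"{mol}.", f)
    for mol, f in fit.brain.items():
        add(f"{mol}.", f)
    for (gene, organ), f in fit.isg.items():
        add(f"{gene}_{organ}.", f)
    for full, v in values.items():
        report.estimates.setdefault(full, []).append(v)
        report.se.setdefault(full, []).append(ses[full])


def recovery_experiment(
    true_params: Mapping[str, KineticParameterSet] | KineticParameterSet,
    design: StudyDesign = StudyDesign(),
    n_replicates: int = 20,
    seed: int | None = None,
    isg: Mapping[ISGKey, ISGParams] | None = None,
    stages: Sequence[str] = ("transcription", "protein"),
    n_starts: int = 2,
    jitter: float = 0.3,
    start_perturbation: float = 0.35,
) -> RecoveryReport:
    """Generate -> fit ``n_replicates`` synthetic studies and aggregate.

    Each replicate draws fresh observation noise and fresh starting values
    (truth perturbed log-normally with sd ``start_perturbation``), then
    runs the sequential fit for the requested stage prefix.  Replicate
    failures are recorded, not fatal.  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(true_params, KineticParameterSet):
        true_params = {true_params.molecule: true_params}
    isg = dict(isg or {})
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(n_replicates, 3))

    mols = tuple(sorted(true_params))
    variants = {
        mol: {"n_transit": true_params[mol].protein.n_transit,
              "peripheral": true_params[mol].protein.has_peripheral}
        for mol in mols
    }
    report = RecoveryReport(
        truth=_flatten_truth(true_params, isg),
        estimates={}, se={}, n_replicates=n_replicates, n_failures=0,
    )
    for rep in range(n_replicates):
        gen_seed, start_seed, fit_seed = (int(s) for s in rep_seeds[rep])
        dataset = generate_study(true_params, design, isg=isg, seed=gen_seed)
        starts = _starts_from_truth(
            true_params, isg, stages,
            np.random.default_rng(start_seed), start_perturbation,
        )
        config = SequentialConfig(
            molecules=mols, stages=tuple(stages), variants=variants,
            starts=starts, n_starts=n_starts, jitter=jitter, seed=fit_seed,
        )
        try:
            fit = sequential_fit(dataset, config)
        except StageFailure as exc:
            report.n_failures += 1
            report.failures.append(f"replicate {rep}: {exc}")
            if exc.completed is not None:
                _collect(exc.completed, report)
            continue
        _collect(fit, report)
    return report
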
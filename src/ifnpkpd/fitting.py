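"""Maximum-likelihood fitting: stage specifications, the ELS engine, the
sequential four-stage procedure, and uncertainty quantification.

The model is fitted in the order in which information flows through it:

1. ``transcription`` — DNA/DNA'/mRNA rates, fitted jointly to both
   molecules' liver mRNA (one shared parameter set);
2. ``protein`` — hepatic synthesis/degradation, transit delay and
   liver/serum exchange, per molecule, with transcription fixed;
3. ``brain`` — serum->brain input and brain exit rates, per molecule,
   driven by the stage-2 predicted serum profile;
4. ``isg`` — turnover parameters per gene and organ, driven by the
   predicted protein profiles (liver: saturable synthesis shared across
   molecules; brain: linear synthesis per molecule, shared degradation).

All observations available to a stage are fitted simultaneously as a
naive pooled analysis (destructive sampling yields cross-sectional data,
so no animal-level random effects are estimated).  Parameters are
log-transformed internally to enforce positivity.  The per-response
residual variance omega^2 is profiled analytically (mean squared log
residual) and the remaining objective is minimized by multi-start
trust-region least squares inside an iteratively-reweighted loop, whose
fixed points are the extended-least-squares optima.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import dynamics
from .dynamics import propagate_matrix, transcription_matrix, turnover_response
from .likelihood import OMEGA2_FLOOR, Dataset, ErrorModel, neg2ll, profile_omega2
from .params import (
    BrainParams,
    HepaticProteinParams,
    ISGParams,
    KineticParameterSet,
    PeripheralExchange,
    TranscriptionParams,
)

__all__ = [
    "StageSpec",
    "FitResult",
    "SequentialConfig",
    "SequentialFit",
    "StageFailure",
    "fit_stage",
    "sequential_fit",
    "standard_errors",
    "DEFAULT_GRID_STEP",
]

DEFAULT_GRID_STEP = 0.05  # h; fine grid for driver profiles (design times lie on it)

_TRANSCRIPTION_NAMES = ("k_nunc", "k_int", "k_s1", "k_s2", "k_deg")
_PROTEIN_NAMES = ("k_s", "k_d", "k_tran", "k_ls", "k_sl", "k_sp", "k_ps")
_BRAIN_NAMES = ("k_sb", "k_e")

STAGE_ORDER = ("transcription", "protein", "brain", "isg")


class StageFailure(RuntimeError):
    """A stage failed; carries any results completed before the failure."""

    def __init__(self, stage: str, message: str, completed=None):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.completed = completed


@dataclass
class StageSpec:
    """Which parameters a stage estimates, which it holds fixed, and on
    which responses/molecules it is evaluated."""

    stage: str
    free: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    responses: tuple[str, ...] = ()
    molecules: tuple[str, ...] = ()
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGE_ORDER}")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        if not self.free:
            raise ValueError("a stage must have at least one free parameter")


@dataclass
class FitResult:
    """Outcome of one stage fit."""

    label: str
    stage: str
    molecules: tuple[str, ...]
    estimates: dict[str, float]
    fixed: dict[str, float]
    omega2: dict[str, float]
    mvof: float
    rss_log: float
    n: int
    np_free: int
    aic: float
    converged: bool
    n_eval: int
    se: dict[str, float] | None = None
    cv_percent: dict[str, float] | None = None
    seed: int | None = None
    message: str = ""
    start: dict[str, float] = field(default_factory=dict)
    # non-serialized: objective with omega^2 held at the optimum, for SEs
    _objective: Callable[[np.ndarray], float] | None = field(
        default=None, repr=False, compare=False
    )

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if not k.startswith("_")}
        d["molecules"] = list(self.molecules)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        d["molecules"] = tuple(d.get("molecules", ()))
        return cls(**d)


# ---------------------------------------------------------------------------
# ELS engine


def _els_minimize(
    predict: Callable[[np.ndarray], np.ndarray],
    log_obs: np.ndarray,
    response_groups: dict[str, np.ndarray],
    x0_log: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    max_rounds: int = 6,
    max_nfev_per_round: int | None = None,
):
    """Minimize the profiled ELS objective over log-parameters.

    ``predict`` maps a natural-scale parameter vector to per-observation
    predictions.  ``bounds`` is a (lower, upper) box in log space; it acts
    as a weak prior that stops structurally flat parameter combinations
    from escaping to degenerate regions.
    Returns (x_log_opt, mvof, omega2, rss, converged, n_eval).
    """
    n_eval = 0

    def log_pred(x_log):
        nonlocal n_eval
        n_eval += 1
        x_log = np.asarray(x_log, dtype=float)
        if not np.all(np.isfinite(x_log)):  # trust-region probe gone astray
            return np.full(log_obs.shape, -1e6)
        # clip keeps parameters finite when a step overshoots in log space
        with np.errstate(over="ignore", invalid="ignore", under="ignore"):
            pred = predict(np.exp(np.clip(x_log, -200.0, 200.0)))
        pred = np.asarray(pred, dtype=float)
        if not np.all(np.isfinite(pred)):  # overflowed matrix exponential etc.
            return np.full(log_obs.shape, -1e6)
        return np.log(np.clip(pred, 1e-300, None))

    def raw_residuals(x_log):
        return log_obs - log_pred(x_log)

    def mvof_of(raw):
        total, rss = 0.0, 0.0
        om = {}
        for resp, idx in response_groups.items():
            r = raw[idx]
            w2 = profile_omega2(r)
            om[resp] = w2
            rss += float(np.dot(r, r))
            total += r.size * math.log(w2) + float(np.dot(r, r)) / w2
        return total, om, rss

    x0_log = np.asarray(x0_log, dtype=float)
    if bounds is None:
        lb = np.full_like(x0_log, -np.inf)
        ub = np.full_like(x0_log, np.inf)
    else:
        lb, ub = (np.asarray(b, dtype=float) for b in bounds)

    def weighted_fn(omega2):
        scale = np.empty_like(log_obs)
        for resp, idx in response_groups.items():
            scale[idx] = math.sqrt(omega2[resp])

        def weighted(x_log):
            return raw_residuals(x_log) / scale

        return weighted

    def irls(x_init):
        x = np.clip(np.asarray(x_init, dtype=float), lb, ub)
        omega2 = {resp: 1.0 for resp in response_groups}
        prev_mvof = math.inf
        converged = False
        result = None
        for _ in range(max_rounds):
            result = least_squares(
                weighted_fn(omega2), x, method="trf", bounds=(lb, ub),
                max_nfev=max_nfev_per_round, xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            x = result.x
            raw = raw_residuals(x)
            mvof, omega2, rss = mvof_of(raw)
            if abs(prev_mvof - mvof) < 1e-9 * (abs(mvof) + 1.0):
                converged = bool(result.status > 0)
                break
            prev_mvof = mvof
        else:
            converged = bool(result is not None and result.status > 0)
        # Near-interpolating fits (noise-free data) sit in likelihood
        # valleys whose slope falls below the forward-difference Jacobian
        # noise of the LM pass; one central-difference trust-region pass
        # with a diff step well above the model-evaluation noise floor
        # resolves them.  Skipped when residual noise dominates.
        if float(np.mean(raw * raw)) < 1e-6:
            polish = least_squares(
                weighted_fn(omega2), x, method="trf", jac="3-point",
                bounds=(lb, ub), diff_step=1e-2,
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=1200,
            )
            raw_p = raw_residuals(polish.x)
            mvof_p, omega2_p, rss_p = mvof_of(raw_p)
            if mvof_p <= mvof:
                x, mvof, omega2, rss = polish.x, mvof_p, omega2_p, rss_p
                converged = converged or bool(polish.status > 0)
        return x, mvof, omega2, rss, converged

    solutions = [irls(x0_log)]
    # A poorly informed rate can run away in log space (towards 0 or
    # infinity on the natural scale), where its Jacobian column vanishes
    # and the optimizer freezes.  Retry from the escaped solution with the
    # runaway coordinates pulled back near the start.
    if np.any(np.abs(solutions[0][0] - x0_log) > 3.0):
        solutions.append(irls(np.clip(solutions[0][0], x0_log - 2.0, x0_log + 2.0)))

    def better(a, b):
        """Lower MVOF wins; near-ties resolved by least departure from the
        start (flat directions then stay where the data left them)."""
        if a is None:
            return b
        if b[1] < a[1] - 1e-3:
            return b
        if b[1] < a[1] + 1e-3 and (
            np.linalg.norm(b[0] - x0_log) < np.linalg.norm(a[0] - x0_log)
        ):
            return b
        return a

    best = None
    for sol in solutions:
        best = better(best, sol)
    x, mvof, omega2, rss, converged = best
    return x, mvof, omega2, rss, converged, n_eval


def _finite_diff_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                         rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function at x (natural scale)."""
    p = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-150)  # floor avoids h**2 underflow
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def standard_errors(fit: FitResult) -> tuple[dict[str, float], dict[str, float]]:
    """Asymptotic SEs and CV% from the numerically differentiated Hessian
    of MVOF/2 at the optimum (omega^2 held at its estimate).

    Raises if the fit carries no objective (e.g. deserialized results) or
    if the Hessian is not positive definite (no silent pseudo-inverse).
    """
    if fit._objective is None:
        raise ValueError("fit carries no objective closure; re-run fit_stage")
    names = list(fit.estimates)
    theta = np.array([fit.estimates[n] for n in names])
    H = _finite_diff_hessian(fit._objective, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular Hessian for {fit.label}: {exc}") from exc
    diag = np.diag(cov)
    if np.any(diag <= 0) or np.any(np.linalg.eigvalsh(H) <= 0):
        raise np.linalg.LinAlgError(
            f"Hessian for {fit.label} is not positive definite; SEs unavailable"
        )
    se = {n: float(math.sqrt(d)) for n, d in zip(names, diag)}
    cv = {n: 100.0 * se[n] / abs(fit.estimates[n]) for n in names}
    return se, cv


# ---------------------------------------------------------------------------
# stage predictors


def _row_positions(frame: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    """Position of each observation row's time in the sorted ``times``."""
    return np.searchsorted(times, frame["time_h"].to_numpy())


def _transcription_predictor(frame: pd.DataFrame, free: Sequence[str],
                             fixed: Mapping[str, float], options: Mapping):
    times = np.unique(frame["time_h"].to_numpy())
    pos = _row_positions(frame, times)
    depletes = bool(options.get("conversion_depletes_dna", True))
    x0 = np.array([1.0, 0.0, 0.0]) * float(options.get("dose_scale", 1.0) or 1.0)

    def predict(theta_vec: np.ndarray) -> np.ndarray:
        theta = dict(fixed)
        theta.update(zip(free, theta_vec))
        k_nunc, k_int = theta["k_nunc"], theta["k_int"]
        loss = k_nunc + (k_int if depletes else 0.0)
        A = np.array([
            [-loss, 0.0, 0.0],
            [k_int, -k_int, 0.0],
            [theta["k_s1"], theta["k_s2"], -theta["k_deg"]],
        ])
        mrna = propagate_matrix(A, x0, times)[:, 2]
        return mrna[pos]

    return predict


def _protein_matrix(tr: TranscriptionParams, theta: Mapping[str, float],
                    n_transit: int, peripheral: bool, k_sb: float,
                    k_e: float | None = None) -> np.ndarray:
    """System matrix of the transcription + protein blocks, assembled
    directly from raw rates; a brain row is appended when ``k_e`` is
    given.  States: DNA, DNA', mRNA, T1..Tn, liver, serum[, peripheral]
    [, brain].  Matches :func:`dynamics.kinetic_matrix`."""
    m = 5 + n_transit + (1 if peripheral else 0) + (1 if k_e is not None else 0)
    A = np.zeros((m, m))
    A[:3, :3] = transcription_matrix(tr)
    k_tran = theta.get("k_tran", 1.0)
    for i in range(n_transit):
        A[3 + i, 2 + i] = k_tran
        A[3 + i, 3 + i] = -k_tran
    liv = 3 + n_transit
    ser = liv + 1
    A[liv, liv - 1] += theta["k_s"]
    A[liv, liv] += -(theta["k_d"] + theta["k_ls"])
    A[liv, ser] += theta["k_sl"]
    A[ser, liv] += theta["k_ls"]
    A[ser, ser] += -(theta["k_sl"] + k_sb)
    if peripheral:
        per = ser + 1
        A[ser, ser] += -theta["k_sp"]
        A[ser, per] += theta["k_ps"]
        A[per, ser] += theta["k_sp"]
        A[per, per] += -theta["k_ps"]
    if k_e is not None:
        br = m - 1
        A[br, ser] = k_sb
        A[br, br] = -k_e
    return A


def _protein_predictor(frame: pd.DataFrame, free: Sequence[str],
                       fixed: Mapping[str, float], options: Mapping):
    molecule = frame["molecule"].unique()
    if len(molecule) != 1:
        raise ValueError("the protein stage is fitted per molecule")
    transcription = options["transcription"]
    n_transit = int(options.get("n_transit", 3))
    peripheral = bool(options.get("peripheral", False))
    include_brain = bool(options.get("include_brain", False)) \
        or "protein_brain" in set(frame["response"])
    times = np.unique(frame["time_h"].to_numpy())
    pos = _row_positions(frame, times)
    liv = 3 + n_transit
    ser = liv + 1
    br = ser + (2 if peripheral else 1)
    col = np.select(
        [frame["response"].to_numpy() == "protein_liver",
         frame["response"].to_numpy() == "protein_serum"],
        [liv, ser], default=br,
    )
    m = 5 + n_transit + (1 if peripheral else 0) + (1 if include_brain else 0)
    x0 = np.zeros(m)
    x0[0] = 1.0

    def predict(theta_vec: np.ndarray) -> np.ndarray:
        theta = dict(fixed)
        theta.update(zip(free, theta_vec))
        # brain uptake is negligible for serum mass balance during the
        # staged pass; it enters as an (effectively zero) constant until
        # the joint refinement estimates it from the brain data
        k_sb = float(theta.get("k_sb", 1e-12))
        k_e = float(theta["k_e"]) if include_brain else None
        A = _protein_matrix(transcription, theta, n_transit, peripheral,
                            k_sb, k_e)
        sol = propagate_matrix(A, x0, times)
        return sol[pos, col]

    return predict


def _brain_predictor(frame: pd.DataFrame, free: Sequence[str],
                     fixed: Mapping[str, float], options: Mapping):
    molecule = frame["molecule"].unique()
    if len(molecule) != 1:
        raise ValueError("the brain stage is fitted per molecule")
    molecule = molecule[0]
    grid_t, serum = options["serum_profile"]
    grid_t = np.asarray(grid_t, dtype=float)
    serum = np.asarray(serum, dtype=float)
    obs_t = frame["time_h"].to_numpy()

    def predict(theta_vec: np.ndarray) -> np.ndarray:
        theta = dict(fixed)
        theta.update(zip(free, theta_vec))
        # the brain equation is itself a linear turnover model with the
        # serum profile as driver: dbr/dt = k_sb*serum - k_e*br
        br = turnover_response(
            grid_t, serum, ISGParams(k_s_isg=theta["k_sb"], k_d_isg=theta["k_e"])
        )
        return np.interp(obs_t, grid_t, br)

    return predict


def _isg_predictor(frame: pd.DataFrame, free: Sequence[str],
                   fixed: Mapping[str, float], options: Mapping):
    gene = options["gene"]
    organ = options["organ"]
    mode = options.get("mode", "saturable" if organ == "liver" else "linear")
    shared_synthesis = bool(options.get("shared_synthesis", organ == "liver"))
    drivers = options["drivers"]  # molecule -> (grid_t, protein profile)
    response = f"{gene}_{organ}"
    mols = tuple(frame["molecule"].unique())
    if mode == "saturable" and not any(n in free or n in fixed for n in ("ifn50",)):
        raise ValueError("saturable ISG mode requires an ifn50 parameter")

    frame_t = frame["time_h"].to_numpy()
    row_groups = {mol: np.asarray(idx)
                  for mol, idx in frame.groupby("molecule").indices.items()}
    grids = {mol: (np.asarray(drivers[mol][0], float),
                   np.asarray(drivers[mol][1], float)) for mol in mols}

    def predict(theta_vec: np.ndarray) -> np.ndarray:
        theta = dict(fixed)
        theta.update(zip(free, theta_vec))
        out = np.empty(len(frame))
        for mol in mols:
            ks = theta["k_s_isg"] if shared_synthesis else theta[f"k_s_isg:{mol}"]
            p = ISGParams(
                k_s_isg=ks, k_d_isg=theta["k_d_isg"],
                ifn50=theta["ifn50"] if mode == "saturable" else None,
                isg0=float(theta.get("isg0", 0.0)),
            )
            grid_t, driver = grids[mol]
            series = turnover_response(grid_t, driver, p)
            idx = row_groups[mol]
            out[idx] = np.interp(frame_t[idx], grid_t, series)
        return out

    return predict


_PREDICTORS = {
    "transcription": _transcription_predictor,
    "protein": _protein_predictor,
    "brain": _brain_predictor,
    "isg": _isg_predictor,
}


def _canonicalize_transcription(estimates: dict[str, float],
                                spec: StageSpec) -> dict[str, float]:
    """Resolve the transcription block's exact flip-flop ambiguity.

    With depleting DNA -> DNA' conversion, swapping the fast eigenvalues —
    (k_nunc, k_deg) -> (k_deg - k_int, k_nunc + k_int) — leaves the mRNA
    curve identical at every time, so the likelihood has two exactly tied
    optima.  The canonical labelling takes mRNA turnover faster than total
    DNA loss (k_deg > k_nunc + k_int), matching the reported estimates.
    """
    if not spec.options.get("conversion_depletes_dna", True):
        return estimates
    full = dict(spec.fixed)
    full.update(estimates)
    if not all(n in full for n in ("k_nunc", "k_int", "k_deg")):
        return estimates
    if {"k_nunc", "k_deg"} - set(estimates):
        return estimates  # cannot relabel fixed parameters
    k_nunc, k_int, k_deg = full["k_nunc"], full["k_int"], full["k_deg"]
    if k_deg >= k_nunc + k_int or k_deg - k_int <= 0:
        return estimates
    out = dict(estimates)
    out["k_nunc"] = k_deg - k_int
    out["k_deg"] = k_nunc + k_int
    return out


# ---------------------------------------------------------------------------
# public fitting entry points


def fit_stage(
    dataset: Dataset,
    spec: StageSpec,
    start: Mapping[str, float],
    seed: int | None = None,
    n_starts: int = 5,
    jitter: float = 0.3,
    bound_width: float = 4.0,
    shared_omega2: bool = False,
    label: str | None = None,
) -> FitResult:
    """Fit one stage by profiled extended least squares.

    ``start`` supplies a positive initial value for every free parameter.
    ``n_starts`` runs (``n_starts`` - 1 log-normally jittered copies of the
    start plus the start itself) are minimized and the lowest-MVOF solution
    is kept (near-ties go to the solution nearest the start).  The search
    is confined to ``start`` x/÷ exp(``bound_width``) — a weak prior box
    (~55-fold each way by default) that keeps structurally flat parameter
    combinations from escaping to degenerate regions; estimates at a bound
    are flagged in ``message``.  Observations are restricted to
    ``spec.responses`` and ``spec.molecules`` (when given).
    """
    missing = [r for r in spec.responses if r not in dataset.responses]
    if missing:
        raise ValueError(f"dataset lacks responses required by the stage: {missing}")
    frame = dataset.frame
    if spec.molecules:
        frame = frame[frame["molecule"].isin(spec.molecules)]
    frame = frame[frame["response"].isin(spec.responses)].reset_index(drop=True)
    if len(frame) == 0:
        raise ValueError("no observations match the stage specification")
    missing_start = [n for n in spec.free if n not in start]
    if missing_start:
        raise ValueError(f"start values missing for {missing_start}")
    for n in spec.free:
        if not start[n] > 0:
            raise ValueError(f"start for {n} must be positive")

    predict = _PREDICTORS[spec.stage](frame, spec.free, spec.fixed, spec.options)
    log_obs = np.log(frame["value"].to_numpy())
    if shared_omega2:
        groups = {"shared": np.arange(len(frame))}
    else:
        groups = {r: np.asarray(i) for r, i in frame.groupby("response").indices.items()}

    x0 = np.log([start[n] for n in spec.free])
    lb, ub = x0 - bound_width, x0 + bound_width
    rng = np.random.default_rng(seed)
    starts = [x0] + [
        np.clip(x0 + rng.normal(0.0, jitter, x0.size), lb, ub)
        for _ in range(n_starts - 1)
    ]

    best = None
    total_eval = 0
    for x_start in starts:
        try:
            sol = _els_minimize(predict, log_obs, groups, x_start, bounds=(lb, ub))
        except Exception as exc:  # optimizer blow-up on a bad start
            warnings.warn(f"a start failed for stage {spec.stage}: {exc}",
                          RuntimeWarning, stacklevel=2)
            continue
        total_eval += sol[5]
        if best is None or sol[1] < best[1] - 1e-3 or (
            sol[1] < best[1] + 1e-3
            and np.linalg.norm(sol[0] - x0) < np.linalg.norm(best[0] - x0)
        ):
            best = sol
    if best is None:
        raise StageFailure(spec.stage, "every optimization start failed")
    x_opt, mvof, omega2, rss, converged, _ = best
    at_bound = [n for n, v in zip(spec.free, x_opt)
                if v <= lb[spec.free.index(n)] + 1e-6
                or v >= ub[spec.free.index(n)] - 1e-6]

    estimates = dict(zip(spec.free, np.exp(x_opt)))
    if spec.stage == "transcription":
        estimates = _canonicalize_transcription(estimates, spec)
    n_obs = len(frame)
    np_free = len(spec.free)
    aic = n_obs * math.log(rss / n_obs) + 2 * np_free if rss > 0 else -math.inf

    om_fixed = {r: max(w2, OMEGA2_FLOOR) for r, w2 in omega2.items()}
    scale2 = np.empty(len(frame))
    for r, idx in groups.items():
        scale2[idx] = om_fixed[r]

    def objective(theta_vec: np.ndarray) -> float:
        raw = log_obs - np.log(np.clip(predict(theta_vec), 1e-300, None))
        return 0.5 * float(np.sum(raw * raw / scale2))

    result = FitResult(
        label=label or spec.stage,
        stage=spec.stage,
        molecules=tuple(sorted(frame["molecule"].unique())),
        estimates=estimates,
        fixed=dict(spec.fixed),
        omega2={r: float(w) for r, w in omega2.items()},
        mvof=float(mvof),
        rss_log=float(rss),
        n=n_obs,
        np_free=np_free,
        aic=float(aic),
        converged=bool(converged),
        n_eval=total_eval,
        seed=seed,
        start={n: float(start[n]) for n in spec.free},
        message=(f"parameter(s) at search bound: {at_bound}" if at_bound else ""),
        _objective=objective,
    )
    try:
        result.se, result.cv_percent = standard_errors(result)
    except np.linalg.LinAlgError as exc:
        note = f"standard errors unavailable: {exc}"
        result.message = f"{result.message}; {note}" if result.message else note
    return result


# ---------------------------------------------------------------------------
# sequential procedure


@dataclass
class SequentialConfig:
    """Configuration of the four-stage sequential fit.

    ``variants`` maps each molecule to its structural choices
    (``n_transit``, ``peripheral``); ``isg_models`` maps (gene, organ) to
    ``mode`` ('saturable'/'linear') and ``shared_synthesis``.  ``starts``
    holds per-stage starting values: ``starts['transcription']`` is a flat
    map, ``starts['protein'][molecule]`` / ``starts['brain'][molecule]`` /
    ``starts['isg'][(gene, organ)]`` likewise.
    """

    molecules: tuple[str, ...]
    stages: tuple[str, ...] = STAGE_ORDER
    variants: dict = field(default_factory=dict)
    isg_models: dict = field(default_factory=dict)
    starts: dict = field(default_factory=dict)
    n_starts: int = 5
    jitter: float = 0.3
    bound_width: float = 4.0
    seed: int | None = None
    grid_step: float = DEFAULT_GRID_STEP
    shared_omega2: bool = False
    # One back-substitution pass after the brain stage: the protein stage
    # is refitted with the estimated serum->brain uptake held fixed (it is
    # zero during the first pass), then the brain stage is refitted on the
    # updated serum profile.  Without it, the missing uptake leaks into
    # the hepatic degradation estimate of slowly cleared molecules.
    refine_brain_uptake: bool = True

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stages {bad}")
        order = [STAGE_ORDER.index(s) for s in self.stages]
        if order != sorted(order) or order != list(range(len(order))):
            raise ValueError(
                "stages must form a prefix of "
                "(transcription, protein, brain, isg) in order"
            )

    def variant(self, molecule: str) -> dict:
        v = {"n_transit": 3, "peripheral": False}
        v.update(self.variants.get(molecule, {}))
        return v


@dataclass
class SequentialFit:
    """Ordered results of the sequential procedure."""

    transcription: FitResult | None = None
    protein: dict[str, FitResult] = field(default_factory=dict)
    brain: dict[str, FitResult] = field(default_factory=dict)
    isg: dict[tuple[str, str], FitResult] = field(default_factory=dict)

    def all(self) -> list[FitResult]:
        out = [self.transcription] if self.transcription else []
        out += list(self.protein.values()) + list(self.brain.values())
        out += list(self.isg.values())
        return out

    def parameter_set(self, molecule: str, n_transit: int = 3,
                      peripheral: bool = False) -> KineticParameterSet:
        """Assemble a kinetic parameter set from the fitted stages."""
        if self.transcription is None or molecule not in self.protein:
            raise ValueError("transcription and protein stages are required")
        tr = TranscriptionParams(**{
            n: self.transcription.estimates.get(
                n, self.transcription.fixed.get(n))
            for n in _TRANSCRIPTION_NAMES
        })
        est = dict(self.protein[molecule].fixed)
        est.update(self.protein[molecule].estimates)
        brain_fit = self.brain.get(molecule)
        k_sb = brain_fit.estimates["k_sb"] if brain_fit else 1e-12
        k_e = brain_fit.estimates["k_e"] if brain_fit else 1.0
        per = (PeripheralExchange(est["k_sp"], est["k_ps"]) if peripheral else None)
        protein = HepaticProteinParams(
            k_s=est["k_s"], k_d=est["k_d"], k_tran=est.get("k_tran", 1.0),
            k_ls=est["k_ls"], k_sl=est["k_sl"], k_sb=k_sb,
            n_transit=n_transit, peripheral=per,
        )
        return KineticParameterSet(
            molecule=molecule, transcription=tr, protein=protein,
            brain=BrainParams(k_e=k_e),
        )


def _profile_grid(t_max: float, step: float) -> np.ndarray:
    n = int(round(t_max / step))
    return np.linspace(0.0, n * step, n + 1)


def sequential_fit(dataset: Dataset, config: SequentialConfig) -> SequentialFit:
    """Run the sequential procedure on a dataset.

    Halts with :exc:`StageFailure` (carrying completed results) if any
    stage cannot be fitted.
    """
    rng = np.random.default_rng(config.seed)

    def stage_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    out = SequentialFit()
    t_max = float(dataset.frame["time_h"].max())
    grid = _profile_grid(max(t_max, 1.0), config.grid_step)

    def run(spec: StageSpec, start, label):
        try:
            return fit_stage(
                dataset, spec, start, seed=stage_seed(),
                n_starts=config.n_starts, jitter=config.jitter,
                bound_width=config.bound_width,
                shared_omega2=config.shared_omega2, label=label,
            )
        except StageFailure:
            raise
        except Exception as exc:
            raise StageFailure(spec.stage, str(exc), completed=out) from exc

    stages = config.stages
    if "transcription" in stages:
        start = config.starts.get("transcription")
        if start is None:
            raise StageFailure("transcription", "no starting values configured", out)
        spec = StageSpec(
            stage="transcription", free=_TRANSCRIPTION_NAMES,
            responses=("mRNA_liver",), molecules=config.molecules,
        )
        out.transcription = run(spec, start, "transcription")

    def protein_free(mol: str) -> list[str]:
        v = config.variant(mol)
        free = ["k_s", "k_d", "k_ls", "k_sl"]
        if v["n_transit"] > 0:
            free.insert(2, "k_tran")
        if v["peripheral"]:
            free += ["k_sp", "k_ps"]
        return free

    def fit_protein_stage(mol: str, tr: TranscriptionParams, start) -> FitResult:
        spec = StageSpec(
            stage="protein", free=tuple(protein_free(mol)),
            responses=("protein_liver", "protein_serum"), molecules=(mol,),
            options={"transcription": tr, **config.variant(mol)},
        )
        return run(spec, start, f"protein:{mol}")

    def fit_brain_stage(mol: str, start) -> FitResult:
        v = config.variant(mol)
        params = out.parameter_set(mol, n_transit=v["n_transit"],
                                   peripheral=v["peripheral"])
        serum = dynamics.propagate(params, grid)["serum"]
        spec = StageSpec(
            stage="brain", free=_BRAIN_NAMES,
            responses=("protein_brain",), molecules=(mol,),
            options={"serum_profile": (grid, serum)},
        )
        return run(spec, start, f"brain:{mol}")

    if "protein" in stages:
        if out.transcription is None:
            raise StageFailure("protein", "transcription stage results required", out)
        tr = TranscriptionParams(**{
            n: out.transcription.estimates[n] for n in _TRANSCRIPTION_NAMES
        })
        for mol in config.molecules:
            start = (config.starts.get("protein") or {}).get(mol)
            if start is None:
                raise StageFailure("protein", f"no starting values for {mol}", out)
            out.protein[mol] = fit_protein_stage(mol, tr, start)

    if "brain" in stages:
        if not out.protein:
            raise StageFailure("brain", "protein stage results required", out)
        for mol in config.molecules:
            start = (config.starts.get("brain") or {}).get(mol)
            if start is None:
                raise StageFailure("brain", f"no starting values for {mol}", out)
            out.brain[mol] = fit_brain_stage(mol, start)
        if config.refine_brain_uptake:
            # joint pass over liver+serum+brain: the staged pass holds the
            # serum->brain uptake at zero, which otherwise leaks into the
            # hepatic degradation rate of slowly cleared molecules
            for mol in config.molecules:
                free = tuple(protein_free(mol)) + _BRAIN_NAMES
                start = dict(out.protein[mol].estimates)
                start.update(out.brain[mol].estimates)
                spec = StageSpec(
                    stage="protein", free=free,
                    responses=("protein_liver", "protein_serum", "protein_brain"),
                    molecules=(mol,),
                    options={"transcription": tr, **config.variant(mol),
                             "include_brain": True},
                )
                joint = run(spec, start, f"protein+brain:{mol}")
                out.protein[mol] = joint
                out.brain[mol] = joint

    if "isg" in stages:
        if not out.protein:
            raise StageFailure("isg", "protein stage results required", out)
        isg_responses = [r for r in dataset.responses
                         if r.split("_")[0] in ("ISG15", "OAS")]
        profiles: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for mol in config.molecules:
            v = config.variant(mol)
            params = out.parameter_set(mol, n_transit=v["n_transit"],
                                       peripheral=v["peripheral"])
            traj = dynamics.propagate(params, grid)
            profiles[(mol, "liver")] = (grid, traj["liver"])
            profiles[(mol, "brain")] = (grid, traj["brain"])
        for resp in isg_responses:
            gene, organ = resp.split("_")
            if organ == "brain" and not out.brain:
                raise StageFailure("isg", "brain stage results required for brain ISGs", out)
            model = {"mode": "saturable" if organ == "liver" else "linear",
                     "shared_synthesis": organ == "liver"}
            model.update(config.isg_models.get((gene, organ), {}))
            mols = tuple(m for m in config.molecules
                         if (dataset.frame["molecule"].eq(m)
                             & dataset.frame["response"].eq(resp)).any())
            free = ["k_d_isg"]
            if model["shared_synthesis"]:
                free.insert(0, "k_s_isg")
            else:
                free = [f"k_s_isg:{m}" for m in mols] + free
            if model["mode"] == "saturable":
                free.append("ifn50")
            start = (config.starts.get("isg") or {}).get((gene, organ))
            if start is None:
                raise StageFailure("isg", f"no starting values for {gene}/{organ}", out)
            spec = StageSpec(
                stage="isg", free=tuple(free),
                responses=(resp,), molecules=mols,
                options={"gene": gene, "organ": organ,
                         "drivers": {m: profiles[(m, organ)] for m in mols},
                         **model},
            )
            out.isg[(gene, organ)] = run(spec, start, f"{gene}:{organ}")
    return out
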
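"""Independent oracles used by the tests.

Everything here is written from the model definition directly — explicit
fixed-step Euler integration with hand-coded derivatives, closed-form
solutions of the reduced linear systems, and a direct Gaussian log-density
sum — deliberately not reusing the package's right-hand sides, simulator
or likelihood code.
"""

from __future__ import annotations

import math

import numpy as np


def euler_simulate(
    rates: dict[str, float],
    n_transit: int = 3,
    peripheral: bool = False,
    t_end: float = 48.0,
    dt: float = 1e-3,
    dose: float = 1.0,
    record_times=(),
) -> dict[str, np.ndarray]:
    """Fixed-step explicit Euler integration of the full kinetic system.

    ``rates`` holds k_nunc, k_int, k_s1, k_s2, k_deg, k_s, k_d, k_tran,
    k_ls, k_sl, k_sb, k_e and (if ``peripheral``) k_sp, k_ps.  Returns the
    recorded state at ``record_times`` (grid-snapped).
    """
    r = rates
    n_steps = int(round(t_end / dt))
    record = sorted(set(int(round(t / dt)) for t in record_times))
    rec_iter = iter(record)
    next_rec = next(rec_iter, None)

    dna, dnap, mrna = dose, 0.0, 0.0
    transit = [0.0] * n_transit
    liver = serum = per = brain = 0.0
    out = {k: [] for k in ("t", "mRNA", "liver", "serum", "brain", "peripheral")}

    def snapshot(step):
        out["t"].append(step * dt)
        out["mRNA"].append(mrna)
        out["liver"].append(liver)
        out["serum"].append(serum)
        out["brain"].append(brain)
        out["peripheral"].append(per)

    if next_rec == 0:
        snapshot(0)
        next_rec = next(rec_iter, None)
    for step in range(1, n_steps + 1):
        d_dna = -(r["k_nunc"] + r["k_int"]) * dna
        d_dnap = r["k_int"] * dna - r["k_int"] * dnap
        d_mrna = r["k_s1"] * dna + r["k_s2"] * dnap - r["k_deg"] * mrna
        d_transit = []
        prev = mrna
        for tval in transit:
            d_transit.append(r["k_tran"] * (prev - tval))
            prev = tval
        feed = transit[-1] if n_transit else mrna
        d_liver = (r["k_s"] * feed - r["k_d"] * liver
                   - r["k_ls"] * liver + r["k_sl"] * serum)
        d_serum = r["k_ls"] * liver - r["k_sl"] * serum - r["k_sb"] * serum
        d_per = 0.0
        if peripheral:
            d_serum += -r["k_sp"] * serum + r["k_ps"] * per
            d_per = r["k_sp"] * serum - r["k_ps"] * per
        d_brain = r["k_sb"] * serum - r["k_e"] * brain

        dna += dt * d_dna
        dnap += dt * d_dnap
        mrna += dt * d_mrna
        transit = [tv + dt * dv for tv, dv in zip(transit, d_transit)]
        liver += dt * d_liver
        serum += dt * d_serum
        per += dt * d_per
        brain += dt * d_brain
        if next_rec == step:
            snapshot(step)
            next_rec = next(rec_iter, None)
    return {k: np.asarray(v) for k, v in out.items()}


def cascade_mrna(t, k_nunc: float, k_s1: float, k_deg: float):
    """Closed-form mRNA for the reduced (k_int -> 0) two-exponential cascade:
    mRNA(t) = k_s1/(k_deg - k_nunc) * (exp(-k_nunc t) - exp(-k_deg t))."""
    t = np.asarray(t, dtype=float)
    return k_s1 / (k_deg - k_nunc) * (np.exp(-k_nunc * t) - np.exp(-k_deg * t))


def constant_driver_turnover(t, synthesis: float, k_d: float, isg0: float = 0.0):
    """Closed-form turnover response to a constant synthesis rate:
    ISG(t) = S/k_d (1 - e^{-k_d t}) + isg0 e^{-k_d t}."""
    t = np.asarray(t, dtype=float)
    return synthesis / k_d * (1.0 - np.exp(-k_d * t)) + isg0 * np.exp(-k_d * t)


def one_compartment_steady_state(k_in: float, k_out: float, driver: float) -> float:
    """Steady state of dx/dt = k_in*driver - k_out*x."""
    return k_in * driver / k_out


def gaussian_log_scale_neg2ll(y_obs, y_pred, omega2_by_group, groups) -> float:
    """Direct -2*sum(log N(log y | log pred, omega^2)) minus N*log(2*pi)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    total = 0.0
    for g, idx in groups.items():
        w2 = omega2_by_group[g]
        for j in idx:
            r = math.log(y_obs[j]) - math.log(y_pred[j])
            logpdf = -0.5 * (math.log(2 * math.pi * w2) + r * r / w2)
            total += -2.0 * logpdf
    return total - y_obs.size * math.log(2 * math.pi)
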
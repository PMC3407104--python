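"""Model discrimination: likelihood-ratio tests on MVOF differences for
nested candidates, AIC for non-nested ones, and a precision gate.

A drop in MVOF between nested fits is referred to a chi-squared
distribution with as many degrees of freedom as extra parameters; for one
extra parameter the 5%/1%/0.1% critical drops are 3.84, 6.63 and 10.83.
Non-nested candidates are ranked by AIC = N·ln(RSS/N) + 2·Np computed on
the log-scale residual sum of squares.  A winning model whose parameter
precision is inadequate (any CV% above 100) is demoted in favour of the
next candidate with proper standard errors.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

from scipy.stats import chi2

from .fitting import FitResult

__all__ = [
    "ComparisonResult",
    "lrt_threshold",
    "lrt",
    "aic",
    "select",
    "SIGNIFICANCE_LEVELS",
]

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)
CV_GATE_PERCENT = 100.0


@dataclass
class ComparisonResult:
    """Outcome of a model comparison."""

    candidates: tuple[str, ...]
    selected: str
    dmvof: float | None = None
    delta_aic: float | None = None
    extra_params: int | None = None
    p_value: float | None = None
    significant: dict[float, bool] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.selected not in self.candidates:
            raise ValueError("selected model must be among the candidates")

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["candidates"] = list(self.candidates)
        d["significant"] = {str(k): v for k, v in self.significant.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def report(self) -> str:
        """Human-readable selection summary."""
        lines = [f"candidates: {', '.join(self.candidates)}"]
        if self.dmvof is not None:
            lines.append(
                f"dMVOF = {self.dmvof:.3f} with {self.extra_params} extra "
                f"parameter(s); p = {self.p_value:.3g}"
            )
            for alpha, sig in self.significant.items():
                lines.append(f"  significant at {alpha * 100:g}%: {'yes' if sig else 'no'}")
        if self.delta_aic is not None:
            lines.append(f"delta AIC (best vs runner-up) = {self.delta_aic:.3f}")
        lines.append(f"selected: {self.selected}")
        if self.notes:
            lines.append(f"note: {self.notes}")
        return "\n".join(lines)


def lrt_threshold(alpha: float, df: int = 1) -> float:
    """Critical MVOF drop for significance level alpha and df extra params."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.ppf(1.0 - alpha, df))


def lrt(fit_nested: FitResult, fit_full: FitResult,
        extra_params: int | None = None) -> ComparisonResult:
    """Likelihood-ratio comparison of two nested fits on the same data."""
    if fit_nested.n != fit_full.n:
        raise ValueError(
            f"nested and full fits use different data sizes "
            f"({fit_nested.n} vs {fit_full.n})"
        )
    if extra_params is None:
        extra_params = fit_full.np_free - fit_nested.np_free
    if extra_params < 1:
        raise ValueError("the full model must have at least one extra parameter")
    if fit_full.np_free - fit_nested.np_free != extra_params:
        raise ValueError("extra_params inconsistent with the fits' parameter counts")
    dmvof = fit_nested.mvof - fit_full.mvof
    notes = ""
    if dmvof < 0:
        notes = ("negative dMVOF: the full model fits worse than the nested one; "
                 "suspect optimizer failure and refit")
        warnings.warn(notes, RuntimeWarning, stacklevel=2)
    significant = {
        alpha: dmvof > lrt_threshold(alpha, extra_params)
        for alpha in SIGNIFICANCE_LEVELS
    }
    p = float(chi2.sf(max(dmvof, 0.0), extra_params))
    selected = fit_full.label if significant[0.05] else fit_nested.label
    return ComparisonResult(
        candidates=(fit_nested.label, fit_full.label),
        selected=selected,
        dmvof=float(dmvof),
        extra_params=int(extra_params),
        p_value=p,
        significant=significant,
        notes=notes,
    )


def aic(fit: FitResult) -> float:
    """AIC = N·ln(RSS/N) + 2·Np on the log-scale residual sum of squares."""
    if not fit.rss_log > 0:
        raise ValueError("AIC requires a positive residual sum of squares")
    return fit.n * math.log(fit.rss_log / fit.n) + 2 * fit.np_free


def _cv_adequate(fit: FitResult) -> bool:
    if fit.cv_percent is None:
        return False
    return all(cv <= CV_GATE_PERCENT for cv in fit.cv_percent.values())


def select(candidates: list[FitResult],
           nesting: list[tuple[str, str, int]] | None = None) -> ComparisonResult:
    """Select among candidate fits.

    ``nesting`` lists (nested_label, full_label, extra_params) pairs that
    are resolved by LRT at the 5% level first; whatever remains is ranked
    by AIC.  A winner with any CV% above 100 is demoted in favour of the
    next-ranked candidate with proper standard errors.
    """
    if not candidates:
        raise ValueError("at least one candidate fit is required")
    by_label = {f.label: f for f in candidates}
    if len(by_label) != len(candidates):
        raise ValueError("candidate labels must be unique")
    if len(candidates) == 1:
        only = candidates[0]
        warnings.warn("single candidate supplied; returning it unchanged",
                      UserWarning, stacklevel=2)
        return ComparisonResult(candidates=(only.label,), selected=only.label,
                                notes="single candidate")

    alive = dict(by_label)
    last_lrt: ComparisonResult | None = None
    for nested_label, full_label, extra in nesting or []:
        if nested_label not in alive or full_label not in alive:
            continue
        cmp = lrt(alive[nested_label], alive[full_label], extra)
        last_lrt = cmp
        loser = full_label if cmp.selected == nested_label else nested_label
        del alive[loser]

    ranked = sorted(alive.values(), key=aic)
    winner = ranked[0]
    notes = []
    if not _cv_adequate(winner):
        for alt in ranked[1:]:
            if _cv_adequate(alt):
                notes.append(
                    f"{winner.label} demoted: parameter CV% above "
                    f"{CV_GATE_PERCENT:g}% (or no standard errors); "
                    f"{alt.label} selected with proper standard errors"
                )
                winner = alt
                break
        else:
            notes.append("no candidate has adequate precision; "
                         "keeping the minimum-AIC model")
    delta = aic(ranked[1]) - aic(ranked[0]) if len(ranked) > 1 else None
    return ComparisonResult(
        candidates=tuple(by_label),
        selected=winner.label,
        dmvof=last_lrt.dmvof if last_lrt else None,
        extra_params=last_lrt.extra_params if last_lrt else None,
        p_value=last_lrt.p_value if last_lrt else None,
        significant=last_lrt.significant if last_lrt else {},
        delta_aic=delta,
        notes="; ".join(notes),
    )
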
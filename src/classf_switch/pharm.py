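"""Pharmacology statistics: t/F p-values, one-way ANOVA with Fisher LSD,
net BRET, and concentration-response curve fitting.

Concentration-response models (responses y against dose, with
x = log10(dose)):

    threePL : y = bottom + (top - bottom) / (1 + 10**(logEC50 - x))
    fourPL  : y = bottom + (top - bottom) / (1 + 10**(hill*(logEC50 - x)))
    bell    : y = bottom + rise / (1 + 10**(log_mid_rise - x))
                       - fall / (1 + 10**(log_mid_fall - x))

The bell model is the sum of an ascending and a descending unit-slope
logistic sharing one baseline: responses rise toward bottom+rise around the
first midpoint and fall by ``fall`` around the second, giving the biphasic
shape seen for some agonists.  logEC50 values are base-10 logs of molar
concentration, so a 10-fold potency shift is a change of 1.0.

Fisher's LSD post-hoc p-values are UNADJUSTED pairwise t tests using the
pooled within-group mean square — that is the definition of LSD; no
multiple-comparison correction is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trajectory import TestResult

__all__ = [
    "TestResult",
    "DoseResponseFit",
    "p_from_t",
    "p_from_f",
    "one_way_anova_lsd",
    "net_bret",
    "fit_concentration_response",
    "dose_response_model",
    "MODELS",
]

_P_FLOOR = np.finfo(float).tiny


def format_p(p: float) -> str:
    """Render a p-value; values below 1e-15 print as '<1e-15'."""
    return "<1e-15" if p < 1e-15 else f"{p:.4g}"


def p_from_t(t: float, df: int) -> float:
    """Two-tailed p from a t statistic: p = 2*(1 - CDF_t(|t|; df))."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return max(float(2.0 * stats.t.sf(abs(t), df)), _P_FLOOR)


def p_from_f(F: float, df1: int, df2: int) -> float:
    """Upper-tail p from an F statistic: p = 1 - CDF_F(F; df1, df2)."""
    if df1 < 1 or df2 < 1:
        raise ValueError(f"dfs must be >= 1, got ({df1}, {df2})")
    if F < 0:
        raise ValueError(f"F must be >= 0, got {F}")
    return max(float(stats.f.sf(F, df1, df2)), _P_FLOOR)


def one_way_anova_lsd(groups: dict[str, np.ndarray]) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA plus Fisher LSD pairwise comparisons.

    Returns the omnibus F test (df1 = k-1, df2 = N-k) and a DataFrame of
    unadjusted pairwise LSD tests (group_a, group_b, t, df, p), each t using
    the pooled within-group mean square on N-k df.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2, got {a.size}")
    k = len(arrays)
    values = np.concatenate(list(arrays.values()))
    N = values.size
    grand = values.mean()

    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df1, df2 = k - 1, N - k
    ms_within = ss_within / df2

    if ms_within == 0:
        if ss_between == 0:
            omnibus = TestResult("F", 0.0, (df1, df2), 1.0)
        else:
            raise ValueError("degenerate variance: zero within-group variance with unequal means")
    else:
        F = (ss_between / df1) / ms_within
        omnibus = TestResult("F", float(F), (df1, df2), p_from_f(float(F), df1, df2))

    rows = []
    for ga, gb in itertools.combinations(arrays, 2):
        a, b = arrays[ga], arrays[gb]
        if ms_within == 0:
            t = 0.0 if a.mean() == b.mean() else np.inf
        else:
            se = np.sqrt(ms_within * (1.0 / a.size + 1.0 / b.size))
            t = (a.mean() - b.mean()) / se
        p = _P_FLOOR if np.isinf(t) else p_from_t(float(t), df2)
        rows.append({"group_a": ga, "group_b": gb, "t": float(t), "df": df2, "p": p})
    return omnibus, pd.DataFrame(rows)


def net_bret(ratio_both, ratio_donor_only):
    """Net BRET: ratio of donor+acceptor cells minus donor-only ratio.

    Accepts scalars or arrays (element-wise).
    """
    both = np.asarray(ratio_both, dtype=float)
    donor = np.asarray(ratio_donor_only, dtype=float)
    if not (np.all(np.isfinite(both)) and np.all(np.isfinite(donor))):
        raise ValueError("BRET ratios must be finite")
    out = both - donor
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------- curve fits

def _pow10(e):
    # clip the exponent so extreme optimizer excursions saturate cleanly
    return 10.0 ** np.clip(e, -300.0, 300.0)


def _fourpl(x, bottom, top, logec50, hill):
    return bottom + (top - bottom) / (1.0 + _pow10(hill * (logec50 - x)))


def _threepl(x, bottom, top, logec50):
    return _fourpl(x, bottom, top, logec50, 1.0)


def _bell(x, bottom, rise, fall, log_mid_rise, log_mid_fall):
    asc = rise / (1.0 + _pow10(log_mid_rise - x))
    desc = fall / (1.0 + _pow10(log_mid_fall - x))
    return bottom + asc - desc


MODELS = {
    "threePL": (_threepl, ("bottom", "top", "logEC50")),
    "fourPL": (_fourpl, ("bottom", "top", "logEC50", "hill")),
    "bell": (_bell, ("bottom", "rise", "fall", "log_mid_rise", "log_mid_fall")),
}


def dose_response_model(model: str, doses, params: dict[str, float]) -> np.ndarray:
    """Evaluate a named concentration-response model at the given doses."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    func, names = MODELS[model]
    x = np.log10(np.asarray(doses, dtype=float))
    return func(x, *[params[n] for n in names])


@dataclass
class DoseResponseFit:
    model: str
    params: dict[str, float]
    rss: float
    converged: bool

    @property
    def log_ec50(self) -> float:
        """Primary logEC50 (the ascending midpoint for the bell model)."""
        return self.params.get("logEC50", self.params.get("log_mid_rise"))

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50


def _starts(model: str, x: np.ndarray, y: np.ndarray, n_starts: int):
    lo, hi = x.min(), x.max()
    grid = np.linspace(lo, hi, n_starts)
    bottom0, top0 = float(y.min()), float(y.max())
    if model == "threePL":
        return [(bottom0, top0, g) for g in grid]
    if model == "fourPL":
        return [(bottom0, top0, g, 1.0) for g in grid]
    span = max(top0 - bottom0, 1e-6)
    starts = []
    for m1 in grid:
        for m2 in grid:
            if m1 < m2:
                starts.append((bottom0, span, span, m1, m2))
    return starts or [(bottom0, span, span, lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3)]


def fit_concentration_response(
    doses, responses, model: str = "fourPL", n_starts: int = 5
) -> DoseResponseFit:
    """Least-squares concentration-response fit with multi-start
    initialization (grid of logEC50 starts spanning the dose range, to avoid
    local minima).  Non-convergence is flagged on the result rather than
    raised; too few distinct doses for the parameter count is an error.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    func, names = MODELS[model]
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if len(np.unique(doses)) < len(names):
        raise ValueError(
            f"{model} has {len(names)} parameters but only "
            f"{len(np.unique(doses))} distinct doses supplied"
        )
    x = np.log10(doses)

    import warnings

    best_popt, best_rss = None, np.inf
    for p0 in _starts(model, x, y, n_starts):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(func, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(((func(x, *popt) - y) ** 2).sum())
        if np.isfinite(rss) and rss < best_rss:
            best_popt, best_rss = popt, rss
    if best_popt is None:
        fallback = _starts(model, x, y, n_starts)[0]
        return DoseResponseFit(model, dict(zip(names, fallback)), np.inf, False)
    return DoseResponseFit(model, dict(zip(names, map(float, best_popt))), best_rss, True)
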
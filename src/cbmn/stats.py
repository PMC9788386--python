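"""Group-level genotoxicity statistics.

One-way ANOVA with Dunnett's many-to-one post-hoc comparisons against the
control group (adjusted p-values from the equicorrelated multivariate-t
distribution), significance stars at alpha = 0.05 / 0.01 / 0.001, per-group
mean +/- SEM summaries, and a four-parameter logistic (4PL) dose-response
fit on log10 concentration with the IC50 at the curve midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import PlateLayout

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class StatisticalError(ValueError):
    """Degenerate input for a statistical procedure."""


def stars(p: float) -> str:
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return ""


@dataclass(frozen=True)
class Comparison:
    group: str
    mean_diff: float
    statistic: float
    p_unadjusted: float  # marginal t-test p with the pooled SD / df
    p_adjusted: float
    stars: str


@dataclass
class StatResult:
    endpoint: str
    f_statistic: float
    p_overall: float
    comparisons: list[Comparison] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "endpoint": self.endpoint, "group": c.group,
            "mean_diff": c.mean_diff, "statistic": c.statistic,
            "p_unadjusted": c.p_unadjusted, "p_adjusted": c.p_adjusted,
            "stars": c.stars, "f_statistic": self.f_statistic,
            "p_overall": self.p_overall,
        } for c in self.comparisons])


def dunnett_test(groups: dict[str, np.ndarray], control: str,
                 endpoint: str = "") -> StatResult:
    """One-way ANOVA + Dunnett many-to-one comparisons versus ``control``.

    Adjusted p-values integrate the joint multivariate-t distribution of the
    comparison statistics, so the family-wise error rate is controlled at the
    nominal level without the conservatism of Bonferroni.  Deterministic for
    fixed inputs.
    """
    if control not in groups:
        raise StatisticalError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise StatisticalError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise StatisticalError(f"group {k!r} needs n >= 2")
    if all(np.var(v) == 0 for v in arrays.values()):
        raise StatisticalError("all groups have zero variance")

    names = [k for k in arrays if k != control]
    ctrl = arrays[control]
    f_stat, p_overall = stats.f_oneway(*arrays.values())
    res = stats.dunnett(*[arrays[k] for k in names], control=ctrl,
                        rng=np.random.default_rng(0))
    df = sum(v.size for v in arrays.values()) - len(arrays)
    comps = []
    for k, t, p in zip(names, np.atleast_1d(res.statistic),
                       np.atleast_1d(res.pvalue)):
        p_unadj = 2.0 * stats.t.sf(abs(float(t)), df)
        comps.append(Comparison(
            group=k, mean_diff=float(arrays[k].mean() - ctrl.mean()),
            statistic=float(t), p_unadjusted=float(p_unadj),
            p_adjusted=float(p), stars=stars(float(p))))
    return StatResult(endpoint=endpoint, f_statistic=float(f_stat),
                      p_overall=float(p_overall), comparisons=comps)


@dataclass
class DoseResponseFit:
    """4PL fit: response = bottom + (top-bottom)/(1 + 10^(hill*(logc - logIC50)))."""

    bottom: float
    top: float
    hill: float
    ic50: float
    rss: float
    converged: bool

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        x = np.log10(np.asarray(concentrations, dtype=np.float64))
        return _four_pl(x, self.bottom, self.top, self.hill,
                        math.log10(self.ic50))


def _four_pl(logc, bottom, top, hill, log_ic50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_4pl(concentrations, responses, zero_floor: float | None = None,
            ) -> DoseResponseFit:
    """Least-squares four-parameter logistic fit on log10 concentration.

    A zero dose is mapped to ``zero_floor`` (default one decade below the
    lowest nonzero concentration).  Multi-start initialisation over hill sign
    and IC50 quantiles; the IC50 is the concentration at the curve midpoint
    (top+bottom)/2.  Non-informative data never raise — the convergence flag
    is set false instead.
    """
    conc = np.asarray(concentrations, dtype=np.float64)
    resp = np.asarray(responses, dtype=np.float64)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValueError("concentrations and responses must be 1-D and equal length")
    if np.unique(conc).size < 5:
        raise ValueError("need >= 5 distinct concentrations")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    nonzero = conc[conc > 0]
    if nonzero.size == 0:
        raise ValueError("all concentrations are zero")
    floor = zero_floor if zero_floor is not None else float(nonzero.min()) / 10.0
    x = np.log10(np.where(conc > 0, conc, floor))

    spread = float(resp.max() - resp.min())
    if spread == 0 or not np.isfinite(spread):
        return DoseResponseFit(bottom=float(resp.mean()), top=float(resp.mean()),
                               hill=0.0, ic50=float(10 ** np.median(x)),
                               rss=0.0, converged=False)

    def residuals(theta):
        bottom, top, hill, log_ic50 = theta
        return _four_pl(x, bottom, top, hill, log_ic50) - resp

    best = None
    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    for hill0 in (1.0, -1.0, 2.0, -2.0):
        for lic0 in (q25, q50, q75):
            theta0 = np.array([resp.min(), resp.max(), hill0, lic0])
            try:
                sol = optimize.least_squares(residuals, theta0, method="lm",
                                             max_nfev=2000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return DoseResponseFit(float("nan"), float("nan"), 0.0, float("nan"),
                               float("nan"), converged=False)
    bottom, top, hill, log_ic50 = best.x
    if bottom > top:  # canonical orientation: bottom <= top
        bottom, top = top, bottom
        hill = -hill
    rss = float(2.0 * best.cost)
    # informative fit: real span and finite midpoint inside a sane range
    converged = bool(best.success and np.isfinite(best.x).all()
                     and (top - bottom) > 0.05 * spread
                     and abs(log_ic50) < 12)
    return DoseResponseFit(bottom=float(bottom), top=float(top),
                           hill=float(hill), ic50=float(10.0 ** log_ic50),
                           rss=rss, converged=converged)


def summarize_endpoints(results: pd.DataFrame, layout: PlateLayout,
                        endpoints: list[str] | None = None) -> pd.DataFrame:
    """Per-group mean and SEM for each endpoint column.

    SEM = sd / sqrt(n) over replicate wells; n = 1 rows get NaN SEM and an
    ``n1`` flag.  Row order is deterministic (layout group order).
    """
    endpoints = endpoints or ["cbpi", "pct_bnc", "mn_per_1000_bnc",
                              "n_mono", "n_bi", "n_multi"]
    endpoints = [e for e in endpoints if e in results.columns]
    if results.empty:
        raise StatisticalError("empty results table")
    rows = []
    for group in layout.groups():
        sub = results[results["group"] == group]
        if sub.empty:
            continue
        for ep in endpoints:
            vals = sub[ep].to_numpy(dtype=np.float64)
            n = vals.size
            sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            rows.append({"group": group, "endpoint": ep, "n": n,
                         "mean": float(vals.mean()), "sem": sem,
                         "flag": "" if n > 1 else "n1"})
    return pd.DataFrame(rows, columns=["group", "endpoint", "n", "mean",
                                       "sem", "flag"])


def endpoint_anova(results: pd.DataFrame, layout: PlateLayout, control: str,
                   endpoints: list[str] | None = None) -> pd.DataFrame:
    """Dunnett tables for every endpoint, concatenated into one frame."""
    endpoints = endpoints or ["cbpi", "pct_bnc", "mn_per_1000_bnc"]
    frames = []
    for ep in endpoints:
        if ep not in results.columns:
            continue
        groups = {g: results.loc[results["group"] == g, ep].to_numpy()
                  for g in layout.groups()}
        groups = {g: v for g, v in groups.items() if v.size >= 2}
        if control not in groups or len(groups) < 2:
            continue
        try:
            frames.append(dunnett_test(groups, control, endpoint=ep).to_frame())
        except StatisticalError:
            continue
    if not frames:
        return pd.DataFrame(columns=["endpoint", "group", "mean_diff",
                                     "p_adjusted", "stars", "f_statistic",
                                     "p_overall"])
    return pd.concat(frames, ignore_index=True)
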
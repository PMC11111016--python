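"""Label-incorporation time-course fitting and group comparison.

Under step labeling, a metabolite pool at steady state incorporates tracer
with first-order kinetics, y(t) = y_inf * (1 - exp(-k t)), whose half-time
is t1/2 = ln 2 / k.  Two empirical sigmoid families are offered for curves
with lag phases (upstream pools delay the label front): a three-parameter
sigmoid a / (1 + exp(-(t - t0)/b)) and the four-parameter logistic
d + (a - d) / (1 + (t/c)^b).  When no model is named, the lowest AICc wins.

Treatment groups are compared per timepoint with a two-sided equal-variance
Student's t test, without multiplicity correction by default (a Holm
adjustment is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

__all__ = [
    "TimeSeries",
    "KineticFit",
    "fit_first_order",
    "fit_sigmoid3",
    "fit_logistic4",
    "fit_best",
    "compare_timepoints",
]

MAX_EVALS = 10_000
FIT_TOL = 1e-8


@dataclass
class TimeSeries:
    """Replicated observations of one quantity over time."""

    time: np.ndarray  # minutes
    value: np.ndarray  # concentration (ng/g FW) or label fraction
    replicate: np.ndarray | None = None
    group: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value arrays differ in length")
        if np.any(self.time < 0):
            raise ValueError("times must be >= 0")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.time.shape:
                raise ValueError("replicate ids must match data length")

    @property
    def n_distinct_times(self) -> int:
        return np.unique(self.time).size


@dataclass
class KineticFit:
    """Converged (or flagged) fit of one kinetic model."""

    model: str
    converged: bool
    params: dict[str, float] = field(default_factory=dict)
    stderr: dict[str, float] = field(default_factory=dict)
    rss: float = np.nan
    aicc: float = np.nan
    half_time: float | None = None  # min; ln2/k for first_order
    message: str = ""

    def predict(self, t: np.ndarray) -> np.ndarray:
        if not self.converged:
            raise ValueError(f"cannot predict from unconverged fit: {self.message}")
        t = np.asarray(t, dtype=float)
        return _MODEL_FUNCS[self.model](t, **self.params)


def _first_order(t, y_inf, k):
    return y_inf * (1.0 - np.exp(-k * t))


def _sigmoid3(t, a, t0, b):
    return a / (1.0 + np.exp(-(t - t0) / b))


def _logistic4(t, a, b, c, d):
    with np.errstate(divide="ignore"):
        ratio = np.where(t > 0, (t / c) ** b, np.inf if b < 0 else 0.0)
    return d + (a - d) / (1.0 + ratio)


_MODEL_FUNCS = {"first_order": _first_order, "sigmoid3": _sigmoid3, "logistic4": _logistic4}


def _aicc(n: int, n_par: int, rss: float) -> float:
    if rss <= 0:
        rss = np.finfo(float).tiny
    aic = n * np.log(rss / n) + 2 * n_par
    denom = n - n_par - 1
    return aic + (2 * n_par * (n_par + 1) / denom if denom > 0 else np.inf)


def _finish(result, model_name: str, n: int) -> KineticFit:
    params = {p: float(result.params[p].value) for p in result.params}
    stderr = {
        p: float(result.params[p].stderr) if result.params[p].stderr is not None else np.nan
        for p in result.params
    }
    rss = float(np.sum(result.residual**2))
    fit = KineticFit(
        model=model_name,
        converged=bool(result.success),
        params=params,
        stderr=stderr,
        rss=rss,
        aicc=_aicc(n, len(params), rss),
        message=result.message or "",
    )
    if model_name == "first_order" and fit.converged:
        k = params["k"]
        fit.half_time = float(np.log(2.0) / k) if k > 0 else None
    return fit


def _flagged(model_name: str, msg: str) -> KineticFit:
    return KineticFit(model=model_name, converged=False, message=msg)


def fit_first_order(ts: TimeSeries) -> KineticFit:
    """Fit y(t) = y_inf (1 - e^(-k t)) with k >= 0.

    y_inf starts at max(y); k from a log-linear regression of
    log(1 - y/y_inf) on t.  A series indistinguishable from zero is flagged
    as unidentifiable rather than fitted.
    """
    if ts.n_distinct_times < 3:
        raise ValueError("need >= 3 distinct timepoints")
    t, y = ts.time, ts.value
    ymax = float(np.max(np.abs(y)))
    if ymax == 0:
        return _flagged("first_order", "series identically zero: k unidentifiable")
    y_inf0 = float(np.max(y))
    if y_inf0 <= 0:
        return _flagged("first_order", "no positive plateau: model inapplicable")
    # log-linear initial k on interior points
    frac = 1.0 - y / (1.0001 * y_inf0)
    mask = (frac > 1e-12) & (t > 0)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(frac[mask]), 1)[0]
        k0 = max(-float(slope), 1e-6)
    else:
        k0 = 1.0 / max(float(np.median(t[t > 0])) if np.any(t > 0) else 1.0, 1e-6)
    model = Model(_first_order)
    pars = model.make_params(y_inf=y_inf0, k=k0)
    pars["k"].set(min=0.0)
    result = model.fit(
        y, pars, t=t, max_nfev=MAX_EVALS, fit_kws={"xtol": FIT_TOL, "ftol": FIT_TOL}
    )
    return _finish(result, "first_order", t.size)


def fit_sigmoid3(ts: TimeSeries) -> KineticFit:
    """Fit the three-parameter sigmoid a / (1 + e^(-(t - t0)/b)).

    b < 0 is permitted and denotes a monotone-decreasing curve.
    """
    if ts.n_distinct_times < 4:
        raise ValueError("need >= 4 distinct timepoints")
    t, y = ts.time, ts.value
    span = float(np.max(y) - np.min(y))
    if span == 0:
        return _flagged("sigmoid3", "constant series: sigmoid unidentifiable")
    a0 = float(np.max(y))
    t00 = float(np.median(t))
    b0 = max((float(np.max(t)) - float(np.min(t))) / 8.0, 1e-6)
    if y[np.argsort(t)][-1] < y[np.argsort(t)][0]:
        b0 = -b0
    model = Model(_sigmoid3)
    pars = model.make_params(a=a0, t0=t00, b=b0)
    result = model.fit(
        y, pars, t=t, max_nfev=MAX_EVALS, fit_kws={"xtol": FIT_TOL, "ftol": FIT_TOL}
    )
    return _finish(result, "sigmoid3", t.size)


def fit_logistic4(ts: TimeSeries) -> KineticFit:
    """Fit the four-parameter logistic d + (a - d)/(1 + (t/c)^b), c > 0."""
    if ts.n_distinct_times < 5:
        raise ValueError("need >= 5 distinct timepoints")
    t, y = ts.time, ts.value
    span = float(np.max(y) - np.min(y))
    if span == 0:
        return _flagged("logistic4", "constant series: slope unidentifiable")
    order = np.argsort(t)
    a0 = float(np.mean(y[order][: max(1, t.size // 4)]))  # early asymptote
    d0 = float(np.mean(y[order][-max(1, t.size // 4):]))  # late asymptote
    positive_t = t[t > 0]
    c0 = float(np.median(positive_t)) if positive_t.size else 1.0
    model = Model(_logistic4)
    pars = model.make_params(a=a0, b=1.0, c=max(c0, 1e-6), d=d0)
    pars["c"].set(min=1e-12)
    result = model.fit(
        y, pars, t=t, max_nfev=MAX_EVALS, fit_kws={"xtol": FIT_TOL, "ftol": FIT_TOL}
    )
    return _finish(result, "logistic4", t.size)


_FITTERS = {
    "first_order": fit_first_order,
    "sigmoid3": fit_sigmoid3,
    "logistic4": fit_logistic4,
}


def fit_best(ts: TimeSeries, models: tuple[str, ...] = ("first_order", "sigmoid3", "logistic4")) -> KineticFit:
    """Fit the named models and return the converged one with lowest AICc."""
    fits = []
    for name in models:
        try:
            fits.append(_FITTERS[name](ts))
        except ValueError:
            continue
    converged = [f for f in fits if f.converged]
    if not converged:
        return fits[0] if fits else _flagged("first_order", "no model applicable")
    return min(converged, key=lambda f: f.aicc)


def plot_timecourse(ts: TimeSeries, fit: KineticFit | None, path) -> None:
    """Export a time-course scatter with the fitted curve overlaid (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ts.time, ts.value, "o", alpha=0.7, label=ts.group or "data")
    if fit is not None and fit.converged:
        grid = np.linspace(float(np.min(ts.time)), float(np.max(ts.time)), 200)
        ax.plot(grid, fit.predict(grid), "-", label=fit.model)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (ng/g FW)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def compare_timepoints(
    group_a: TimeSeries,
    group_b: TimeSeries,
    welch: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """Two-sided Student's t test (equal variances) at each shared timepoint.

    Timepoints with fewer than two replicates in either group are skipped
    with a note.  ``welch=True`` drops the equal-variance assumption;
    ``holm=True`` applies a Holm step-down adjustment across timepoints.
    """
    times = np.intersect1d(np.unique(group_a.time), np.unique(group_b.time))
    rows = []
    for tp in times:
        a = group_a.value[group_a.time == tp]
        b = group_b.value[group_b.time == tp]
        if a.size < 2 or b.size < 2:
            rows.append(
                {"time": tp, "n_a": a.size, "n_b": b.size, "t": np.nan,
                 "p": np.nan, "note": "skipped: <2 replicates"}
            )
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            # degenerate noise-free groups: equal means are indistinguishable,
            # unequal means are separated with certainty
            same = np.mean(a) == np.mean(b)
            t_stat = 0.0 if same else np.inf * np.sign(np.mean(a) - np.mean(b))
            p = 1.0 if same else 0.0
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {"time": tp, "n_a": a.size, "n_b": b.size, "t": float(t_stat),
             "p": float(p), "note": ""}
        )
    out = pd.DataFrame(rows, columns=["time", "n_a", "n_b", "t", "p", "note"])
    if holm and len(out):
        tested = out["p"].notna()
        p = out.loc[tested, "p"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        out.loc[tested, "p_holm"] = adj
    return out
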
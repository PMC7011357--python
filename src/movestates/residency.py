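"""Range-residency diagnosis from empirical semi-variance functions.

A range-resident animal's positional semi-variance asymptotes at long time
lags (the track "fills" a home range); a dispersing or drifting animal's
semi-variance keeps growing.  The paper-style visual variogram inspection is
replaced here by an explicit, parameterized heuristic that always returns
the underlying variogram so a human can override the call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["Variogram", "empirical_svf", "classify_residency", "residency_changepoint"]


@dataclass
class Variogram:
    lag_h: np.ndarray
    svf_km2: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_h": self.lag_h, "svf_km2": self.svf_km2, "n_pairs": self.n_pairs}
        )


def empirical_svf(fixes: pd.DataFrame, lag_bins: np.ndarray) -> Variogram:
    """Empirical semi-variance of position as a function of time lag.

    svf(tau) = (1/2) * mean over pairs with |dt| in the bin of
    ||x(t+dt) - x(t)||^2.  `lag_bins` are bin edges in hours; empty bins get
    count 0 and NaN semi-variance.
    """
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes")
    t = pd.to_datetime(fixes["t"]).to_numpy()
    th = (t - t[0]) / np.timedelta64(1, "h")
    x = fixes["x_km"].to_numpy(dtype=float)
    y = fixes["y_km"].to_numpy(dtype=float)
    dt = np.abs(th[:, None] - th[None, :])
    d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
    iu = np.triu_indices(len(th), k=1)
    dt = dt[iu]
    d2 = d2[iu]
    edges = np.asarray(lag_bins, dtype=float)
    idx = np.digitize(dt, edges) - 1
    nb = len(edges) - 1
    svf = np.full(nb, np.nan)
    cnt = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = idx == b
        cnt[b] = sel.sum()
        if cnt[b]:
            svf[b] = 0.5 * d2[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Variogram(lag_h=centers, svf_km2=svf, n_pairs=cnt)


def classify_residency(
    vg: Variogram,
    stability_fraction: float = 0.15,
    window: float = 0.25,
    alpha: float = 0.05,
    min_pairs: int = 30,
) -> dict:
    """Classify a track as resident / non_resident / indeterminate.

    Resident iff, over the final `window` fraction of populated lags, (a)
    the slope of svf vs lag is flat — statistically indistinguishable from
    zero at level `alpha`, or practically negligible (projected relative
    change over the window below `stability_fraction`; with tens of
    thousands of pairs per bin a biologically irrelevant slope is easily
    "significant") — and (b) the late-lag svf plateaus within
    `stability_fraction` of the variogram maximum.  Too few long-lag pairs
    yields 'indeterminate', never a silent 'resident'.
    """
    ok = vg.n_pairs > 0
    lag = vg.lag_h[ok]
    svf = vg.svf_km2[ok]
    cnt = vg.n_pairs[ok]
    if len(lag) < 4:
        return {"classification": "indeterminate", "reason": "too few populated lags"}
    k = max(3, int(np.ceil(window * len(lag))))
    llag, lsvf, lcnt = lag[-k:], svf[-k:], cnt[-k:]
    if lcnt.sum() < min_pairs:
        return {"classification": "indeterminate", "reason": "too few long-lag pairs"}
    vmax = np.nanmax(svf)
    if vmax < 1e-12:  # stationary point: degenerate asymptote at 0
        return {
            "classification": "resident",
            "slope": 0.0,
            "slope_p": 1.0,
            "plateau_ratio": 1.0,
            "late_mean_km2": 0.0,
        }
    res = stats.linregress(llag, lsvf)
    slope_p = res.pvalue if np.isfinite(res.pvalue) else 1.0
    late_mean = float(np.average(lsvf, weights=lcnt))
    plateau_ratio = late_mean / vmax
    rel_change = res.slope * (llag[-1] - llag[0]) / late_mean if late_mean > 0 else 0.0
    flat = (slope_p > alpha) or (abs(rel_change) <= stability_fraction)
    plateaued = plateau_ratio >= 1.0 - stability_fraction
    return {
        "classification": "resident" if (flat and plateaued) else "non_resident",
        "slope": float(res.slope),
        "slope_p": float(slope_p),
        "relative_change": float(rel_change),
        "plateau_ratio": float(plateau_ratio),
        "late_mean_km2": late_mean,
    }


def residency_changepoint(
    fixes: pd.DataFrame,
    window_days: float = 45.0,
    step_days: float = 15.0,
    n_bins: int = 20,
    **classify_kwargs,
) -> dict:
    """Detect a resident -> non_resident stage switch by classifying sliding
    windows; the change point is the start of the first persistent flip
    (all subsequent windows agreeing with the new label)."""
    t = pd.to_datetime(fixes["t"]).reset_index(drop=True)
    t0, t1 = t.iloc[0], t.iloc[-1]
    labels = []
    starts = []
    w = pd.Timedelta(days=window_days)
    cur = t0
    while cur + w <= t1 + pd.Timedelta(days=step_days):
        sub = fixes[(t >= cur) & (t < cur + w)]
        if len(sub) >= 20:
            span_h = (pd.to_datetime(sub["t"]).iloc[-1] - pd.to_datetime(sub["t"]).iloc[0]) / pd.Timedelta(hours=1)
            # long lags within a window are pair-starved; stop at half span
            bins = np.linspace(0, max(span_h / 2, 1.0), n_bins + 1)
            cl = classify_residency(empirical_svf(sub, bins), **classify_kwargs)
            labels.append(cl["classification"])
            starts.append(cur)
        cur += pd.Timedelta(days=step_days)
    change = None
    for k in range(1, len(labels)):
        if labels[k] != labels[0] and labels[k] != "indeterminate":
            tail = [l for l in labels[k:] if l != "indeterminate"]
            if tail and all(l == labels[k] for l in tail):
                change = starts[k]
                break
    return {"window_labels": labels, "window_starts": starts, "changepoint": change}
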
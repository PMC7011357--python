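"""Kill-cluster detection and caching-phase machinery.

A GPS cluster is a run of consecutive fixes that stay within a fixed radius
(default 200 m) of their running centroid and whose time span covers at
least one complete overnight window (18:00 -> 06:00).  Clusters around
field-confirmed kill remains define the caching phase; the hunger covariate
is days elapsed since the end of the most recent feeding event on
medium-sized prey.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Cluster",
    "detect_clusters",
    "classify_clusters",
    "label_caching_phase",
    "hunger_covariate",
    "detect_excursions",
    "cluster_dwell_time",
    "cluster_report",
]

DEFAULT_RADIUS_M = 200.0
NIGHT_WINDOW = (18, 6)  # 18:00 to 06:00 the next day
MEDIUM_PREY = ("wild_ungulate", "domestic")


@dataclass
class Cluster:
    centroid: tuple[float, float]  # km
    members: np.ndarray  # integer indices into the fix table
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    classification: str = "unvisited"


MIN_NIGHT_H = 9.0


def _covers_full_night(
    t_start, t_end, track_span=None, night=NIGHT_WINDOW, min_night_h=MIN_NIGHT_H
) -> bool:
    """True if [t_start, t_end] contains a complete 18:00 -> 06:00 window.

    The window is clipped to the track's observed extent so that a track
    ending shortly before 06:00 can still satisfy the rule, provided at
    least `min_night_h` hours of the night are observed and covered.
    """
    ev_h, morn_h = night
    lo, hi = track_span if track_span is not None else (t_start, t_end)
    day = t_start.normalize() - pd.Timedelta(days=1)
    last = t_end.normalize() + pd.Timedelta(days=1)
    while day <= last:
        ws = max(day + pd.Timedelta(hours=ev_h), lo)
        we = min(day + pd.Timedelta(days=1, hours=morn_h), hi)
        if (
            (we - ws) / pd.Timedelta(hours=1) >= min_night_h
            and t_start <= ws
            and t_end >= we
        ):
            return True
        day += pd.Timedelta(days=1)
    return False


def detect_clusters(
    fixes: pd.DataFrame,
    radius_m: float = DEFAULT_RADIUS_M,
    night: tuple[int, int] = NIGHT_WINDOW,
) -> list[Cluster]:
    """Find GPS clusters by the overnight rule.

    Greedy running-centroid construction: starting from each unconsumed fix,
    subsequent fixes join while they stay within `radius_m` of the current
    centroid (centroid updated as members join).  A candidate run becomes a
    cluster when its time span covers at least one complete overnight
    window.  Overlapping qualifying runs are merged (ties broken toward the
    earlier site because construction scans forward in time).
    """
    t = pd.to_datetime(fixes["t"]).reset_index(drop=True)
    x = fixes["x_km"].to_numpy(dtype=float)
    y = fixes["y_km"].to_numpy(dtype=float)
    n = len(fixes)
    r_km = radius_m / 1000.0
    clusters: list[Cluster] = []
    track_span = (t.iloc[0], t.iloc[-1]) if n else None
    i = 0
    while i < n - 1:
        cx, cy = x[i], y[i]
        members = [i]
        j = i + 1
        while j < n:
            if np.hypot(x[j] - cx, y[j] - cy) <= r_km:
                members.append(j)
                cx = np.mean(x[members])
                cy = np.mean(y[members])
                j += 1
            else:
                break
        if len(members) > 1 and _covers_full_night(
            t[members[0]], t[members[-1]], track_span, night
        ):
            clusters.append(
                Cluster(
                    centroid=(float(cx), float(cy)),
                    members=np.array(members),
                    t_start=t[members[0]],
                    t_end=t[members[-1]],
                )
            )
            i = j
        else:
            i += 1
    return _merge_overlapping(clusters, x, y, t, r_km)


def _merge_overlapping(clusters, x, y, t, r_km):
    merged: list[Cluster] = []
    for cl in clusters:
        if merged:
            prev = merged[-1]
            d = np.hypot(cl.centroid[0] - prev.centroid[0], cl.centroid[1] - prev.centroid[1])
            if d <= r_km and cl.t_start <= prev.t_end + pd.Timedelta(hours=3):
                members = np.union1d(prev.members, cl.members)
                merged[-1] = Cluster(
                    centroid=(float(np.mean(x[members])), float(np.mean(y[members]))),
                    members=members,
                    t_start=min(prev.t_start, cl.t_start),
                    t_end=max(prev.t_end, cl.t_end),
                    classification=prev.classification,
                )
                continue
        merged.append(cl)
    return merged


def classify_clusters(
    clusters: list[Cluster], kill_sites: pd.DataFrame | None, radius_m: float = DEFAULT_RADIUS_M
) -> list[Cluster]:
    """Label clusters as caching_site (centroid within radius of confirmed
    kill remains) or bed_site; without a kill table they stay unvisited."""
    if kill_sites is None:
        return clusters
    r_km = radius_m / 1000.0
    for cl in clusters:
        d = np.hypot(
            kill_sites["x_km"].to_numpy(dtype=float) - cl.centroid[0],
            kill_sites["y_km"].to_numpy(dtype=float) - cl.centroid[1],
        )
        cl.classification = "caching_site" if (d <= r_km).any() else "bed_site"
    return clusters


def label_caching_phase(
    fixes: pd.DataFrame, kill_sites: pd.DataFrame, radius_m: float = DEFAULT_RADIUS_M
) -> np.ndarray:
    """Phase label per fix: 'caching' iff within `radius_m` of a non-small
    kill site during that site's feeding span, else 'general'.

    Labels are temporally gated to the feeding span so that later revisits
    of an old kill site do not contaminate the caching budget.
    """
    t = pd.to_datetime(fixes["t"]).to_numpy()
    x = fixes["x_km"].to_numpy(dtype=float)
    y = fixes["y_km"].to_numpy(dtype=float)
    labels = np.array(["general"] * len(fixes), dtype=object)
    r_km = radius_m / 1000.0
    for _, site in kill_sites.iterrows():
        if site.get("prey_category", "wild_ungulate") not in MEDIUM_PREY:
            continue
        t0, t1 = site["t_first"], site["t_last"]
        if pd.isna(t0) or pd.isna(t1):
            raise ValueError(f"kill site {site.get('site_id', '?')} has no feeding span")
        near = np.hypot(x - site["x_km"], y - site["y_km"]) <= r_km
        during = (t >= np.datetime64(pd.Timestamp(t0))) & (t <= np.datetime64(pd.Timestamp(t1)))
        labels[near & during] = "caching"
    return labels


def hunger_covariate(
    fix_times, feeding_events: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Days since the end of the last feeding event, per fix.

    Feeding events (columns t_first, t_last, optional prey_category) are
    restricted to medium-sized prey.  The value is clamped to 0 during a
    feeding span.  Fixes before the first event are left-censored: they get
    the per-animal median of the observed values and are flagged in the
    returned boolean mask.
    """
    t = pd.to_datetime(pd.Series(fix_times)).to_numpy()
    ev = feeding_events
    if "prey_category" in ev:
        ev = ev[ev["prey_category"].isin(MEDIUM_PREY)]
    ev = ev.sort_values("t_first").reset_index(drop=True)
    if len(ev) == 0:
        raise ValueError("no medium-prey feeding events to define hunger")
    starts = pd.to_datetime(ev["t_first"]).to_numpy()
    ends = pd.to_datetime(ev["t_last"]).to_numpy()
    hunger = np.full(len(t), np.nan)
    for k in range(len(ev)):
        during = (t >= starts[k]) & (t <= ends[k])
        hunger[during] = 0.0
        after = t > ends[k]
        if k + 1 < len(ev):
            after &= t < starts[k + 1]
        days = (t[after] - ends[k]) / np.timedelta64(1, "D")
        hunger[after] = days
    censored = np.isnan(hunger)
    if censored.any():
        observed = hunger[~censored]
        fill = float(np.median(observed)) if len(observed) else 0.0
        hunger[censored] = fill
        warnings.warn(
            f"{censored.sum()} fixes precede the first feeding event; "
            f"left-censored hunger set to the median ({fill:.2f} d)",
            RuntimeWarning,
        )
    return hunger, censored


def detect_excursions(
    fixes: pd.DataFrame, cluster: Cluster, radius_m: float = DEFAULT_RADIUS_M
) -> list[dict]:
    """Bouts of leaving and returning to a feeding area: maximal runs of
    consecutive fixes beyond `radius_m` of the cluster centroid, bounded on
    both sides by in-radius fixes.  A trailing departure with no return is
    not an excursion."""
    t = pd.to_datetime(fixes["t"]).reset_index(drop=True)
    d = np.hypot(
        fixes["x_km"].to_numpy(dtype=float) - cluster.centroid[0],
        fixes["y_km"].to_numpy(dtype=float) - cluster.centroid[1],
    )
    out_mask = d > radius_m / 1000.0
    excursions = []
    n = len(fixes)
    i = 0
    while i < n:
        if out_mask[i]:
            j = i
            while j < n and out_mask[j]:
                j += 1
            if i > 0 and j < n:  # bounded by in-radius fixes on both sides
                dur = (t[j] - t[i]) / pd.Timedelta(hours=1)
                excursions.append(
                    {"t_leave": t[i], "t_return": t[j], "duration_h": float(dur),
                     "indices": np.arange(i, j)}
                )
            i = j
        else:
            i += 1
    return excursions


def cluster_dwell_time(
    cluster: Cluster,
    fixes: pd.DataFrame,
    radius_m: float = DEFAULT_RADIUS_M,
    subtract_excursions: bool = False,
) -> float:
    """Hours from the first to the last fix within `radius_m` of the cluster
    centroid, optionally minus time spent on excursions."""
    t = pd.to_datetime(fixes["t"]).reset_index(drop=True)
    d = np.hypot(
        fixes["x_km"].to_numpy(dtype=float) - cluster.centroid[0],
        fixes["y_km"].to_numpy(dtype=float) - cluster.centroid[1],
    )
    inside = np.where(d <= radius_m / 1000.0)[0]
    if len(inside) < 2:
        return 0.0
    span = (t[inside[-1]] - t[inside[0]]) / pd.Timedelta(hours=1)
    if subtract_excursions:
        for exc in detect_excursions(fixes, cluster, radius_m):
            span -= exc["duration_h"]
    return float(span)


def cluster_report(
    clusters: list[Cluster], fixes: pd.DataFrame, radius_m: float = DEFAULT_RADIUS_M
) -> pd.DataFrame:
    """Tidy per-cluster summary (centroid, span, members, dwell, excursions)."""
    rows = []
    for k, cl in enumerate(clusters):
        excs = detect_excursions(fixes, cl, radius_m)
        rows.append(
            {
                "cluster_id": k,
                "centroid_x_km": cl.centroid[0],
                "centroid_y_km": cl.centroid[1],
                "t_start": cl.t_start,
                "t_end": cl.t_end,
                "n_fixes": len(cl.members),
                "classification": cl.classification,
                "dwell_h": cluster_dwell_time(cl, fixes, radius_m),
                "n_excursions": len(excs),
            }
        )
    return pd.DataFrame(rows)
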
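"""Telemetry preparation: reading relocation tables, study filters, step and
turning-angle computation, and splitting into regular 1-h and 3-h series.

Works in projected planar kilometres throughout.  A step series is a tidy
DataFrame with one row per step (the move from fix t to fix t+1):

    burst_id, t, step_km, angle_rad, hour, temp_c [, hunger_days]

The turning angle at row t is the change in travel bearing from the previous
step, wrapped to (-pi, pi]; it is NaN for the first step of every burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Track", "compute_steps", "apply_study_filters", "split_by_interval", "read_fixes"]

# Lambing-season exclusion window for the hunger analysis (month, day).
LAMBING_WINDOW = ((5, 1), (6, 30))
POST_COLLARING_DISCARD_H = 96.0

DEFAULT_ALIASES = {
    "individual-local-identifier": "animal_id",
    "timestamp": "t",
    "location-long": "lon",
    "location-lat": "lat",
    "external-temperature": "temp_c",
    "temperature": "temp_c",
}


@dataclass
class Track:
    """A regular-interval sequence of fixes for one animal and life stage."""

    animal_id: str
    interval_h: float
    fixes: pd.DataFrame
    life_stage: str | None = None
    burst_id: int = 0


def read_fixes(path, column_aliases: dict | None = None) -> pd.DataFrame:
    """Read a relocation CSV, applying Movebank-style column aliases."""
    df = pd.read_csv(path)
    aliases = dict(DEFAULT_ALIASES)
    if column_aliases:
        aliases.update(column_aliases)
    df = df.rename(columns={k: v for k, v in aliases.items() if k in df.columns})
    df["t"] = pd.to_datetime(df["t"])
    return df


def _bearings(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.arctan2(np.diff(y), np.diff(x))


def _wrap(a: np.ndarray) -> np.ndarray:
    return -(np.mod(-a + np.pi, 2 * np.pi) - np.pi)


def compute_steps(track: Track) -> pd.DataFrame:
    """Step lengths (km) and turning angles (rad) for one burst.

    Bursts are never bridged: this operates on a single regular burst; use
    `split_by_interval` first and concatenate the results.
    """
    fx = track.fixes.reset_index(drop=True)
    if fx["t"].duplicated().any():
        dup = fx.loc[fx["t"].duplicated(), "t"].iloc[0]
        raise ValueError(f"duplicate timestamp {dup} for animal {track.animal_id}")
    if not fx["t"].is_monotonic_increasing:
        raise ValueError(f"timestamps not increasing for animal {track.animal_id}")
    n = len(fx)
    cols = ["burst_id", "t", "step_km", "angle_rad", "hour", "temp_c"]
    if n < 2:
        return pd.DataFrame(columns=cols)
    x = fx["x_km"].to_numpy(dtype=float)
    y = fx["y_km"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite coordinates")
    steps = np.hypot(np.diff(x), np.diff(y))
    bear = _bearings(x, y)
    angles = np.full(n - 1, np.nan)
    if n >= 3:
        angles[1:] = _wrap(np.diff(bear))
    t = fx["t"].iloc[:-1].reset_index(drop=True)
    hour = t.dt.hour + t.dt.minute / 60.0 + t.dt.second / 3600.0
    out = pd.DataFrame(
        {
            "burst_id": track.burst_id,
            "t": t,
            "step_km": steps,
            "angle_rad": angles,
            "hour": hour.to_numpy(),
            "temp_c": (
                fx["temp_c"].iloc[:-1].to_numpy(dtype=float)
                if "temp_c" in fx
                else np.nan
            ),
        }
    )
    return out


def apply_study_filters(
    fixes: pd.DataFrame, collaring_date, mode: str = "general"
) -> pd.DataFrame:
    """Discard the first 4 days post-collaring always; additionally drop the
    two months following the lambing season (May 1 - June 30) when
    mode == 'hunger_analysis'."""
    if mode not in ("general", "hunger_analysis"):
        raise ValueError(f"unknown filter mode {mode!r}")
    collaring_date = pd.Timestamp(collaring_date)
    t = pd.to_datetime(fixes["t"])
    keep = t >= collaring_date + pd.Timedelta(hours=POST_COLLARING_DISCARD_H)
    if mode == "hunger_analysis":
        (m0, d0), (m1, d1) = LAMBING_WINDOW
        md = t.dt.month * 100 + t.dt.day
        keep &= ~((md >= m0 * 100 + d0) & (md <= m1 * 100 + d1))
    return fixes.loc[keep.to_numpy()].reset_index(drop=True)


def split_by_interval(
    fixes: pd.DataFrame,
    tolerance_min: float = 5.0,
    animal_id: str = "",
    life_stage: str | None = None,
) -> dict[int, list[Track]]:
    """Partition time-sorted fixes into regular 1-h and 3-h bursts.

    Maximal runs of successive gaps within tolerance of 60 or 180 minutes
    become bursts of the corresponding sampling regime; other gaps break
    bursts.  A boundary fix between two regimes is assigned to the earlier
    run and duplicated as the opening fix of the later run, so neither
    series loses a step.
    """
    fixes = fixes.sort_values("t").reset_index(drop=True)
    out: dict[int, list[Track]] = {1: [], 3: []}
    n = len(fixes)
    if n < 2:
        return out
    gaps_min = np.diff(fixes["t"].to_numpy()).astype("timedelta64[s]").astype(float) / 60.0
    cls = np.zeros(len(gaps_min), dtype=int)
    cls[np.abs(gaps_min - 60.0) <= tolerance_min] = 1
    cls[np.abs(gaps_min - 180.0) <= tolerance_min] = 3
    burst_counter = 0
    i = 0
    while i < len(cls):
        c = cls[i]
        j = i
        while j < len(cls) and cls[j] == c:
            j += 1
        if c in (1, 3) and j - i >= 1:
            burst = fixes.iloc[i : j + 1].reset_index(drop=True)
            out[c].append(
                Track(
                    animal_id=animal_id,
                    interval_h=float(c),
                    fixes=burst,
                    life_stage=life_stage,
                    burst_id=burst_counter,
                )
            )
            burst_counter += 1
        i = j
    return out


def steps_table(tracks: list[Track]) -> pd.DataFrame:
    """Concatenate per-burst step series into one tidy table."""
    frames = [compute_steps(tr) for tr in tracks]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(
            columns=["burst_id", "t", "step_km", "angle_rad", "hour", "temp_c"]
        )
    return pd.concat(frames, ignore_index=True)
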
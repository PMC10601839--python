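"""Behavioural-module segmentation and course-direction statistics.

Trajectories are segmented into three behaviour modules as a function of the
time elapsed since odour was last perceptible (``T_last``):

- ``tracking``:   T_last <= tracking_max_gap (default 12 steps, 0.48 s);
- ``lost``:       T_last >= the per-agent lost threshold (25-38 steps);
- ``recovering``: in between.

Course direction is the direction of the realized ground displacement; it is
compared against the current wind direction and against the local plume
centreline angle (median centreline-segment orientation within a +/-2 cm
band of the agent's downwind coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ModuleThresholds",
    "LOST_THRESHOLDS",
    "encounters",
    "time_since_last",
    "segment_modules",
    "course_direction",
    "course_relative",
    "wrap_angle",
    "module_summaries",
    "tracking_course_stats",
]

#: Per-agent lost-module thresholds in steps (chosen by visual inspection in
#: the study conditions these defaults mirror).
LOST_THRESHOLDS = {1: 30, 2: 25, 3: 35, 4: 38, 5: 25}


@dataclass
class ModuleThresholds:
    """tracking/recovering/lost boundaries, in environment steps (25/s)."""

    tracking_max_gap: int = 12     # steps (0.48 s, honouring "under 0.5 s")
    lost_min_gap: int = 30         # steps, per-agent (25-38)

    def __post_init__(self):
        if not 0 < self.tracking_max_gap < self.lost_min_gap:
            raise ValueError("need 0 < tracking_max_gap < lost_min_gap")


def encounters(odour_series) -> np.ndarray:
    """Binary onset series: 1 exactly at the first step of each contiguous
    perceptible-odour run, 0 elsewhere.  Input is sensed odour (already
    thresholded, so perceptible means > 0)."""
    o = np.asarray(odour_series, dtype=float)
    perceptible = o > 0
    prev = np.concatenate([[False], perceptible[:-1]])
    return (perceptible & ~prev).astype(int)


def time_since_last(perceptible_series) -> np.ndarray:
    """Steps since the last perceptible step: 0 at perceptible steps,
    otherwise incrementing by 1 per step.  Before any perceptible step the
    count runs from the episode start."""
    p = np.asarray(perceptible_series).astype(bool)
    out = np.empty(p.size, dtype=int)
    last = -1
    for t in range(p.size):
        if p[t]:
            last = t
        out[t] = t - last
    return out


def segment_modules(t_last, thresholds: ModuleThresholds | None = None) -> np.ndarray:
    """Per-step behaviour labels from T_last alone."""
    th = thresholds if thresholds is not None else ModuleThresholds()
    t_last = np.asarray(t_last)
    labels = np.where(t_last <= th.tracking_max_gap, "tracking",
                      np.where(t_last >= th.lost_min_gap, "lost",
                               "recovering"))
    return labels


def course_direction(positions) -> np.ndarray:
    """Per-step course angle (degrees) from consecutive positions; nan where
    the displacement is zero.  Output has length len(positions) - 1."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("need at least two positions")
    d = np.diff(pos, axis=0)
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    ang[(d == 0).all(axis=1)] = np.nan
    return ang


def wrap_angle(a):
    """Wrap angle(s) in degrees to (-180, 180]."""
    w = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(w == -180.0, 180.0, w)


def course_relative(course, reference) -> np.ndarray:
    """Wrapped difference course - reference, in (-180, 180].  nan reference
    entries (e.g. the no-centreline sentinel) propagate to nan."""
    return wrap_angle(np.asarray(course, dtype=float)
                      - np.asarray(reference, dtype=float))


_SUMMARY_VARS = ("heading_deg", "dx", "dy", "turn", "move", "stray")


def module_summaries(df: pd.DataFrame, labels=None,
                     variables=_SUMMARY_VARS) -> dict:
    """Per-module empirical distributions of the key behavioural measures.

    Returns ``{module: {variable: {"samples", "median", "q1", "q3", "n"}}}``;
    the raw samples are kernel-density-ready, the quantiles are what tests
    and summary tables assert on.
    """
    if labels is None:
        labels = df["module"].to_numpy()
    labels = np.asarray(labels)
    out = {}
    for module in ("tracking", "recovering", "lost"):
        mask = labels == module
        stats = {}
        for var in variables:
            s = df.loc[mask, var].to_numpy(dtype=float)
            s = s[np.isfinite(s)]
            if s.size:
                stats[var] = {"samples": s,
                              "median": float(np.median(s)),
                              "q1": float(np.quantile(s, 0.25)),
                              "q3": float(np.quantile(s, 0.75)),
                              "n": int(s.size)}
            else:
                stats[var] = {"samples": s, "median": np.nan,
                              "q1": np.nan, "q3": np.nan, "n": 0}
        out[module] = stats
    return out


def annotate_episode(df: pd.DataFrame,
                     thresholds: ModuleThresholds | None = None) -> pd.DataFrame:
    """Add encounter/T_last/module columns to one episode's step log."""
    df = df.copy()
    enc = encounters(df["odour"].to_numpy())
    t_last = time_since_last(df["odour"].to_numpy() > 0)
    df["encounter"] = enc
    df["t_last"] = t_last
    df["module"] = segment_modules(t_last, thresholds)
    return df


def annotate(episodes: pd.DataFrame,
             thresholds: ModuleThresholds | None = None) -> pd.DataFrame:
    """Annotate a multi-episode log (grouped by episode_id)."""
    parts = [annotate_episode(g, thresholds)
             for _, g in episodes.groupby("episode_id", sort=False)]
    return pd.concat(parts, ignore_index=True)


def tracking_course_stats(episodes: pd.DataFrame,
                          centreline_angles=None,
                          thresholds: ModuleThresholds | None = None,
                          max_episodes: int = 60,
                          post_switch_only: bool = False,
                          switch_time: float | None = None,
                          rng=None) -> pd.DataFrame:
    """Course-direction statistics for the tracking module.

    Aggregates up to ``max_episodes`` random successful episodes, restricted
    to tracking-module steps; for switch-once data only post-switch steps
    are retained.  Returns a tidy per-step table with the course direction
    relative to the wind and (when ``centreline_angles`` is given, aligned
    with the input rows) relative to the local plume centreline.
    """
    df = episodes.copy().reset_index(drop=True)
    if centreline_angles is not None:
        df["centreline_deg"] = np.asarray(centreline_angles, dtype=float)
    ok = df[df["outcome"] == "success"]["episode_id"].unique()
    if ok.size > max_episodes:
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator) else rng
        ok = rng.choice(ok, size=max_episodes, replace=False)
    df = df[df["episode_id"].isin(ok)]
    df = annotate(df, thresholds)
    df = df[df["module"] == "tracking"]
    if post_switch_only:
        if switch_time is None:
            raise ValueError("post_switch_only requires switch_time")
        df = df[df["t"] >= switch_time]
    wind_deg = np.degrees(np.arctan2(df["wind_y"], df["wind_x"]))
    out = pd.DataFrame({
        "episode_id": df["episode_id"].to_numpy(),
        "step": df["step"].to_numpy(),
        "course_deg": df["course_deg"].to_numpy(),
        "course_rel_wind": course_relative(df["course_deg"], wind_deg),
    })
    if "centreline_deg" in df:
        out["course_rel_centreline"] = course_relative(
            df["course_deg"], df["centreline_deg"])
    return out.dropna(subset=["course_rel_wind"]).reset_index(drop=True)
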
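"""Particle-based two-dimensional odour plume simulator.

An odour source at the origin emits discrete puffs as a Poisson process into
a spatially homogeneous wind field. Each puff is advected downwind, perturbed
laterally by crosswind noise (a biased random walk), and grows radially at a
fixed rate so that its concentration falls as the inverse cube of its radius
(conservation of odourant mass in 3-D).  A parallel set of noiseless puffs
traces the plume centreline.  The simulator runs at 100 iterations per second;
the agent-facing environment subsamples every 4th frame (25 Hz).

Five wind regimes are supported:

- ``constant``:     wind direction 0 deg throughout.
- ``switch-once``:  one 45 deg anticlockwise switch at a configurable time.
- ``switch-many``:  piecewise-constant direction; switch times form a renewal
                    process with mean spacing ~3 s, increments drawn from a
                    truncated Gaussian (sd 45 deg, |increment| <= 60 deg).
- ``sparse``:       constant wind, puff birth rate reduced 0.4-fold.
- ``sparser``:      sparse plus radial diffusion rate reduced 0.5-fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PlumeConfig",
    "Puff",
    "WindSchedule",
    "PlumeFrame",
    "PlumeSimulator",
    "NO_CENTRELINE",
    "REGIMES",
    "config_for_regime",
    "emit_puffs",
    "step_puff",
    "sample_concentration",
    "wind_direction",
    "local_centreline_angle",
    "frame_table",
]

#: Sentinel returned when no centreline puff lies within the query band.
NO_CENTRELINE = math.nan

REGIMES = ("constant", "switch-once", "switch-many", "sparse", "sparser")


@dataclass
class PlumeConfig:
    """Simulator parameters (all SI units; defaults match the baseline plume)."""

    dt_sim: float = 0.01            # s per simulator iteration (100 Hz)
    birth_rate: float = 1.0         # Poisson mean, puffs per iteration
    r0: float = 0.01                # initial puff radius, m
    c0: float = 1.0                 # initial puff concentration, a.u.
    r_delta: float = 0.01           # radial growth rate, m/s
    wind_speed: float = 0.5         # m/s
    crosswind_noise_sd: float = 0.005   # m/s velocity perturbation per iteration
    extents: tuple = ((-2.0, 10.0), (-5.0, 5.0))  # ((xmin, xmax), (ymin, ymax)), m
    birth_fold: float = 1.0         # multiplicative birth-rate modifier
    diffusion_fold: float = 1.0     # multiplicative growth-rate modifier

    def __post_init__(self):
        if self.dt_sim <= 0:
            raise ValueError("dt_sim must be positive")
        if self.birth_rate < 0:
            raise ValueError("birth_rate must be non-negative")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.r_delta < 0:
            raise ValueError("r_delta must be non-negative")
        (x0, x1), (y0, y1) = self.extents
        if x1 <= x0 or y1 <= y0:
            raise ValueError("extents must be non-degenerate")

    @property
    def arena_area(self) -> float:
        """Arena area in m^2 (120 m^2 at the default extents)."""
        (x0, x1), (y0, y1) = self.extents
        return (x1 - x0) * (y1 - y0)

    @property
    def growth_rate(self) -> float:
        """Effective radial growth rate r_delta * diffusion_fold, m/s."""
        return self.r_delta * self.diffusion_fold

    @property
    def effective_birth_rate(self) -> float:
        return self.birth_rate * self.birth_fold


def config_for_regime(regime: str, base: PlumeConfig | None = None) -> PlumeConfig:
    """Return the plume configuration for a named wind/sparsity regime.

    ``sparse`` reduces the birth rate 0.4-fold; ``sparser`` additionally
    halves the radial diffusion rate.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    cfg = base if base is not None else PlumeConfig()
    if regime == "sparse":
        return replace(cfg, birth_fold=0.4)
    if regime == "sparser":
        return replace(cfg, birth_fold=0.4, diffusion_fold=0.5)
    return replace(cfg)


@dataclass
class Puff:
    """One odour packet."""

    x: float
    y: float
    radius: float
    concentration: float
    birth_time: float
    is_centreline: bool = False


@dataclass
class WindSchedule:
    """Time-dependent wind direction (degrees anticlockwise from +x).

    ``switch-many`` switch times and increments are generated lazily from the
    schedule's own random stream, so ``direction(t)`` is a deterministic
    function of time for a fixed seed.
    """

    regime: str = "constant"
    switch_time: float = 30.0       # s, switch-once only
    switch_angle: float = 45.0      # deg, switch-once increment
    switch_interval_mean: float = 3.0   # s, switch-many renewal mean
    switch_sd: float = 45.0         # deg
    switch_truncation: float = 60.0  # deg, |increment| bound
    seed: int | None = None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        self._rng = np.random.default_rng(self.seed)
        # event_times[i] is when the angle becomes event_angles[i]
        self._event_times: list[float] = []
        self._event_angles: list[float] = []
        self._increments: list[float] = []
        self._next_time = 0.0
        self._angle = 0.0

    def _truncated_increment(self) -> float:
        while True:
            d = self._rng.normal(0.0, self.switch_sd)
            if abs(d) <= self.switch_truncation:
                return d

    def _extend_events(self, t: float) -> None:
        while self._next_time <= t:
            self._next_time += self._rng.exponential(self.switch_interval_mean)
            d = self._truncated_increment()
            self._angle += d
            self._event_times.append(self._next_time)
            self._event_angles.append(self._angle)
            self._increments.append(d)

    def direction(self, t: float) -> float:
        """Wind angle in degrees at time ``t`` (>= 0)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        if self.regime in ("constant", "sparse", "sparser"):
            return 0.0
        if self.regime == "switch-once":
            return self.switch_angle if t >= self.switch_time else 0.0
        # switch-many
        self._extend_events(t)
        idx = np.searchsorted(self._event_times, t, side="right")
        if idx == 0:
            return 0.0
        return self._event_angles[idx - 1]

    def increments(self, n: int) -> np.ndarray:
        """First ``n`` switch-many increments (degrees)."""
        if self.regime != "switch-many":
            raise ValueError("increments are defined only for switch-many")
        while len(self._increments) < n:
            self._extend_events(self._next_time)
        return np.asarray(self._increments[:n])

    def event_times(self, horizon: float) -> np.ndarray:
        """Switch event times up to ``horizon`` seconds."""
        if self.regime != "switch-many":
            raise ValueError("event times are defined only for switch-many")
        self._extend_events(horizon)
        times = np.asarray(self._event_times)
        return times[times <= horizon]

    def wind_vector(self, t: float, speed: float) -> np.ndarray:
        a = math.radians(self.direction(t))
        return np.array([speed * math.cos(a), speed * math.sin(a)])


@dataclass
class PlumeFrame:
    """Snapshot of the plume at one instant."""

    time: float
    wind_vector: np.ndarray
    x: np.ndarray
    y: np.ndarray
    radius: np.ndarray
    concentration: np.ndarray
    cx: np.ndarray          # centreline puff positions
    cy: np.ndarray
    cbirth: np.ndarray


# ---------------------------------------------------------------------------
# Per-puff operations (the simulator applies the same rules vectorized).
# ---------------------------------------------------------------------------

def emit_puffs(config: PlumeConfig, rng: np.random.Generator, t: float = 0.0) -> list[Puff]:
    """Draw one iteration's newborn puffs (Poisson, mean birth_rate*birth_fold)."""
    n = rng.poisson(config.effective_birth_rate)
    return [
        Puff(0.0, 0.0, config.r0, config.c0, birth_time=t)
        for _ in range(n)
    ]


def step_puff(puff: Puff, wind: tuple, config: PlumeConfig,
              rng: np.random.Generator | None = None) -> Puff:
    """Advance one puff by one simulator iteration.

    Radius grows by ``r_delta * diffusion_fold * dt_sim``; the concentration
    is recomputed from mass conservation, c = c0 (r0 / r)^3; the position is
    advected by the wind plus (for non-centreline puffs) a crosswind velocity
    perturbation ~ N(0, crosswind_noise_sd).
    """
    dt = config.dt_sim
    wx, wy = wind
    r = puff.radius + config.growth_rate * dt
    c = config.c0 * (config.r0 / r) ** 3
    x = puff.x + wx * dt
    y = puff.y + wy * dt
    if not puff.is_centreline:
        if rng is None:
            raise ValueError("non-centreline puffs require an rng")
        v_noise = rng.normal(0.0, config.crosswind_noise_sd)
        speed = math.hypot(wx, wy)
        if speed > 0:
            ux, uy = -wy / speed, wx / speed   # unit crosswind direction
        else:
            ux, uy = 0.0, 1.0
        x += v_noise * ux * dt
        y += v_noise * uy * dt
    return Puff(x, y, r, c, puff.birth_time, puff.is_centreline)


def sample_concentration(point: tuple, frame: PlumeFrame) -> float:
    """Instantaneous concentration at ``point``: the sum of the concentrations
    of every (non-centreline) puff whose radius covers the point."""
    px, py = point
    if frame.x.size == 0:
        return 0.0
    d2 = (frame.x - px) ** 2 + (frame.y - py) ** 2
    inside = d2 <= frame.radius ** 2
    return float(frame.concentration[inside].sum())


def wind_direction(t: float, schedule: WindSchedule) -> float:
    """Wind angle (degrees anticlockwise from +x) at time ``t``."""
    return schedule.direction(t)


def _wrap_deg(a):
    """Wrap to (-180, 180]."""
    w = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(w == -180.0, 180.0, w)


def local_centreline_angle(x: float, frame: PlumeFrame, band: float = 0.02) -> float:
    """Median orientation (degrees) of the plume centreline near downwind
    coordinate ``x``, using centreline puffs within ``+/- band`` metres.

    Returns the ``NO_CENTRELINE`` nan sentinel when no centreline puff lies in
    the band; callers skip such time steps.
    """
    cx, cy, cbirth = frame.cx, frame.cy, frame.cbirth
    if cx.size < 2:
        return NO_CENTRELINE
    order = np.argsort(cbirth)           # oldest (most downwind) first
    cx, cy = cx[order], cy[order]
    in_band = np.abs(cx - x) <= band
    if not in_band.any():
        return NO_CENTRELINE
    idx = np.flatnonzero(in_band)
    lo, hi = idx.min(), idx.max()
    # include one neighbour on each side so a single in-band puff still
    # defines a segment
    lo = max(lo - 1, 0)
    hi = min(hi + 1, cx.size - 1)
    sx, sy = cx[lo:hi + 1], cy[lo:hi + 1]
    # vector from newer to older puff points downwind along the local spine
    dx = sx[:-1] - sx[1:]
    dy = sy[:-1] - sy[1:]
    keep = (dx != 0) | (dy != 0)
    if not keep.any():
        return NO_CENTRELINE
    ang = np.degrees(np.arctan2(dy[keep], dx[keep]))
    # circular median: centre on the first segment angle before taking the
    # median so a spine near +/-180 deg does not split
    ref = ang[0]
    centred = _wrap_deg(ang - ref)
    return float(_wrap_deg(ref + np.median(centred)))


# ---------------------------------------------------------------------------
# Vectorized simulator
# ---------------------------------------------------------------------------

class PlumeSimulator:
    """Vectorized plume simulation with independently seeded random streams
    for puff births, crosswind noise and wind switches."""

    def __init__(self, config: PlumeConfig | None = None,
                 schedule: WindSchedule | None = None,
                 seed: int | None = None):
        self.config = config if config is not None else PlumeConfig()
        seq = np.random.SeedSequence(seed)
        s_birth, s_noise, s_wind = seq.spawn(3)
        self.rng_births = np.random.default_rng(s_birth)
        self.rng_noise = np.random.default_rng(s_noise)
        if schedule is None:
            schedule = WindSchedule("constant")
        if schedule.regime == "switch-many" and schedule.seed is None:
            schedule = replace(schedule, seed=s_wind.generate_state(1)[0])
        self.schedule = schedule
        self.t = 0.0
        n0 = 0
        self.x = np.empty(n0)
        self.y = np.empty(n0)
        self.r = np.empty(n0)
        self.birth = np.empty(n0)
        self.cx = np.empty(n0)
        self.cy = np.empty(n0)
        self.cr = np.empty(n0)
        self.cbirth = np.empty(n0)
        # introspection: last iteration's crosswind velocity draws and births
        self.last_noise_velocities = np.empty(0)
        self.last_births = 0

    # -- dynamics ---------------------------------------------------------

    def wind_vector(self, t: float | None = None) -> np.ndarray:
        if t is None:
            t = self.t
        return self.schedule.wind_vector(t, self.config.wind_speed)

    def step(self) -> None:
        """Advance one simulator iteration (dt_sim)."""
        cfg = self.config
        dt = cfg.dt_sim
        wx, wy = self.wind_vector(self.t)
        speed = math.hypot(wx, wy)
        if speed > 0:
            ux, uy = -wy / speed, wx / speed
        else:
            ux, uy = 0.0, 1.0

        # advect + diffuse existing puffs
        n = self.x.size
        v_noise = self.rng_noise.normal(0.0, cfg.crosswind_noise_sd, n)
        self.last_noise_velocities = v_noise
        self.x += wx * dt + v_noise * ux * dt
        self.y += wy * dt + v_noise * uy * dt
        self.r += cfg.growth_rate * dt
        self.cx += wx * dt
        self.cy += wy * dt
        self.cr += cfg.growth_rate * dt

        # births at the source
        k = int(self.rng_births.poisson(cfg.effective_birth_rate))
        self.last_births = k
        if k:
            self.x = np.append(self.x, np.zeros(k))
            self.y = np.append(self.y, np.zeros(k))
            self.r = np.append(self.r, np.full(k, cfg.r0))
            self.birth = np.append(self.birth, np.full(k, self.t))
        # one noiseless centreline puff per iteration
        self.cx = np.append(self.cx, 0.0)
        self.cy = np.append(self.cy, 0.0)
        self.cr = np.append(self.cr, cfg.r0)
        self.cbirth = np.append(self.cbirth, self.t)

        self._cull()
        self.t += dt

    def _cull(self) -> None:
        (x0, x1), (y0, y1) = self.config.extents
        keep = ((self.x > x0 - self.r) & (self.x < x1 + self.r)
                & (self.y > y0 - self.r) & (self.y < y1 + self.r))
        if not keep.all():
            self.x, self.y = self.x[keep], self.y[keep]
            self.r, self.birth = self.r[keep], self.birth[keep]
        keep = ((self.cx > x0 - self.cr) & (self.cx < x1 + self.cr)
                & (self.cy > y0 - self.cr) & (self.cy < y1 + self.cr))
        if not keep.all():
            self.cx, self.cy = self.cx[keep], self.cy[keep]
            self.cr, self.cbirth = self.cr[keep], self.cbirth[keep]

    def run(self, duration: float) -> None:
        """Advance the simulation by ``duration`` seconds."""
        for _ in range(int(round(duration / self.config.dt_sim))):
            self.step()

    # -- queries ----------------------------------------------------------

    @property
    def concentration(self) -> np.ndarray:
        cfg = self.config
        return cfg.c0 * (cfg.r0 / self.r) ** 3

    def frame(self) -> PlumeFrame:
        return PlumeFrame(
            time=self.t,
            wind_vector=self.wind_vector(),
            x=self.x.copy(), y=self.y.copy(), radius=self.r.copy(),
            concentration=self.concentration,
            cx=self.cx.copy(), cy=self.cy.copy(), cbirth=self.cbirth.copy(),
        )

    def sample_concentration(self, point: tuple) -> float:
        px, py = point
        if self.x.size == 0:
            return 0.0
        d2 = (self.x - px) ** 2 + (self.y - py) ** 2
        inside = d2 <= self.r ** 2
        cfg = self.config
        return float((cfg.c0 * (cfg.r0 / self.r[inside]) ** 3).sum())

    def stray_distance(self, point: tuple) -> float:
        """Distance from ``point`` to the nearest puff edge (0 inside a puff)."""
        if self.x.size == 0:
            return math.inf
        px, py = point
        d = np.hypot(self.x - px, self.y - py) - self.r
        return float(max(d.min(), 0.0))

    def local_centreline_angle(self, x: float, band: float = 0.02) -> float:
        return local_centreline_angle(x, self.frame(), band=band)

    # -- state snapshots (used by the deterministic evaluation grid) -------

    def snapshot(self) -> dict:
        return {
            "t": self.t,
            "x": self.x.copy(), "y": self.y.copy(),
            "r": self.r.copy(), "birth": self.birth.copy(),
            "cx": self.cx.copy(), "cy": self.cy.copy(),
            "cr": self.cr.copy(), "cbirth": self.cbirth.copy(),
            "rng_births": self.rng_births.bit_generator.state,
            "rng_noise": self.rng_noise.bit_generator.state,
        }

    def restore(self, snap: dict) -> None:
        self.t = snap["t"]
        self.x, self.y = snap["x"].copy(), snap["y"].copy()
        self.r, self.birth = snap["r"].copy(), snap["birth"].copy()
        self.cx, self.cy = snap["cx"].copy(), snap["cy"].copy()
        self.cr, self.cbirth = snap["cr"].copy(), snap["cbirth"].copy()
        self.rng_births.bit_generator.state = snap["rng_births"]
        self.rng_noise.bit_generator.state = snap["rng_noise"]


def frame_table(sim: PlumeSimulator, duration: float, every: int = 4) -> pd.DataFrame:
    """Run the simulator and export a tabular puff log.

    One row per puff per sampled frame; every ``every``-th iteration is
    exported (4 matches the 25 Hz environment frame rate).
    """
    rows = []
    n_iter = int(round(duration / sim.config.dt_sim))
    for i in range(n_iter):
        sim.step()
        if i % every:
            continue
        fr = sim.frame()
        for j in range(fr.x.size):
            rows.append((fr.time, j, fr.x[j], fr.y[j], fr.radius[j],
                         fr.concentration[j], False))
        for j in range(fr.cx.size):
            rows.append((fr.time, fr.x.size + j, fr.cx[j], fr.cy[j],
                         math.nan, math.nan, True))
    return pd.DataFrame(
        rows, columns=["time", "puff_id", "x", "y", "radius",
                       "concentration", "is_centreline"])
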
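"""Agent-environment loop for the plume-tracking task.

The environment runs at 25 steps per second on a plume simulated at 100 Hz
(four simulator iterations per environment step).  Each step the agent
receives an egocentric observation -- the ambient wind vector rotated into
its heading frame plus the locally sensed odour concentration -- and issues a
continuous turn/move command.  The realized ground displacement is the
commanded motion along the new heading plus full wind advection, so course
direction and head direction generally differ.

Episode outcome set: ``success`` (within the 0.2 m homing radius),
``stray_fail`` (further than 2 m from every puff, or outside the arena), or
``timeout`` (300 steps, 12 s of flight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .plume import PlumeConfig, PlumeSimulator, WindSchedule, config_for_regime

__all__ = [
    "EnvConfig",
    "AgentState",
    "PlumeTrackingEnv",
    "egocentrize",
    "sense_odour",
    "reward",
    "terminate",
    "evaluation_grid",
    "DT_ENV",
    "SIM_ITERS_PER_STEP",
    "THETA_MAX",
    "DELTA_MAX",
]

DT_ENV = 0.04                    # s per environment step (25 Hz)
SIM_ITERS_PER_STEP = 4           # 100 Hz plume -> 25 Hz environment
THETA_MAX = 6.25 * math.pi       # rad/s maximum turn rate
DELTA_MAX = 2.5                  # m/s maximum forward speed
ODOUR_MIN = 1e-4                 # sensing floor, a.u.
ODOUR_MAX = 1.0                  # sensing ceiling, a.u.


@dataclass
class EnvConfig:
    """Environment, reward and initialization parameters."""

    homing_radius: float = 0.2       # m
    max_stray: float = 2.0           # m, stray_fail threshold
    max_steps: int = 300             # steps (12 s)
    # reward coefficients
    r_home: float = 100.0            # terminal homing bonus
    k_radial: float = 1.0            # per metre of radial approach
    k_time: float = 0.05             # per step
    k_stray: float = 2.0             # per metre beyond stray_ramp_start
    stray_ramp_start: float = 1.5    # m
    # initialization region: a downwind box spanning the plume envelope
    # plus a margin ("within or slightly outside plumes")
    init_x: tuple = (1.0, 8.0)       # m
    init_margin: float = 0.5         # m beyond the plume half-width
    warmup: float = 25.0             # s of plume simulated before episodes

    def __post_init__(self):
        if self.init_x[1] <= self.init_x[0]:
            raise ValueError("empty initialization region")


@dataclass
class AgentState:
    """Agent pose plus the most recent realized displacement."""

    x: float
    y: float
    heading_deg: float          # head direction, deg anticlockwise from +x
    course_deg: float = math.nan  # direction of realized displacement
    dx: float = 0.0
    dy: float = 0.0

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


def egocentrize(wind_vector, heading_deg: float) -> np.ndarray:
    """Rotate the ground-frame wind vector by ``-heading`` into the agent's
    heading frame; returns (w_X, w_Y)."""
    a = math.radians(heading_deg)
    c, s = math.cos(a), math.sin(a)
    wx, wy = wind_vector
    return np.array([c * wx + s * wy, -s * wx + c * wy])


def sense_odour(raw: float) -> float:
    """Clip raw concentration into the sensing range: values below the
    1e-4 floor are imperceptible (0); values above 1.0 saturate."""
    if raw < 0:
        raise ValueError("concentration must be non-negative")
    if raw < ODOUR_MIN:
        return 0.0
    return min(raw, ODOUR_MAX)


def reward(d_prev: float, d_now: float, stray: float, success: bool,
           cfg: EnvConfig) -> float:
    """Shaped scalar reward: large terminal homing bonus, a mild dense term
    for reducing radial distance to the source, a per-step time penalty, and
    a stray penalty ramping beyond ``stray_ramp_start``."""
    r = cfg.k_radial * (d_prev - d_now) - cfg.k_time
    if math.isfinite(stray):
        r -= cfg.k_stray * max(0.0, stray - cfg.stray_ramp_start)
    if success:
        r += cfg.r_home
    return r


def terminate(distance: float, stray: float, t_step: int, cfg: EnvConfig,
              in_bounds: bool = True) -> str | None:
    """Episode outcome, or ``None`` while the episode continues."""
    if distance <= cfg.homing_radius:
        return "success"
    if stray > cfg.max_stray or not in_bounds:
        return "stray_fail"
    if t_step >= cfg.max_steps:
        return "timeout"
    return None


class PlumeTrackingEnv:
    """reset/step environment wrapping one plume simulation.

    Observation space: 3 continuous values (w_X, w_Y in m/s; odour in a.u.,
    0 or within [1e-4, 1]).  Action space: 2 continuous values, turn in
    [-1, 1] (fraction of the 6.25*pi rad/s turn capacity) and move in [0, 1]
    (fraction of the 2.5 m/s forward speed).
    """

    observation_names = ("wind_x_ego", "wind_y_ego", "odour")
    action_names = ("turn", "move")
    action_low = np.array([-1.0, 0.0])
    action_high = np.array([1.0, 1.0])

    def __init__(self, regime: str = "constant",
                 plume_config: PlumeConfig | None = None,
                 env_config: EnvConfig | None = None,
                 seed: int | None = None,
                 warmup: float | None = None):
        self.regime = regime
        self.env_config = env_config if env_config is not None else EnvConfig()
        cfg = config_for_regime(regime, plume_config)
        seq = np.random.SeedSequence(seed)
        s_plume, s_init = seq.spawn(2)
        schedule = WindSchedule(regime)
        if regime == "switch-once":
            # the switch falls inside the episode window
            schedule.switch_time = (warmup if warmup is not None
                                    else self.env_config.warmup) + 4.0
        self.sim = PlumeSimulator(cfg, schedule,
                                  seed=int(s_plume.generate_state(1)[0]))
        self.rng_init = np.random.default_rng(s_init)
        self.sim.run(warmup if warmup is not None else self.env_config.warmup)
        self.state: AgentState | None = None
        self.t_step = 0
        self.outcome: str | None = None
        self._d_prev = math.nan

    # -- initialization ---------------------------------------------------

    def plume_half_width(self, x: float) -> float:
        """Nominal plume half-width at downwind coordinate ``x`` (the radius
        a puff reaches after advecting there)."""
        cfg = self.sim.config
        return cfg.r0 + cfg.growth_rate * max(x, 0.0) / cfg.wind_speed

    def sample_initial_position(self, x_range: tuple | None = None,
                                margin: float | None = None) -> tuple:
        ec = self.env_config
        x_lo, x_hi = x_range if x_range is not None else ec.init_x
        m = margin if margin is not None else ec.init_margin
        x = self.rng_init.uniform(x_lo, x_hi)
        hw = self.plume_half_width(x) + m
        y = self.rng_init.uniform(-hw, hw)
        return x, y

    def _observe(self) -> np.ndarray:
        st = self.state
        wind = self.sim.wind_vector()
        wx, wy = egocentrize(wind, st.heading_deg)
        odour = sense_odour(self.sim.sample_concentration((st.x, st.y)))
        return np.array([wx, wy, odour])

    def reset(self, position: tuple | None = None,
              heading_deg: float | None = None,
              x_range: tuple | None = None,
              margin: float | None = None) -> tuple[AgentState, np.ndarray]:
        if position is None:
            position = self.sample_initial_position(x_range, margin)
        if heading_deg is None:
            heading_deg = self.rng_init.uniform(0.0, 360.0)
        self.state = AgentState(position[0], position[1], float(heading_deg))
        self.t_step = 0
        self.outcome = None
        self._d_prev = math.hypot(*position)
        return self.state, self._observe()

    # -- dynamics ---------------------------------------------------------

    def step(self, action) -> tuple[AgentState, np.ndarray, float, bool, dict]:
        """Advance one 0.04 s step; returns (state, obs, reward, done, info)."""
        if self.outcome is not None:
            raise RuntimeError("episode finished; call reset()")
        action = np.asarray(action, dtype=float)
        if not np.all(np.isfinite(action)):
            raise ValueError("non-finite action")
        turn = float(np.clip(action[0], -1.0, 1.0))
        move = float(np.clip(action[1], 0.0, 1.0))

        st = self.state
        heading = st.heading_deg + math.degrees(turn * THETA_MAX * DT_ENV)
        heading %= 360.0

        # advance the plume 4 simulator iterations (100 Hz -> 25 Hz)
        for _ in range(SIM_ITERS_PER_STEP):
            self.sim.step()
        wind = self.sim.wind_vector()

        a = math.radians(heading)
        dx = move * DELTA_MAX * DT_ENV * math.cos(a) + wind[0] * DT_ENV
        dy = move * DELTA_MAX * DT_ENV * math.sin(a) + wind[1] * DT_ENV
        x, y = st.x + dx, st.y + dy
        course = math.degrees(math.atan2(dy, dx)) if (dx or dy) else math.nan
        self.state = AgentState(x, y, heading, course, dx, dy)
        self.t_step += 1

        d_now = math.hypot(x, y)
        stray = self.sim.stray_distance((x, y))
        (x0, x1), (y0, y1) = self.sim.config.extents
        in_bounds = (x0 <= x <= x1) and (y0 <= y <= y1)
        outcome = terminate(d_now, stray, self.t_step, self.env_config,
                            in_bounds)
        self.outcome = outcome
        rew = reward(self._d_prev, d_now, stray, outcome == "success",
                     self.env_config)
        self._d_prev = d_now
        obs = self._observe()
        info = {
            "outcome": outcome,
            "distance": d_now,
            "stray": stray,
            "wind": wind,
            "turn": turn,
            "move": move,
            "time": self.t_step * DT_ENV,
        }
        return self.state, obs, rew, outcome is not None, info


def evaluation_grid(env: PlumeTrackingEnv,
                    n_locations: int = 15,
                    timestamps: tuple = (25.0, 30.0),
                    n_headings: int = 8,
                    seed: int = 0) -> list[dict]:
    """The standardized evaluation grid: the cartesian product of
    ``n_locations`` initial locations x initial plume timestamps x
    ``n_headings`` evenly spaced initial head directions (15 x 2 x 8 = 240
    episodes at the defaults).

    Locations are drawn once from the environment's initialization region
    with a dedicated seed, so the grid is deterministic.
    """
    rng = np.random.default_rng(seed)
    ec = env.env_config
    locations = []
    for _ in range(n_locations):
        x = rng.uniform(*ec.init_x)
        hw = env.plume_half_width(x) + ec.init_margin
        locations.append((x, rng.uniform(-hw, hw)))
    headings = [i * 360.0 / n_headings for i in range(n_headings)]
    grid = []
    for loc in locations:
        for ts in timestamps:
            for hd in headings:
                grid.append({"position": loc, "timestamp": ts,
                             "heading_deg": hd})
    return grid
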
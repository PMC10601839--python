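"""Scripted agents and synthetic hidden-state traces.

The scripted controllers emulate the cast/surge/spiral phenomenology of
plume tracking with known, hand-written control laws, so every analysis
module can be exercised without reinforcement-learning training.  The
synthetic trace builder plants known functions of the behavioural features
into a 64-unit "hidden state", giving the neural analyses ground truth for
parameter-recovery tests.  All traces produced here are synthetic stand-ins
for trained-network activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import run_episode
from .behaviour import wrap_angle
from .environment import PlumeTrackingEnv, DT_ENV, THETA_MAX
from .neural import ewma

__all__ = [
    "ScriptedAgentSpec",
    "ScriptedPolicy",
    "generate_scripted_trajectory",
    "build_synthetic_trace",
]

CONTROLLERS = ("cast_and_surge", "upwind_only", "spiral", "random")

#: maximum heading change per environment step, degrees
TURN_PER_STEP = math.degrees(THETA_MAX * DT_ENV)


@dataclass
class ScriptedAgentSpec:
    """Deterministic (given a seed) hand-written controller."""

    controller: str = "cast_and_surge"
    surge_speed: float = 1.0        # move fraction while surging
    cast_amplitude: float = 10.0    # steps of crosswind travel per half-cast
    cast_period: float = 20.0       # steps per cast half-cycle growth
    spiral_turn: float = 0.3        # constant turn fraction for spiral
    spiral_move: float = 0.7
    lost_after: int = 12            # steps without odour before casting

    def __post_init__(self):
        if self.controller not in CONTROLLERS:
            raise ValueError(f"unknown controller {self.controller!r}")


class ScriptedPolicy:
    """Policy-protocol wrapper around a scripted controller.

    Exposes the same ``init_state``/``act`` interface as the learned
    policies; the reported "hidden state" is a zero vector (replaced by
    :func:`build_synthetic_trace` when analyses need structure).
    """

    kind = "scripted"
    seed = None

    def __init__(self, spec: ScriptedAgentSpec, seed: int | None = None):
        self.spec = spec
        self.rng = np.random.default_rng(seed)

    def init_state(self):
        return {"t_last": 10_000, "phase": 0, "cast_sign": 1.0,
                "cast_timer": 0}

    def _bearing_to_upwind(self, obs):
        # ego wind (wx, wy); upwind is opposite the wind vector
        return wrap_angle(math.degrees(math.atan2(obs[1], obs[0])) + 180.0)

    def act(self, state, obs, rng=None, deterministic=True, normalized=False):
        sp = self.spec
        st = dict(state)
        st["t_last"] = 0 if obs[2] > 0 else st["t_last"] + 1
        if sp.controller == "random":
            a = np.array([self.rng.uniform(-1, 1), self.rng.uniform(0, 1)])
        elif sp.controller == "spiral":
            a = np.array([sp.spiral_turn, sp.spiral_move])
        elif sp.controller == "upwind_only":
            err = self._bearing_to_upwind(obs)
            a = np.array([np.clip(err / TURN_PER_STEP, -1, 1), 1.0])
        else:  # cast_and_surge
            if st["t_last"] <= sp.lost_after:
                err = self._bearing_to_upwind(obs)
                a = np.array([np.clip(err / TURN_PER_STEP, -1, 1),
                              sp.surge_speed])
            else:
                st["cast_timer"] += 1
                if st["cast_timer"] >= sp.cast_amplitude:
                    st["cast_sign"] *= -1.0
                    st["cast_timer"] = 0
                # crosswind heading: upwind +/- 90 deg
                err = wrap_angle(self._bearing_to_upwind(obs)
                                 + 90.0 * st["cast_sign"])
                a = np.array([np.clip(err / TURN_PER_STEP, -1, 1), 0.8])
        return a, st, {"h": np.zeros(64), "u": a, "logp": 0.0, "value": 0.0}


def generate_scripted_trajectory(spec: ScriptedAgentSpec,
                                 env: PlumeTrackingEnv,
                                 seed: int | None = None,
                                 episode_id: int = 0,
                                 position=None, heading_deg=None,
                                 reset_kwargs=None,
                                 synthetic_trace: dict | None = None):
    """Run a scripted controller through the real environment.

    Returns ``(episode_df, trace, outcome)``.  If ``synthetic_trace`` is
    given (a planted-structure spec, see :func:`build_synthetic_trace`), the
    returned trace is a synthetic hidden-state matrix constructed from known
    functions of the episode's features instead of the all-zero placeholder.
    """
    policy = ScriptedPolicy(spec, seed=seed)
    df, trace, outcome = run_episode(env, policy, deterministic=True,
                                     episode_id=episode_id,
                                     regime=env.regime,
                                     position=position,
                                     heading_deg=heading_deg,
                                     reset_kwargs=reset_kwargs)
    if synthetic_trace is not None:
        trace = build_synthetic_trace(df, seed=seed, **synthetic_trace)
    return df, trace, outcome


def build_synthetic_trace(episode_df: pd.DataFrame,
                          planted: dict | None = None,
                          n_hidden: int = 64,
                          snr: float = 10.0,
                          seed: int | None = None) -> np.ndarray:
    """Synthetic (T, 64) hidden-state matrix with planted structure.

    ``planted`` maps a feature spec to nothing in particular -- each key is
    embedded into the population through a random read-in vector.  Keys:

    - ``("odour_ewma", w)``: EWMA of sensed odour with window w;
    - ``("odour_enc", w)``:  EWMA of the encounter onset signal;
    - ``"t_last"``:          steps since odour was last perceptible;
    - ``"heading"``:         (cos, sin) of head direction.

    Each planted signal is standardized and broadcast through a random unit
    vector; isotropic Gaussian noise is added at amplitude 1/snr of the
    signal.
    """
    from .behaviour import encounters, time_since_last

    rng = np.random.default_rng(seed)
    T = len(episode_df)
    H = np.zeros((T, n_hidden))
    odour = episode_df["odour"].to_numpy()
    signals = []
    for key in (planted or {}):
        if isinstance(key, tuple) and key[0] == "odour_ewma":
            signals.append(ewma(odour, key[1]))
        elif isinstance(key, tuple) and key[0] == "odour_enc":
            signals.append(ewma(encounters(odour).astype(float), key[1]))
        elif key == "t_last":
            signals.append(time_since_last(odour > 0).astype(float))
        elif key == "heading":
            a = np.radians(episode_df["heading_deg"].to_numpy())
            signals.append(np.cos(a))
            signals.append(np.sin(a))
        else:
            raise ValueError(f"unknown planted key {key!r}")
    for s in signals:
        sd = s.std()
        z = (s - s.mean()) / sd if sd > 0 else s - s.mean()
        v = rng.normal(size=n_hidden)
        v /= np.linalg.norm(v)
        H += np.outer(z, v)
    H += rng.normal(0.0, 1.0 / snr, size=(T, n_hidden))
    return H
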
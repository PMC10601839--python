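import numpy as np
import pandas as pd
import pytest

from plumetrack.agents import RNNPolicy, TrainConfig, train, run_episode
from plumetrack.environment import EnvConfig, PlumeTrackingEnv
from plumetrack.fixtures import ScriptedAgentSpec, ScriptedPolicy

# conditions of the scaled constant-wind training run shared by the
# training-dependent tests: near-source starts, stage-1 curriculum only
SCALED_STEPS = 49152
NEAR_SOURCE = dict(init_x=(0.4, 1.5), init_margin=0.0)


@pytest.fixture(scope="session")
def scaled_trained_policy():
    """One RNN agent PPO-trained at desk scale in constant wind."""
    policy = RNNPolicy(seed=0)
    cfg = TrainConfig(total_steps=SCALED_STEPS, seed=0, stage2_fraction=1.0)
    manifest = train(policy, cfg)
    return policy, cfg, manifest


@pytest.fixture(scope="session")
def upwind_episodes():
    """Scripted upwind-surge episodes through the real environment,
    started inside the plume under constant wind."""
    env = PlumeTrackingEnv("constant", seed=11)
    policy = ScriptedPolicy(ScriptedAgentSpec("upwind_only"))
    snap = env.sim.snapshot()
    dfs = []
    rng = np.random.default_rng(5)
    for i in range(12):
        env.sim.restore(snap)
        x = rng.uniform(2.0, 6.0)
        df, _, _ = run_episode(env, policy, episode_id=i, regime="constant",
                               position=(x, rng.uniform(-0.05, 0.05)),
                               heading_deg=rng.uniform(0, 360))
        dfs.append(df)
    return pd.concat(dfs, ignore_index=True)
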
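import numpy as np
import pytest

from wtrack import cohort
from wtrack.agents import AgentParams, run_ensemble


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject rat-like cohort, shortened for unit tests."""
    spec = cohort.CohortSpec(
        n_subjects=6, n_sessions=6, trials_per_session=40, seed=11,
        min_total=240,
    )
    return cohort.generate_cohort(spec)


@pytest.fixture(scope="session")
def frozen_uniform_ensemble():
    """200 frozen-policy (alpha=0, no bias) agents: uniform over allowed arms."""
    params = AgentParams(variant="memory", alpha=0.0, gamma=0.0,
                         init_bias=0.0, seed=0)
    return run_ensemble(params, 2, 400, 200, base_seed=77)


def uniform_chain_reward_rate() -> float:
    """Exact long-run reward rate of the uniform-over-allowed-arms policy.

    Independent oracle: enumerate the Markov chain over
    (current arm, most-recently-visited outer arm), solve for its
    stationary distribution, and accumulate the expected reward of each
    transition. Mid-session the reward rule depends only on the current
    arm and which outer arm was visited more recently, so four states
    suffice: (1,1), (3,3), (2,1), (2,3).
    """
    states = [(1, 1), (3, 3), (2, 1), (2, 3)]
    idx = {s: i for i, s in enumerate(states)}
    P = np.zeros((4, 4))
    R = np.zeros((4, 4))  # reward of entering column-state from row-state
    for (cur, recent), i in idx.items():
        choices = [a for a in (1, 2, 3) if a != cur]
        for a in choices:
            nxt = (a, recent if a == 2 else a)
            j = idx[nxt]
            P[i, j] += 0.5
            if a == 2:
                R[i, j] = 1.0  # center visits from an outer arm always pay
            elif cur == 2:
                # correct outer arm is the LESS recently visited one
                R[i, j] = 1.0 if a != recent else 0.0
    evals, evecs = np.linalg.eig(P.T)
    pi = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
    pi /= pi.sum()
    return float((pi[:, None] * P * R).sum())
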
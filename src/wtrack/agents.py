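"""Actor-critic REINFORCE agents for the W-maze alternation task.

Each agent chooses the next arm by softmax over propensities
``m(a, s)`` and learns from the TD(0) reward-prediction error
``delta = r + gamma * V(s') - V(s)``. The propensity is a weighted sum of
up to three components, and the model family is defined by which
components are present:

================  ===========================================
variant           propensity components
================  ===========================================
memory            state-based transition table ``b(a, s)``
memory+arm        ``b`` + state-independent arm preference ``bi(a)``
memory+neighbor   ``b`` + neighbor-transition weight ``bn1``
full              all three
================  ===========================================

The state carries the current and immediately preceding arm, i.e. the
memory component has perfect one-step memory — the gating question of
learned working-memory models is deliberately bypassed by always writing
the previous arm into the state.

Every component is updated with the same learning rate ``alpha`` along the
REINFORCE score function ``chi(a = chosen) - p(a)`` scaled by
``alpha * delta``; the critic moves by ``alpha * delta``. Revisiting the
current arm has probability exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel, task
from .task import CENTER_ARM, N_ARMS, N_STATES, START, TaskState

VARIANTS = ("memory", "memory+arm", "memory+neighbor", "full")


def variant_flags(variant: str) -> tuple[bool, bool]:
    """``(has_arm_pref, has_neighbor)`` for a model variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    return (
        variant in ("memory+arm", "full"),
        variant in ("memory+neighbor", "full"),
    )


@dataclass
class AgentParams:
    """Model variant plus its free parameters.

    alpha
        learning rate in [0, 1], shared by every update rule.
    gamma
        temporal discounting factor in [0, 1).
    init_bias
        single non-negative value added at initialization to the
        propensity of going to each outer arm (to ``b`` across all states,
        and to ``bi`` for variants that have it), emulating the outer-arm
        preference animals bring into the task.
    seed
        RNG seed for a single run.
    """

    variant: str = "full"
    alpha: float = 0.1
    gamma: float = 0.9
    init_bias: float = 0.0
    seed: int = 0
    reward_first_center: bool = True

    def __post_init__(self) -> None:
        variant_flags(self.variant)  # validates
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if self.init_bias < 0:
            raise ValueError(f"init_bias must be >= 0, got {self.init_bias}")


@dataclass
class Propensities:
    """Learnable state of an agent: actor components plus the critic."""

    b: np.ndarray  # (13, 3) state-based transition component
    bi: np.ndarray  # (3,) independent arm preference
    bn1: float  # neighbor-transition weight
    V: np.ndarray  # (13,) state values

    def copy(self) -> "Propensities":
        return Propensities(self.b.copy(), self.bi.copy(), self.bn1, self.V.copy())


def init_agent(params: AgentParams) -> Propensities:
    """Fresh propensities with the outer-arm initialization applied."""
    b = np.zeros((N_STATES, N_ARMS))
    b[:, 0] = params.init_bias  # arm 1
    b[:, 2] = params.init_bias  # arm 3; arm 2 stays at 0
    bi = np.zeros(N_ARMS)
    if variant_flags(params.variant)[0]:
        bi[0] = params.init_bias
        bi[2] = params.init_bias
    return Propensities(b=b, bi=bi, bn1=0.0, V=np.zeros(N_STATES))


def total_propensity(
    prop: Propensities, state: TaskState, variant: str = "full"
) -> np.ndarray:
    """Summed propensity ``m(a, s)`` as a 3-vector over arms 1..3.

    The neighbor term adds ``bn1`` to every arm adjacent to the current arm
    (both neighbors from the center, the single neighbor from a track end,
    nothing at the session-start position).
    """
    has_arm, has_neighbor = variant_flags(variant)
    m = prop.b[state.index].copy()
    if has_arm:
        m = m + prop.bi
    if has_neighbor and state.current != START:
        for a in task.ARMS:
            if abs(a - state.current) == 1:
                m[a - 1] += prop.bn1
    return m


def action_distribution(m: np.ndarray, current: int) -> np.ndarray:
    """Softmax of propensities with the current arm forbidden.

    Max-stabilized; the current arm gets probability exactly 0 and the
    remaining entries sum to 1.
    """
    m = np.clip(np.asarray(m, dtype=float), -_kernel._M_CLAMP, _kernel._M_CLAMP)
    allowed = np.ones(N_ARMS, dtype=bool)
    if current != START:
        allowed[current - 1] = False
    p = np.zeros(N_ARMS)
    mmax = m[allowed].max()
    z = 0.0
    # scalar math.exp keeps this path bit-identical to the compiled kernel
    for a in range(N_ARMS):
        if allowed[a]:
            p[a] = math.exp(m[a] - mmax)
            z += p[a]
    p /= z
    return p


def td_error(r: float, v_curr: float, v_next: float, gamma: float) -> float:
    """TD(0) reward-prediction error ``delta = r + gamma*v_next - v_curr``."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must be in [0, 1), got {gamma}")
    return r + gamma * v_next - v_curr


def apply_update(
    prop: Propensities,
    state: TaskState,
    chosen: int,
    policy: np.ndarray,
    delta: float,
    alpha: float,
    variant: str = "full",
) -> Propensities:
    """One actor-critic update, in place; returns ``prop``.

    For every arm ``a`` the score function is ``chi(a = chosen) - p(a)``.
    The current state's ``b`` row, the whole of ``bi``, and ``bn1`` (through
    the summed score of the current arm's neighbors) move by
    ``alpha * delta`` times their score; ``V`` of the current state moves by
    ``alpha * delta``. Components absent from the variant are untouched.
    """
    has_arm, has_neighbor = variant_flags(variant)
    sidx = state.index
    chi = np.zeros(N_ARMS)
    chi[chosen - 1] = 1.0
    score = chi - policy
    prop.b[sidx] += alpha * delta * score
    if has_arm:
        prop.bi += alpha * delta * score
    if has_neighbor and state.current != START:
        neighbor = np.array(
            [abs(a - state.current) == 1 for a in task.ARMS], dtype=float
        )
        prop.bn1 += alpha * delta * float(score @ neighbor)
    prop.V[sidx] += alpha * delta
    return prop


def _session_lengths(n_sessions: int, trials_per_session) -> np.ndarray:
    if np.isscalar(trials_per_session):
        lengths = np.full(n_sessions, int(trials_per_session), dtype=np.int64)
    else:
        lengths = np.asarray(trials_per_session, dtype=np.int64)
        if lengths.shape[0] != n_sessions:
            raise ValueError(
                f"expected {n_sessions} session lengths, got {lengths.shape[0]}"
            )
    if (lengths <= 0).any():
        raise ValueError("session lengths must be positive")
    return lengths


_TT_NAMES = np.array([task.INBOUND, task.OUTBOUND])


def records_to_frame(arm, reward, ttype, err, session, sstart) -> pd.DataFrame:
    """Assemble kernel output arrays into the shared log schema."""
    return pd.DataFrame(
        {
            "session": session.astype(int),
            "visit_index": np.arange(arm.shape[0]),
            "arm": arm.astype(int),
            "reward": reward.astype(int),
            "trial_type": _TT_NAMES[ttype],
            "is_error": err.astype(int),
            "session_start": sstart.astype(bool),
        }
    )


def run_agent(
    params: AgentParams,
    n_sessions: int,
    trials_per_session,
) -> pd.DataFrame:
    """Simulate one agent and return its visit log.

    Propensities persist across the ``n_sessions`` sessions; location and
    outer-arm history reset at each session start. The log has one row per
    well visit with columns ``session`` (1-based), ``visit_index``
    (0-based, global), ``arm``, ``reward``, ``trial_type``, ``is_error``
    and ``session_start``.
    """
    lengths = _session_lengths(n_sessions, trials_per_session)
    n_trials = int(lengths.sum())
    uniforms = np.random.default_rng(params.seed).random(n_trials)
    has_arm, has_neighbor = variant_flags(params.variant)
    outs = [
        np.zeros(n_trials, dtype=np.int8),
        np.zeros(n_trials, dtype=np.int8),
        np.zeros(n_trials, dtype=np.int8),
        np.zeros(n_trials, dtype=np.int8),
        np.zeros(n_trials, dtype=np.int16),
        np.zeros(n_trials, dtype=np.bool_),
    ]
    _kernel.simulate_one(
        params.alpha,
        params.gamma,
        params.init_bias,
        has_arm,
        has_neighbor,
        params.reward_first_center,
        lengths,
        uniforms,
        *outs,
    )
    return records_to_frame(*outs)


def run_agent_reference(
    params: AgentParams,
    n_sessions: int,
    trials_per_session,
) -> pd.DataFrame:
    """Step-by-step runner built from the public primitives.

    Functionally identical to :func:`run_agent` (the suite asserts
    bit-identical logs); kept as the legible specification of the
    simulation loop and as the consistency oracle for the compiled kernel.
    """
    lengths = _session_lengths(n_sessions, trials_per_session)
    n_trials = int(lengths.sum())
    uniforms = np.random.default_rng(params.seed).random(n_trials)
    prop = init_agent(params)
    rows = []
    t_global = 0
    for s, n_sess in enumerate(lengths, start=1):
        state = TaskState(START, START)
        history = task.SessionHistory()
        for t in range(int(n_sess)):
            m = total_propensity(prop, state, params.variant)
            policy = action_distribution(m, state.current)
            u = uniforms[t_global]
            choice = 1 if u < policy[0] else (2 if u < policy[0] + policy[1] else 3)
            r = task.reward_rule(
                state,
                history,
                choice,
                reward_first_center=params.reward_first_center,
            )
            ttype, err = task.classify_trial(state, choice, r)
            next_state = TaskState(state.current, choice)
            v_next = 0.0 if t == n_sess - 1 else prop.V[next_state.index]
            delta = td_error(r, prop.V[state.index], v_next, params.gamma)
            apply_update(
                prop, state, choice, policy, delta, params.alpha, params.variant
            )
            rows.append((s, t_global, choice, r, ttype, err, t == 0))
            history.record(choice)
            state = next_state
            t_global += 1
    return pd.DataFrame(
        rows,
        columns=[
            "session",
            "visit_index",
            "arm",
            "reward",
            "trial_type",
            "is_error",
            "session_start",
        ],
    )


@dataclass
class EnsembleRecords:
    """Per-trial records of an ensemble, one row per repeat."""

    arm: np.ndarray
    reward: np.ndarray
    trial_type: np.ndarray  # 0 inbound, 1 outbound
    is_error: np.ndarray
    session: np.ndarray
    session_start: np.ndarray
    session_lengths: np.ndarray = field(default=None)

    @property
    def n_repeats(self) -> int:
        return self.arm.shape[0]

    @property
    def n_trials(self) -> int:
        return self.arm.shape[1]

    def log(self, i: int) -> pd.DataFrame:
        return records_to_frame(
            self.arm[i],
            self.reward[i],
            self.trial_type[i],
            self.is_error[i],
            self.session[i],
            self.session_start[i],
        )


def run_ensemble(
    params: AgentParams,
    n_sessions: int,
    trials_per_session,
    n_repeats: int,
    base_seed: int | None = None,
) -> EnsembleRecords:
    """Simulate ``n_repeats`` independent agents sharing the parameters.

    Repeat ``i`` is seeded ``base_seed + i`` (``base_seed`` defaults to
    ``params.seed``), so repeat streams are reproducible and identical
    across calls — the common-random-number contract the fitting
    objectives rely on. Repeat ``i`` is bit-identical to
    ``run_agent(params with seed base_seed + i, ...)``.
    """
    if base_seed is None:
        base_seed = params.seed
    lengths = _session_lengths(n_sessions, trials_per_session)
    uniforms = _kernel.ensemble_uniforms(base_seed, n_repeats, int(lengths.sum()))
    has_arm, has_neighbor = variant_flags(params.variant)
    out = _kernel.simulate_many(
        params.alpha,
        params.gamma,
        params.init_bias,
        has_arm,
        has_neighbor,
        params.reward_first_center,
        lengths,
        uniforms,
    )
    return EnsembleRecords(*out, session_lengths=lengths)
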
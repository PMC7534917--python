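"""Inner simulation loop for the actor-critic alternation agents.

The loop is written as scalar Python compiled with numba so that the
annealing fits (hundreds of 200-repeat ensembles) stay cheap. The
uncompiled function (``.py_func``) is the readable reference path; the test
suite asserts bit-identical trajectories between the two, and between this
kernel and the step-by-step composition of the public primitives in
:mod:`wtrack.agents`. All scalar transcendentals go through :mod:`math` so
compiled and interpreted runs share the same libm calls.

State indexing matches :func:`wtrack.task.state_index`: the nine
(previous, current) arm pairs row-major, then (START, arm), then
(START, START) at index 12. Arms are 1..3, START is 0.

Per trial exactly one uniform random draw is consumed (for the arm
sample), so ensembles driven by the same uniform arrays are aligned across
parameter sets (common random numbers).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: trial-type codes in the output arrays
TT_INBOUND = 0
TT_OUTBOUND = 1

#: propensity clamp; softmax is max-stabilized so this never binds in
#: fitted regimes, it only guards runaway parameters during annealing.
_M_CLAMP = 500.0


@njit(cache=True)
def _sidx(prev: int, cur: int) -> int:
    if prev == 0 and cur == 0:
        return 12
    if prev == 0:
        return 9 + cur - 1
    return (prev - 1) * 3 + (cur - 1)


@njit(cache=True)
def simulate_one(
    alpha: float,
    gamma: float,
    init_bias: float,
    has_arm_pref: bool,
    has_neighbor: bool,
    reward_first_center: bool,
    session_lengths: np.ndarray,
    uniforms: np.ndarray,
    arm_out: np.ndarray,
    reward_out: np.ndarray,
    ttype_out: np.ndarray,
    err_out: np.ndarray,
    session_out: np.ndarray,
    sstart_out: np.ndarray,
) -> None:
    """Simulate one agent run, writing per-trial records into the outputs.

    Propensity tables persist across sessions; the location resets to the
    session-start state and the outer-arm visit history resets at every
    session boundary. The last trial of a session is treated as terminal
    (zero successor value) because sessions end on an external clock.
    """
    b = np.zeros((13, 3))
    b[:, 0] = init_bias
    b[:, 2] = init_bias
    bi = np.zeros(3)
    if has_arm_pref:
        bi[0] = init_bias
        bi[2] = init_bias
    bn1 = 0.0
    V = np.zeros(13)

    m = np.zeros(3)
    p = np.zeros(3)

    t_global = 0
    for s in range(session_lengths.shape[0]):
        prev = 0
        cur = 0
        last1 = -1  # within-session visit index of last arm-1 visit
        last3 = -1
        n_sess = session_lengths[s]
        for t in range(n_sess):
            sidx = _sidx(prev, cur)

            # total propensity m(a, s)
            for a in range(3):
                m[a] = b[sidx, a]
                if has_arm_pref:
                    m[a] += bi[a]
            if has_neighbor and cur != 0:
                for a in range(3):
                    if abs((a + 1) - cur) == 1:
                        m[a] += bn1
            for a in range(3):
                if m[a] > _M_CLAMP:
                    m[a] = _M_CLAMP
                elif m[a] < -_M_CLAMP:
                    m[a] = -_M_CLAMP

            # softmax with the current arm forbidden
            mmax = -1.0e300
            for a in range(3):
                if a + 1 != cur and m[a] > mmax:
                    mmax = m[a]
            z = 0.0
            for a in range(3):
                if a + 1 == cur:
                    p[a] = 0.0
                else:
                    p[a] = math.exp(m[a] - mmax)
                    z += p[a]
            for a in range(3):
                p[a] /= z

            # sample the visited arm: one uniform draw per trial
            u = uniforms[t_global]
            if u < p[0]:
                choice = 1
            elif u < p[0] + p[1]:
                choice = 2
            else:
                choice = 3

            # reward delivery
            if cur == 0:
                r = 1 if (choice == 2 and reward_first_center) else 0
            elif cur != 2:
                r = 1 if choice == 2 else 0
            else:
                if last1 < 0 and last3 < 0:
                    r = 1  # center was the session's first visit
                else:
                    correct = 1 if last1 < last3 else 3
                    r = 1 if choice == correct else 0

            # trial taxonomy
            if cur == 2:
                tt = TT_OUTBOUND
                err = 1 - r
            else:
                tt = TT_INBOUND
                err = 1 if choice != 2 else 0

            # TD error with terminal session end
            nidx = _sidx(cur, choice)
            v_next = V[nidx] if t < n_sess - 1 else 0.0
            delta = r + gamma * v_next - V[sidx]

            # REINFORCE actor updates and critic update
            gn = 0.0
            for a in range(3):
                chi = 1.0 if a + 1 == choice else 0.0
                g = alpha * delta * (chi - p[a])
                b[sidx, a] += g
                if has_arm_pref:
                    bi[a] += g
                if has_neighbor and cur != 0 and abs((a + 1) - cur) == 1:
                    gn += chi - p[a]
            if has_neighbor:
                bn1 += alpha * delta * gn
            V[sidx] += alpha * delta

            arm_out[t_global] = choice
            reward_out[t_global] = r
            ttype_out[t_global] = tt
            err_out[t_global] = err
            session_out[t_global] = s + 1
            sstart_out[t_global] = t == 0

            if choice == 1:
                last1 = t
            elif choice == 3:
                last3 = t
            prev = cur
            cur = choice
            t_global += 1


@njit(cache=True)
def simulate_many(
    alpha: float,
    gamma: float,
    init_bias: float,
    has_arm_pref: bool,
    has_neighbor: bool,
    reward_first_center: bool,
    session_lengths: np.ndarray,
    uniforms: np.ndarray,
) -> tuple:
    """Run ``uniforms.shape[0]`` independent repeats; returns 2-D records."""
    n_rep, n_trials = uniforms.shape
    arm = np.zeros((n_rep, n_trials), dtype=np.int8)
    reward = np.zeros((n_rep, n_trials), dtype=np.int8)
    ttype = np.zeros((n_rep, n_trials), dtype=np.int8)
    err = np.zeros((n_rep, n_trials), dtype=np.int8)
    session = np.zeros((n_rep, n_trials), dtype=np.int16)
    sstart = np.zeros((n_rep, n_trials), dtype=np.bool_)
    for i in range(n_rep):
        simulate_one(
            alpha,
            gamma,
            init_bias,
            has_arm_pref,
            has_neighbor,
            reward_first_center,
            session_lengths,
            uniforms[i],
            arm[i],
            reward[i],
            ttype[i],
            err[i],
            session[i],
            sstart[i],
        )
    return arm, reward, ttype, err, session, sstart


def ensemble_uniforms(base_seed: int, n_repeats: int, n_trials: int) -> np.ndarray:
    """Uniform draws for a repeat ensemble, one stream per repeat.

    Repeat ``i`` uses ``numpy``'s default bit generator seeded with
    ``base_seed + i``, so the same ``(base_seed, n_repeats, n_trials)``
    always yields the same draws — the common-random-number device used by
    the fitting objectives.
    """
    out = np.empty((n_repeats, n_trials))
    for i in range(n_repeats):
        out[i] = np.random.default_rng(base_seed + i).random(n_trials)
    return out
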
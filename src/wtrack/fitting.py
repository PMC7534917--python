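"""Parameter estimation for the alternation agents.

Fitting is distance-based: a candidate parameter vector is scored by
simulating a 200-repeat agent ensemble and measuring the root-mean-square
(RMS) difference between the ensemble's smoothed behavioral curves and the
target's (or, for the reward-maximizing objective, the negative of the
ensemble's total reward). Four objectives are supported:

``avg_reward_rms``
    RMS between the ensemble reward curve and the target cohort's average
    reward curve over the fitting window.
``max_reward``
    negative mean total reward per repeat (no behavioral target).
``avg_error_rms``
    RMS(inbound error curve) + RMS(outbound error curve) against the
    target cohort's average error curves, equally weighted.
``individual_error_rms``
    the same error distance against a single subject's curves, with the
    initialization magnitude as a third free parameter.

Every candidate is evaluated with the *same* per-repeat seed vector
(common random numbers), so objective differences reflect parameters
rather than sampling noise and the objective is a deterministic function
of the candidate. Minimization is by simulated annealing restarted from
several independent starting points; the best restart wins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import metrics
from .agents import AgentParams, run_ensemble
from .metrics import (
    BehaviorCurve,
    error_curves,
    error_curves_from_matrices,
    reward_curve,
    reward_curve_from_matrix,
)

OBJECTIVES = ("avg_reward_rms", "max_reward", "avg_error_rms",
              "individual_error_rms")

DEFAULT_BOUNDS = {
    "alpha": (0.0, 1.0),
    "gamma": (0.0, 0.9999),
    "init_bias": (0.0, 5.0),
}


@dataclass
class AnnealConfig:
    """Simulated-annealing schedule (geometric cooling).

    The initial temperature is the objective spread over ``n_temper``
    random probes divided by ``temper_divisor`` (so roughly the scale of
    local objective differences rather than the global range); temperature
    and proposal width both decay geometrically, the proposal width down
    to ``min_scale`` of each bound's range so late proposals can resolve
    narrow valleys (e.g. the discount factor near 1).
    """

    n_iters: int = 2000
    cooling: float = 0.92
    cool_every: int = 25
    proposal_scale: float = 0.15  # fraction of each bound's range
    min_scale: float = 0.005
    n_temper: int = 8
    temper_divisor: float = 10.0
    polish_maxfev: int = 80  # Nelder-Mead refinement of each restart's best


@dataclass
class FitSpec:
    """What to fit, against what, and with which simulation budget."""

    objective: str = "avg_reward_rms"
    variant: str = "memory"
    n_repeats: int = 200
    window: int = 1012
    n_restarts: int = 4
    base_seed: int = 0
    n_sessions: int = 15
    trials_per_session: object = 68
    init_bias: float | None = None  # fixed value for the 2-parameter modes
    reward_first_center: bool = True
    anneal: AnnealConfig = field(default_factory=AnnealConfig)

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(
                f"unknown objective {self.objective!r}; choose from {OBJECTIVES}"
            )
        if self.n_repeats < 1 or self.window < 1:
            raise ValueError("n_repeats and window must be positive")

    @property
    def n_params(self) -> int:
        return 3 if self.objective == "individual_error_rms" else 2


@dataclass
class FitResult:
    """Best parameters found, with the per-restart diagnostics."""

    params: AgentParams
    objective_value: float
    restarts: list
    converged: bool
    spec: FitSpec | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "params": {
                "variant": self.params.variant,
                "alpha": self.params.alpha,
                "gamma": self.params.gamma,
                "init_bias": self.params.init_bias,
            },
            "objective_value": self.objective_value,
            "converged": self.converged,
            "restarts": self.restarts,
        }
        if self.spec is not None:
            spec = asdict(self.spec)
            spec["trials_per_session"] = np.asarray(
                self.spec.trials_per_session
            ).tolist()
            payload["spec"] = spec
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _candidate_params(candidate, spec: FitSpec) -> AgentParams:
    candidate = np.asarray(candidate, dtype=float)
    if spec.n_params == 3:
        init_bias = float(candidate[2])
    else:
        if spec.init_bias is None:
            raise ValueError(
                "init_bias must be set on the spec for 2-parameter objectives"
            )
        init_bias = float(spec.init_bias)
    return AgentParams(
        variant=spec.variant,
        alpha=float(candidate[0]),
        gamma=float(candidate[1]),
        init_bias=init_bias,
        seed=spec.base_seed,
        reward_first_center=spec.reward_first_center,
    )


def simulate_ensemble(params: AgentParams, spec: FitSpec, kinds=("reward",)):
    """Common-random-number ensemble curves for a candidate parameter set.

    Repeat ``i`` is always seeded ``spec.base_seed + i``, so two calls with
    the same spec — regardless of the candidate — share their random draws.
    Returns a dict with the requested curve kinds (``"reward"`` and/or
    ``"errors"``) plus the raw records under ``"records"``.
    """
    rec = run_ensemble(
        params,
        spec.n_sessions,
        spec.trials_per_session,
        spec.n_repeats,
        base_seed=spec.base_seed,
    )
    window = min(spec.window, rec.n_trials)
    out = {"records": rec}
    if "reward" in kinds:
        out["reward"] = reward_curve_from_matrix(rec.reward, window)
    if "errors" in kinds:
        inb, outb = error_curves_from_matrices(
            rec.trial_type, rec.is_error, window
        )
        out["inbound_error"] = inb
        out["outbound_error"] = outb
    return out


def objective_value(candidate, target, spec: FitSpec) -> float:
    """Score one candidate under the spec's objective (lower is better).

    ``target`` is a dict of :class:`BehaviorCurve` (``"reward"`` or
    ``"inbound_error"``/``"outbound_error"``) for the RMS objectives and
    ``None`` for ``max_reward``.
    """
    params = _candidate_params(candidate, spec)
    if spec.objective == "max_reward":
        rec = run_ensemble(
            params, spec.n_sessions, spec.trials_per_session, spec.n_repeats,
            base_seed=spec.base_seed,
        )
        window = min(spec.window, rec.n_trials)
        return -float(rec.reward[:, :window].sum(axis=1).mean())
    if spec.objective == "avg_reward_rms":
        sim = simulate_ensemble(params, spec, kinds=("reward",))
        tgt = target["reward"].values
        win = min(len(tgt), len(sim["reward"]))
        diff = sim["reward"].values[:win] - tgt[:win]
        return float(np.sqrt(np.mean(diff**2)))
    # error-curve objectives, inbound + outbound equally weighted
    sim = simulate_ensemble(params, spec, kinds=("errors",))
    total = 0.0
    for kind in ("inbound_error", "outbound_error"):
        tgt = target[kind].values
        win = min(len(tgt), len(sim[kind]))
        diff = sim[kind].values[:win] - tgt[:win]
        total += float(np.sqrt(np.mean(diff**2)))
    return total


def _bounds_for(spec: FitSpec, bounds=None):
    if bounds is not None:
        return [tuple(b) for b in bounds]
    names = ("alpha", "gamma", "init_bias")[: spec.n_params]
    return [DEFAULT_BOUNDS[n] for n in names]


def anneal(objective, bounds, spec: FitSpec) -> FitResult:
    """Minimize ``objective`` by restarted simulated annealing.

    ``spec.n_restarts`` independent runs start from points drawn uniformly
    within ``bounds``; proposals are Gaussian steps scaled to the bound
    ranges (clipped back inside), the temperature cools geometrically, and
    the initial temperature is set from the objective spread over a few
    random probes. Fully deterministic given ``spec.base_seed``; the best
    evaluation ever seen in each restart is retained and the best restart
    wins.
    """
    bounds = [tuple(b) for b in bounds]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    span = hi - lo
    cfg = spec.anneal

    best_x, best_f = None, np.inf
    restarts = []
    for k in range(spec.n_restarts):
        rng = np.random.default_rng((spec.base_seed + 7919 * (k + 1)) % 2**31)
        x = lo + span * rng.random(len(bounds))
        f = objective(x)
        rb_x, rb_f = x.copy(), f
        probes = []
        for _ in range(cfg.n_temper):
            px = lo + span * rng.random(len(bounds))
            pf = objective(px)
            probes.append(pf)
            if pf < rb_f:
                rb_x, rb_f = px.copy(), pf
        temp = float(np.std(probes + [f])) / cfg.temper_divisor
        if not np.isfinite(temp) or temp == 0:
            temp = max(abs(f), 1.0) * 0.01
        scale = cfg.proposal_scale
        n_evals = 1 + cfg.n_temper
        for it in range(cfg.n_iters):
            prop = np.clip(x + rng.normal(0.0, scale * span), lo, hi)
            fp = objective(prop)
            n_evals += 1
            if fp < f or rng.random() < np.exp(-(fp - f) / max(temp, 1e-300)):
                x, f = prop, fp
            if f < rb_f:
                rb_x, rb_f = x.copy(), f
            if (it + 1) % cfg.cool_every == 0:
                temp *= cfg.cooling
                scale = max(scale * cfg.cooling, cfg.min_scale)
        if cfg.polish_maxfev > 0:
            # deterministic local refinement of the restart's best point
            from scipy.optimize import minimize

            res = minimize(
                lambda z: objective(np.clip(z, lo, hi)),
                rb_x,
                method="Nelder-Mead",
                options={"maxfev": cfg.polish_maxfev, "xatol": 1e-6,
                         "fatol": 1e-12},
            )
            n_evals += res.nfev
            if res.fun < rb_f:
                rb_x, rb_f = np.clip(res.x, lo, hi), float(res.fun)
        restarts.append(
            {"best_x": rb_x.tolist(), "best_f": float(rb_f), "n_evals": n_evals}
        )
        if rb_f < best_f:
            best_x, best_f = rb_x, rb_f
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError(f"all annealing restarts failed: {restarts}")
    return FitResult(
        params=_candidate_params(best_x, spec),
        objective_value=float(best_f),
        restarts=restarts,
        converged=bool(np.isfinite(best_f)),
        spec=spec,
    )


def session_lengths_from_logs(logs, n_sessions: int) -> np.ndarray:
    """Per-session visit counts matched to a target cohort (rounded mean)."""
    counts = np.zeros((len(logs), n_sessions))
    for i, log in enumerate(logs):
        per = log.groupby("session").size()
        for s in range(1, n_sessions + 1):
            counts[i, s - 1] = per.get(s, 0)
    lengths = np.maximum(np.rint(counts.mean(axis=0)).astype(int), 1)
    return lengths


def calibrate_init_bias_to_rate(
    target_rate: float, spec: FitSpec, n_first: int = 25
) -> float:
    """Initialization magnitude matching the target's initial reward rate.

    Bisects the outer-arm initialization of a frozen-policy (zero learning
    rate) ensemble until its mean reward over the first ``n_first`` visits
    matches ``target_rate``; the frozen policy isolates the initial
    conditions from learning. The rate is monotone decreasing in the bias
    (stronger outer preference delays the first rewarded center visits).
    """

    def rate(bias: float) -> float:
        params = AgentParams(
            variant=spec.variant, alpha=0.0, gamma=0.0, init_bias=bias,
            seed=spec.base_seed, reward_first_center=spec.reward_first_center,
        )
        rec = run_ensemble(
            params, spec.n_sessions, spec.trials_per_session, spec.n_repeats,
            base_seed=spec.base_seed,
        )
        return float(rec.reward[:, :n_first].mean())

    lo, hi = 0.0, DEFAULT_BOUNDS["init_bias"][1]
    if rate(lo) <= target_rate:
        return lo
    if rate(hi) >= target_rate:
        warnings.warn("target initial reward rate below the frozen-policy floor")
        return hi
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if rate(mid) > target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_average(target_logs, spec: FitSpec, bounds=None) -> FitResult:
    """Fit (alpha, gamma) to a cohort's average behavior.

    The fitting window is the largest visit count all subjects reach,
    capped at ``spec.window``; per-session trial counts of the simulated
    ensembles match the cohort's. Unless the spec fixes it, the
    initialization magnitude is calibrated so the frozen-policy ensemble
    reproduces the cohort's reward rate over the first 25 visits.
    """
    target_logs = list(target_logs)
    window = min(min(len(log) for log in target_logs), spec.window)
    spec.window = window
    spec.trials_per_session = session_lengths_from_logs(
        target_logs, spec.n_sessions
    )
    if spec.objective == "avg_reward_rms":
        target = {"reward": reward_curve(target_logs, window)}
    elif spec.objective == "avg_error_rms":
        inb, outb = error_curves(target_logs, window)
        target = {"inbound_error": inb, "outbound_error": outb}
    elif spec.objective == "max_reward":
        target = None
    else:
        raise ValueError(
            "individual_error_rms requires fit_individual on a single log"
        )
    if spec.init_bias is None:
        first25 = float(
            np.mean([log["reward"].to_numpy()[:25].mean() for log in target_logs])
        )
        spec.init_bias = calibrate_init_bias_to_rate(first25, spec)
    return anneal(
        lambda x: objective_value(x, target, spec), _bounds_for(spec, bounds),
        spec,
    )


def fit_individual(subject_log: pd.DataFrame, spec: FitSpec,
                   bounds=None) -> FitResult:
    """Fit (alpha, gamma, init_bias) to a single subject's error curves."""
    if spec.objective != "individual_error_rms":
        raise ValueError("fit_individual uses the individual_error_rms objective")
    window = min(len(subject_log), spec.window)
    spec.window = window
    spec.trials_per_session = session_lengths_from_logs(
        [subject_log], spec.n_sessions
    )
    inb, outb = error_curves([subject_log], window)
    target = {"inbound_error": inb, "outbound_error": outb}
    return anneal(
        lambda x: objective_value(x, target, spec), _bounds_for(spec, bounds),
        spec,
    )
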
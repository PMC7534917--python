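"""Behavioral analysis: smoothed performance curves and exponential fits.

All curves live on the well-visit axis (one point per arrival at a reward
well). Binary outcome sequences are smoothed with a Gaussian kernel of
SD 2.25 — in units of well visits for reward curves, and in units of
same-type trials for inbound/outbound error curves, which are then
linearly interpolated back onto the well-visit axis. Each subject (or
model repeat) is smoothed individually before averaging; the spread is the
standard error of the mean across traces.

Learning speed is summarized by least-squares fits of
``y(t) = offset + scale * exp(-t / tau)`` to the first part of a curve,
with a 99% confidence interval on the trial constant ``tau``; two fits are
called different (p < 0.01) only when each tau lies outside the other's
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter1d

from . import task

GAUSSIAN_SD = 2.25

CURVE_KINDS = ("reward", "inbound_error", "outbound_error")


@dataclass
class BehaviorCurve:
    """Across-trace mean of a per-well-visit probability, with its SEM."""

    values: np.ndarray
    sem: np.ndarray
    kind: str
    n_traces: int

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "visit": np.arange(len(self.values)),
                "value": self.values,
                "sem": self.sem,
                "kind": self.kind,
            }
        )


@dataclass
class ExpFitResult:
    """Exponential fit ``offset + scale * exp(-t/tau)`` of a curve."""

    scale: float
    offset: float
    tau: float
    tau_ci99: tuple[float, float]
    tau_se: float
    degenerate: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.tau_ci99
        flag = " (degenerate)" if self.degenerate else ""
        return f"tau={self.tau:.1f} trials, 99% CI ({lo:.1f}, {hi:.1f}){flag}"


def smooth_binary(seq, sd: float = GAUSSIAN_SD) -> np.ndarray:
    """Gaussian smoothing of a binary outcome sequence.

    ``sd`` is in sequence-index units. Edges are reflect-padded, which
    keeps the output within [0, 1] and preserves the mean of constant
    sequences.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 1 or seq.size == 0:
        raise ValueError("need a non-empty 1-D sequence")
    return gaussian_filter1d(seq, sigma=sd, mode="reflect")


def _as_reward_array(log) -> np.ndarray:
    if isinstance(log, pd.DataFrame):
        return log["reward"].to_numpy(dtype=float)
    return np.asarray(log, dtype=float)


def _mean_sem(traces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = traces.mean(axis=0)
    if traces.shape[0] > 1:
        sem = traces.std(axis=0, ddof=1) / np.sqrt(traces.shape[0])
    else:
        sem = np.zeros_like(mean)
    return mean, sem


def reward_curve(logs, window: int, sd: float = GAUSSIAN_SD) -> BehaviorCurve:
    """Across-subject reward-probability curve over the first ``window`` visits.

    Each subject's binary reward sequence is smoothed individually, then
    truncated to ``window`` and averaged; logs shorter than ``window`` are
    excluded with a warning.
    """
    traces = []
    for i, log in enumerate(logs):
        r = _as_reward_array(log)
        if r.size < window:
            warnings.warn(
                f"log {i} has {r.size} < {window} visits; excluded from curve"
            )
            continue
        traces.append(smooth_binary(r, sd)[:window])
    if not traces:
        raise ValueError("no log reaches the analysis window")
    mean, sem = _mean_sem(np.asarray(traces))
    return BehaviorCurve(mean, sem, "reward", len(traces))


def reward_curve_from_matrix(reward: np.ndarray, window: int,
                             sd: float = GAUSSIAN_SD) -> BehaviorCurve:
    """Like :func:`reward_curve` for an (n_traces, n_visits) 0/1 matrix."""
    if reward.shape[1] < window:
        raise ValueError("matrix shorter than the analysis window")
    traces = gaussian_filter1d(
        reward.astype(float), sigma=sd, axis=1, mode="reflect"
    )[:, :window]
    mean, sem = _mean_sem(traces)
    return BehaviorCurve(mean, sem, "reward", reward.shape[0])


def error_trace(
    type_mask: np.ndarray,
    is_error: np.ndarray,
    window: int,
    sd: float = GAUSSIAN_SD,
    min_trials: int = 3,
) -> np.ndarray | None:
    """Single-trace error curve interpolated onto the well-visit axis.

    The error indicator of the trials selected by ``type_mask`` is smoothed
    with SD ``sd`` in units of that trial type's own index, the smoothed
    values are placed at the trials' well-visit positions, and the curve is
    linearly interpolated onto visits ``0..window-1`` (held constant before
    the first and after the last trial of the type). Returns None when the
    trace has fewer than ``min_trials`` trials of the type.
    """
    idx = np.flatnonzero(type_mask)
    if idx.size < min_trials:
        return None
    smoothed = smooth_binary(is_error[idx], sd)
    return np.interp(np.arange(window), idx, smoothed)


def _log_type_arrays(log: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    tt = log["trial_type"].to_numpy()
    return (tt == task.INBOUND), log["is_error"].to_numpy(dtype=float)


def error_curves(
    logs, window: int | None = None, sd: float = GAUSSIAN_SD
) -> tuple[BehaviorCurve, BehaviorCurve]:
    """``(inbound, outbound)`` error curves averaged across subjects.

    Session-start trials count as inbound, which is what produces the
    characteristic bumps at session boundaries (animals rarely start at the
    center arm). Subjects with fewer than 3 trials of a type are excluded
    from that curve with a warning.
    """
    logs = list(logs)
    if window is None:
        window = min(len(log) for log in logs)
    curves = []
    for kind, want_inbound in (("inbound_error", True), ("outbound_error", False)):
        traces = []
        for i, log in enumerate(logs):
            inbound_mask, err = _log_type_arrays(log)
            mask = inbound_mask if want_inbound else ~inbound_mask
            trace = error_trace(mask[:window], err[:window], window, sd)
            if trace is None:
                warnings.warn(f"log {i} has < 3 {kind} trials; excluded")
                continue
            traces.append(trace)
        if not traces:
            raise ValueError(f"no subject contributes to the {kind} curve")
        mean, sem = _mean_sem(np.asarray(traces))
        curves.append(BehaviorCurve(mean, sem, kind, len(traces)))
    return curves[0], curves[1]


def error_curves_from_matrices(
    trial_type: np.ndarray,
    is_error: np.ndarray,
    window: int,
    sd: float = GAUSSIAN_SD,
) -> tuple[BehaviorCurve, BehaviorCurve]:
    """Ensemble version of :func:`error_curves` on kernel record matrices."""
    from . import _kernel

    curves = []
    for kind, code in (("inbound_error", _kernel.TT_INBOUND),
                       ("outbound_error", _kernel.TT_OUTBOUND)):
        traces = []
        for i in range(trial_type.shape[0]):
            trace = error_trace(
                trial_type[i, :window] == code,
                is_error[i, :window].astype(float),
                window,
                sd,
            )
            if trace is not None:
                traces.append(trace)
        mean, sem = _mean_sem(np.asarray(traces))
        curves.append(BehaviorCurve(mean, sem, kind, len(traces)))
    return curves[0], curves[1]


def first_visits_probability(logs, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Arm-visit probabilities over each subject's first ``k`` well visits.

    Returns ``(mean, sem)`` 3-vectors over arms 1..3; the mean sums to 1.
    """
    freqs = []
    for log in logs:
        arms = log["arm"].to_numpy() if isinstance(log, pd.DataFrame) else np.asarray(log)
        if arms.size < k:
            raise ValueError(f"log has {arms.size} < {k} visits")
        first = arms[:k]
        freqs.append([(first == a).mean() for a in task.ARMS])
    mean, sem = _mean_sem(np.asarray(freqs))
    return mean, sem


def _exp_model(t, offset, scale, tau):
    return offset + scale * np.exp(-t / tau)


def fit_exponential(
    curve,
    window: int = 300,
    constrain: tuple[float, float] | None = None,
    ci_method: str = "covariance",
    n_boot: int = 200,
    seed: int = 0,
) -> ExpFitResult:
    """Fit ``y = offset + scale * exp(-t/tau)`` to the first ``window`` points.

    ``constrain=(scale, offset)`` freezes those two parameters and fits only
    ``tau`` (used when comparing decay constants across curves whose
    asymptotes differ). The 99% CI on ``tau`` comes from the fit covariance
    with a t critical value on the residual degrees of freedom
    (``ci_method="covariance"``), or from a residual bootstrap
    (``ci_method="bootstrap"``).

    A curve with no appreciable decay yields a ``degenerate`` result (tau
    unidentifiable: unbounded CI) rather than an exception.
    """
    y = np.asarray(curve.values if isinstance(curve, BehaviorCurve) else curve,
                   dtype=float)
    if window > y.size:
        raise ValueError(f"window {window} exceeds curve length {y.size}")
    y = y[:window]
    t = np.arange(window, dtype=float)

    tail = y[-max(window // 6, 5):].mean()
    p0_tau = max(window / 5.0, 2.0)

    def _degenerate(offset, scale, tau):
        return ExpFitResult(scale, offset, tau, (0.0, np.inf), np.inf,
                            degenerate=True)

    try:
        if constrain is not None:
            scale0, offset0 = constrain

            def model(tt, tau):
                return _exp_model(tt, offset0, scale0, tau)

            popt, pcov = optimize.curve_fit(
                model, t, y, p0=[p0_tau], bounds=([1e-6], [1e7]), maxfev=20000
            )
            offset, scale, tau = offset0, scale0, float(popt[0])
            var_tau = float(pcov[0, 0])
            dof = window - 1
        else:
            popt, pcov = optimize.curve_fit(
                _exp_model,
                t,
                y,
                p0=[tail, y[0] - tail, p0_tau],
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e7]),
                maxfev=20000,
            )
            offset, scale, tau = map(float, popt)
            var_tau = float(pcov[2, 2])
            dof = window - 3
    except RuntimeError as exc:
        warnings.warn(f"exponential fit did not converge: {exc}")
        return _degenerate(tail, 0.0, p0_tau)

    if not np.isfinite(var_tau) or abs(scale) < 1e-8 or tau > 100 * window:
        warnings.warn("degenerate exponential fit: tau unidentifiable")
        return _degenerate(offset, scale, tau)

    if ci_method == "covariance":
        se = np.sqrt(var_tau)
        tcrit = stats.t.ppf(0.995, dof)
        ci = (tau - tcrit * se, tau + tcrit * se)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        resid = y - _exp_model(t, offset, scale, tau)
        taus = []
        for _ in range(n_boot):
            yb = _exp_model(t, offset, scale, tau) + rng.choice(
                resid, size=window, replace=True
            )
            try:
                pb, _ = optimize.curve_fit(
                    _exp_model, t, yb, p0=[offset, scale, tau],
                    bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e7]),
                    maxfev=5000,
                )
                taus.append(pb[2])
            except RuntimeError:
                continue
        if len(taus) < n_boot // 2:
            warnings.warn("bootstrap mostly failed; falling back to covariance CI")
            return fit_exponential(y, window, constrain, "covariance")
        lo, hi = np.percentile(taus, [0.5, 99.5])
        se = float(np.std(taus, ddof=1))
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ExpFitResult(scale, offset, tau, ci, float(se))


def compare_tau(fit_a: ExpFitResult, fit_b: ExpFitResult) -> str:
    """CI-overlap test on two decay constants.

    ``"different"`` (p < 0.01) when each tau lies outside the other fit's
    99% CI; ``"not_distinguished"`` otherwise or when either fit is
    degenerate.
    """
    if fit_a.degenerate or fit_b.degenerate:
        warnings.warn("degenerate fit in comparison; not distinguished")
        return "not_distinguished"
    a_out = not (fit_b.tau_ci99[0] <= fit_a.tau <= fit_b.tau_ci99[1])
    b_out = not (fit_a.tau_ci99[0] <= fit_b.tau <= fit_a.tau_ci99[1])
    return "different" if (a_out and b_out) else "not_distinguished"
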
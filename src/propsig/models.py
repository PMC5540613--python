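"""Analytic waveform models for the depolarization and their fitting.

Two model families describe the detrended depolarization d(t):

* a sum of exponentials  ``f_e(t) = a exp(b t) + c exp(d t)``
* a rational function    ``f_r(t) = (p1 t^2 + p2 t + p3) / (t + q1)``

Both admit closed-form first derivatives and antiderivatives, which the
feature extractor uses for exact integral features.

Fitting uses variable projection: the linear parameters (a, c) or
(p1, p2, p3) are solved by linear least squares for fixed nonlinear
parameters, and only the nonlinear ones — (b, d) or q1 — are searched.
This is deterministic and far more robust than a joint 4-parameter
nonlinear solve, and recovers noiseless parameters to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .errors import DelineationError, LengthError

EXP_SUM = "exp_sum"
RATIONAL = "rational"

#: exponent clip to keep exp() finite during the search
_EXP_CLIP = 300.0
#: minimum pole distance from the fit window, as a fraction of its span
_POLE_MARGIN = 0.02


@dataclass
class FitModel:
    """A fitted analytic model of the depolarization.

    ``params`` is (a, b, c, d) for the exponential-sum family and
    (p1, p2, p3, q1) for the rational family.  ``t_onset``/``t_end`` bound
    the interval, in seconds on the model's own time axis (0 at onset for
    refitted models), over which the fit is meaningful.  ``rmse`` is the
    root-mean-square residual (mV) over the fit window.
    """

    kind: str
    params: tuple[float, float, float, float]
    rmse: float
    t_onset: float
    t_end: float
    converged: bool = True


def eval_model(fit: FitModel, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the model at time(s) ``t`` (model time axis)."""
    t = np.asarray(t, dtype=float)
    if fit.kind == EXP_SUM:
        a, b, c, d = fit.params
        return a * np.exp(np.clip(b * t, -_EXP_CLIP, _EXP_CLIP)) + c * np.exp(
            np.clip(d * t, -_EXP_CLIP, _EXP_CLIP)
        )
    p1, p2, p3, q1 = fit.params
    return (p1 * t**2 + p2 * t + p3) / (t + q1)


def eval_deriv(fit: FitModel, t: np.ndarray | float) -> np.ndarray | float:
    """Closed-form first derivative of the model at ``t``."""
    t = np.asarray(t, dtype=float)
    if fit.kind == EXP_SUM:
        a, b, c, d = fit.params
        return a * b * np.exp(np.clip(b * t, -_EXP_CLIP, _EXP_CLIP)) + c * d * np.exp(
            np.clip(d * t, -_EXP_CLIP, _EXP_CLIP)
        )
    p1, p2, p3, q1 = fit.params
    return (p1 * t**2 + 2 * p1 * q1 * t + p2 * q1 - p3) / (t + q1) ** 2


def eval_antideriv(fit: FitModel, t: np.ndarray | float) -> np.ndarray | float:
    """Closed-form antiderivative F with F' = f, up to a constant.

    Exponential terms with |rate| below 1e-12 are treated as constants
    (antiderivative a*t).  The rational form uses polynomial division,
    valid because the pole t = -q1 is excluded from the fit window.
    """
    t = np.asarray(t, dtype=float)
    if fit.kind == EXP_SUM:
        a, b, c, d = fit.params
        out = np.zeros_like(t)
        for amp, rate in ((a, b), (c, d)):
            if abs(rate) < 1e-12:
                out = out + amp * t
            else:
                out = out + amp / rate * np.exp(np.clip(rate * t, -_EXP_CLIP, _EXP_CLIP))
        return out
    p1, p2, p3, q1 = fit.params
    return (
        p1 * t**2 / 2.0
        + (p2 - p1 * q1) * t
        + (p3 - p2 * q1 + p1 * q1**2) * np.log(np.abs(t + q1))
    )


def shift_time_origin(fit: FitModel, delta: float) -> FitModel:
    """Re-express the model with time origin moved by ``delta`` seconds.

    The returned model g satisfies g(t) = f(t + delta).
    """
    if fit.kind == EXP_SUM:
        a, b, c, d = fit.params
        params = (a * float(np.exp(b * delta)), b, c * float(np.exp(d * delta)), d)
    else:
        p1, p2, p3, q1 = fit.params
        # substitute t -> t + delta in numerator, pole shifts accordingly
        params = (
            p1,
            p2 + 2 * p1 * delta,
            p3 + p2 * delta + p1 * delta**2,
            q1 + delta,
        )
    return replace(
        fit, params=params, t_onset=fit.t_onset - delta, t_end=fit.t_end - delta
    )


def _exp_design(t: np.ndarray, b: float, d: float) -> np.ndarray:
    return np.column_stack(
        [
            np.exp(np.clip(b * t, -_EXP_CLIP, _EXP_CLIP)),
            np.exp(np.clip(d * t, -_EXP_CLIP, _EXP_CLIP)),
        ]
    )


def fit_exp_sum(
    t: np.ndarray,
    d: np.ndarray,
    multistarts: int = 8,
    seed: int = 0,
    max_nfev: int = 400,
) -> FitModel:
    """Fit ``a exp(b t) + c exp(d t)`` by variable projection.

    ``t`` is the model time axis (first sample at 0 by convention).  The
    nonlinear rates (b, d) are searched with bounded least squares from a
    two-timescale heuristic plus ``multistarts`` seeded random restarts; for
    each candidate the amplitudes are the exact linear solution.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if len(t) < 50:
        raise LengthError(f"need >= 50 samples in the fit window, got {len(t)}")
    span = float(t[-1] - t[0]) or 1.0
    scale = float(np.max(np.abs(d))) or 1.0

    def amplitudes(b: float, dd: float) -> np.ndarray:
        A = _exp_design(t, b, dd)
        sol, *_ = np.linalg.lstsq(A, d, rcond=None)
        return sol

    def proj_resid(x: np.ndarray) -> np.ndarray:
        A = _exp_design(t, x[0], x[1])
        sol, *_ = np.linalg.lstsq(A, d, rcond=None)
        return A @ sol - d

    # heuristic rates: time to ~63% of the final excursion sets the slow rate
    final = d[-1] - d[0]
    if abs(final) > 1e-12:
        frac = (d - d[0]) / final
        hit = np.flatnonzero(frac >= 0.632)
        t63 = float(t[hit[0]]) if len(hit) else span / 2.0
        t63 = max(t63, span / 200.0)
    else:
        t63 = span / 2.0
    starts = [
        (-1.0 / t63, -1e-9),
        (-3.0 / t63, -0.3 / t63),
        (-1.0 / t63, -0.05 / t63),
    ]
    rng = np.random.default_rng(seed)
    for _ in range(multistarts):
        starts.append(tuple(-np.exp(rng.uniform(np.log(0.02), np.log(20.0), 2)) / span * 15.0))

    lo, hi = -_EXP_CLIP / span, 0.5
    best = None
    for b0, d0 in starts:
        x0 = np.clip([b0, d0], lo + 1e-9, hi - 1e-9)
        try:
            res = optimize.least_squares(
                proj_resid,
                x0,
                bounds=([lo, lo], [hi, hi]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=max_nfev,
            )
        except (np.linalg.LinAlgError, ValueError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return FitModel(EXP_SUM, (0.0, 0.0, 0.0, 0.0), np.inf, float(t[0]), float(t[-1]), False)
    b, dd = best.x
    a, c = amplitudes(b, dd)
    rmse = float(np.sqrt(np.mean((proj_resid(best.x)) ** 2)))
    converged = rmse < 10.0 * scale  # sanity, not a convergence proof
    return FitModel(EXP_SUM, (float(a), float(b), float(c), float(dd)), rmse, float(t[0]), float(t[-1]), converged)


def _rational_solve(t: np.ndarray, d: np.ndarray, q1: float) -> tuple[np.ndarray, float]:
    den = t + q1
    A = np.column_stack([t**2 / den, t / den, 1.0 / den])
    sol, *_ = np.linalg.lstsq(A, d, rcond=None)
    r = A @ sol - d
    return sol, float(r @ r)


def fit_rational(
    t: np.ndarray,
    d: np.ndarray,
    n_grid: int = 80,
) -> FitModel:
    """Fit ``(p1 t^2 + p2 t + p3) / (t + q1)`` with the pole outside the window.

    For fixed q1 the numerator coefficients are linear, so the profile
    objective over q1 is scanned on a log grid on both sides of the window
    (pole left: q1 > margin; pole right: q1 < -(span + margin)) and refined
    with bounded scalar minimization.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if len(t) < 50:
        raise LengthError(f"need >= 50 samples in the fit window, got {len(t)}")
    t0 = float(t[0])
    tt = t - t0  # work on [0, span] for conditioning
    span = float(tt[-1]) or 1.0
    margin = _POLE_MARGIN * span

    def profile(q1: float) -> float:
        return _rational_solve(tt, d, q1)[1]

    candidates: list[float] = []
    grid = np.geomspace(margin, 100.0 * span, n_grid)
    for side in (grid, -(span + grid)):
        costs = np.array([profile(q) for q in side])
        k = int(np.argmin(costs))
        lo = side[max(k - 1, 0)]
        hi = side[min(k + 1, len(side) - 1)]
        lo, hi = min(lo, hi), max(lo, hi)
        try:
            res = optimize.minimize_scalar(
                profile, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-12 * max(1.0, span)},
            )
            candidates.append(float(res.x))
        except ValueError:
            candidates.append(float(side[k]))
    q1 = min(candidates, key=profile)
    (p1, p2, p3), cost = _rational_solve(tt, d, q1)
    rmse = float(np.sqrt(cost / len(t)))
    model = FitModel(
        RATIONAL, (float(p1), float(p2), float(p3), float(q1)), rmse, 0.0, span, True
    )
    # restore the caller's time axis
    return shift_time_origin(model, -t0)


def model_rmse(fit: FitModel, t: np.ndarray, d: np.ndarray) -> float:
    """RMSE of the model against data over the given window."""
    r = eval_model(fit, t) - d
    return float(np.sqrt(np.mean(np.square(r))))


def refit(
    fit: FitModel,
    t: np.ndarray,
    d: np.ndarray,
    multistarts: int = 8,
    seed: int = 0,
) -> FitModel:
    """Refit the same model family on a new window, never degrading RMSE.

    The refit is initialised from the existing parameters; if the fresh
    solve ends up worse on this window (possible when the window is very
    short), the original parameters are kept.
    """
    if fit.kind == EXP_SUM:
        new = fit_exp_sum(t, d, multistarts=multistarts, seed=seed)
    elif fit.kind == RATIONAL:
        new = fit_rational(t, d)
    else:
        raise DelineationError(f"unknown model kind {fit.kind!r}")
    old_rmse = model_rmse(fit, t, d)
    if not new.converged or new.rmse > old_rmse:
        return replace(fit, rmse=old_rmse, t_onset=float(t[0]), t_end=float(t[-1]))
    return new
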
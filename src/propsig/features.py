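"""The seven morphological/dynamical features of the depolarization.

All features are computed from the fitted analytic model d(t) on the
delineated interval [t_onset, t_end].  The *feature signal* is the product
d(t) * d'(t); its antiderivative is d(t)^2 / 2, so the integral features
have exact closed forms:

==  ==================  ==========================================  =======
#   name                definition                                  units
==  ==================  ==========================================  =======
1   area{d'd}           integral of d'(t) d(t) over the interval    mV^2
2   delta amp           d(t_onset) - d(t_end)                       mV
3   area{d}             integral of d(t) over the interval          mV*s
4   d'd mean            feature 1 / (t_end - t_onset)               mV^2/s
5   delta amp @2s       d(t_onset) - d(t_onset + 2 s)               mV
6   max{d'd}            max of the feature signal on the 2048 Hz
                        grid of the analytic signal                 mV^2/s
7   t_1/2               time from onset for the running feature-
                        signal area to reach half of feature 1      s
==  ==================  ==========================================  =======

Since d(t_onset) = 0 by construction of the detrending, feature 2 equals
|d(t_end)| for decaying signals and feature 1 equals (feature 2)^2 / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .models import FitModel, eval_antideriv, eval_deriv, eval_model


@dataclass
class FeatureVector:
    """The seven features of one depolarization, in the units above."""

    f1_area_dd: float
    f2_delta_amp: float
    f3_area_d: float
    f4_dd_mean: float
    f5_delta_amp_2s: float
    f6_max_dd: float
    f7_t_half: float
    f5_capped: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.f1_area_dd,
                self.f2_delta_amp,
                self.f3_area_d,
                self.f4_dd_mean,
                self.f5_delta_amp_2s,
                self.f6_max_dd,
                self.f7_t_half,
            ]
        )


#: the evaluated feature combinations (1-based feature indices)
COMBOS: dict[str, tuple[int, ...]] = {
    "combo1": (1, 4),
    "combo2": (1, 2, 4),
    "combo3": (1, 2, 4, 5),
    "combo4": (1, 4, 5, 6),
    "best1": (1, 2, 3, 4, 5),
    "best2": (1, 2, 4, 5, 6),
    "all": (1, 2, 3, 4, 5, 6, 7),
}


def _feature_area(fit: FitModel, t_from: float, t_to: float) -> float:
    """Closed-form integral of d' d: difference of d^2/2 at the endpoints."""
    lo = float(eval_model(fit, t_from))
    hi = float(eval_model(fit, t_to))
    return (hi * hi - lo * lo) / 2.0


def extract_features(fit: FitModel, fs: float = 2048.0) -> FeatureVector:
    """Compute the seven features from a fitted model.

    Integral features (1, 3, 4, 7) use the closed-form antiderivatives;
    amplitude features (2, 5) evaluate the model at the fiducials; the
    feature-signal maximum (6) is taken over the discrete 2048 Hz grid of
    the analytic signal.  When the interval is shorter than 2 s, feature 5
    is evaluated at t_end instead and flagged.
    """
    t0, te = fit.t_onset, fit.t_end
    if te < t0:
        raise ValidationError(f"t_end {te} precedes t_onset {t0}")
    width = te - t0

    f1 = _feature_area(fit, t0, te)
    f2 = float(eval_model(fit, t0)) - float(eval_model(fit, te))
    f3 = float(eval_antideriv(fit, te)) - float(eval_antideriv(fit, t0))
    f4 = f1 / width if width > 0 else 0.0

    t5 = t0 + 2.0
    capped = t5 > te
    if capped:
        t5 = te
    f5 = float(eval_model(fit, t0)) - float(eval_model(fit, t5))

    n = max(int(round(width * fs)), 1)
    grid = t0 + np.arange(n + 1) / fs
    grid[-1] = te
    feat_sig = np.asarray(eval_model(fit, grid)) * np.asarray(eval_deriv(fit, grid))
    f6 = float(np.max(feat_sig))

    f7 = _t_half(fit, f1, t0, te)
    return FeatureVector(f1, f2, f3, f4, f5, f6, f7, f5_capped=capped)


def _t_half(fit: FitModel, f1: float, t0: float, te: float, tol: float = 1e-9) -> float:
    """Bisection for the half-area time of the feature signal.

    The running area from t0 is (d(t)^2 - d(t0)^2) / 2, exact at every
    evaluation; bisection converges to ``tol`` seconds (cheap, since each
    evaluation is closed-form).  Degenerate zero-area fits return t_end.
    """
    if f1 == 0.0 or te <= t0:
        return te

    def g(t: float) -> float:
        return _feature_area(fit, t0, t) - f1 / 2.0

    lo, hi = t0, te
    glo = g(lo)
    if glo > 0 or g(hi) < 0:  # non-monotone pathologies: fall back to grid scan
        tgrid = np.linspace(t0, te, 4097)
        areas = np.array([g(t) for t in tgrid])
        return float(tgrid[int(np.argmin(np.abs(areas)))])
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def select_combo(fv: FeatureVector | np.ndarray, combo: str) -> np.ndarray:
    """Return the features of a named combination in ascending index order."""
    key = combo.strip().lower().replace(" ", "")
    if key not in COMBOS:
        raise ConfigurationError(f"unknown feature combination {combo!r}")
    arr = fv.as_array() if isinstance(fv, FeatureVector) else np.asarray(fv)
    return arr[[i - 1 for i in COMBOS[key]]]


FEATURE_COLUMNS = [f"f{i}" for i in range(1, 8)]


def feature_lms_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each feature with the LMS bitterness rating.

    Reporting utility: returns r and p per feature, rows indexed 1..7.
    Rows with missing LMS ratings are dropped.
    """
    sub = table.dropna(subset=["lms_rating"])
    rows = []
    for i, col in enumerate(FEATURE_COLUMNS, start=1):
        r, p = stats.pearsonr(sub[col], sub["lms_rating"])
        rows.append({"feature": i, "r": r, "p": p})
    return pd.DataFrame(rows).set_index("feature")
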
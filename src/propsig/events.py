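"""Depolarization onset (knee point) detection on the 128 Hz segment.

The onset is found from the first derivative of the decimated segment: a
moving two-point standard deviation of the derivative is scanned over the
first 6 s of the window, and the knee is the first sample exceeding an
absolute threshold (2.1 mV/s), falling back to a relative threshold
(0.8 x the maximum) when no sample crosses the absolute one.  Both
thresholds were chosen empirically on tongue recordings and are exposed
as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .errors import ConfigurationError, DetectionError, LengthError
from .preprocess import Segment

ABS_THRESHOLD_MV_S = 2.1
REL_FRACTION = 0.8
SEARCH_WINDOW_S = 6.0

# five-point central difference: exact on polynomials up to degree 4
_CENTRAL5 = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / 12.0
# as-printed variant with all-positive taps (no differencing); kept selectable
_PRINTED = np.array([1.0, 1.0, 0.0, 1.0, 1.0]) / 8.0

KERNELS = {"central5": _CENTRAL5, "printed": _PRINTED}


@dataclass
class DerivativeSignal:
    """First derivative of a segment, in mV/s.

    ``valid_range`` is the half-open index interval where the five-point
    stencil is fully supported; the two samples at each edge are filled by
    one-sided differences and excluded from the knee search.
    """

    xdot: np.ndarray
    fs: float
    valid_range: tuple[int, int]


@dataclass
class KneeEstimate:
    """Coarse depolarization onset at 128 Hz.

    ``index`` is in segment coordinates; ``time`` is seconds relative to
    stimulus application; ``rule_used`` records which threshold fired.
    """

    index: int
    time: float
    rule_used: str


def derivative(x: np.ndarray, fs: float, kernel: str = "central5") -> DerivativeSignal:
    """Differentiate ``x`` with a five-point stencil (units mV/s).

    Interior samples use the selected kernel; the first/last two samples use
    one-sided differences so the output keeps the input length.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise LengthError(f"need at least 5 samples, got {len(x)}")
    if kernel not in KERNELS:
        raise ConfigurationError(f"unknown derivative kernel {kernel!r}")
    c = KERNELS[kernel]
    xdot = np.empty_like(x)
    xdot[2:-2] = (
        c[0] * x[:-4] + c[1] * x[1:-3] + c[2] * x[2:-2] + c[3] * x[3:-1] + c[4] * x[4:]
    ) * fs
    xdot[0] = (x[1] - x[0]) * fs
    xdot[1] = (x[2] - x[0]) * fs / 2.0
    xdot[-2] = (x[-1] - x[-3]) * fs / 2.0
    xdot[-1] = (x[-1] - x[-2]) * fs
    return DerivativeSignal(xdot=xdot, fs=fs, valid_range=(2, len(x) - 2))


def moving_sd(xdot: np.ndarray, window: int = 2) -> np.ndarray:
    """Moving sample standard deviation of the derivative.

    For the default two-point window this is |xdot[k+1] - xdot[k]| / sqrt(2);
    output length is ``len(xdot) - window + 1``.
    """
    xdot = np.asarray(xdot, dtype=float)
    if window < 2:
        raise ConfigurationError(f"window must be >= 2, got {window}")
    if len(xdot) < window:
        raise LengthError(f"input shorter than window {window}")
    if window == 2:
        return np.abs(np.diff(xdot)) / sqrt(2.0)
    views = np.lib.stride_tricks.sliding_window_view(xdot, window)
    return views.std(axis=1, ddof=1)


def detect_knee(
    s: np.ndarray,
    abs_thresh: float = ABS_THRESHOLD_MV_S,
    rel_frac: float = REL_FRACTION,
) -> tuple[int, str]:
    """Scan the moving-SD trace for the knee point.

    Returns ``(index, rule_used)`` — the minimal index with
    ``s > abs_thresh``, else the minimal index with
    ``s >= rel_frac * max(s)``.
    """
    s = np.asarray(s, dtype=float)
    if len(s) == 0 or np.all(np.isnan(s)):
        raise DetectionError("moving-SD trace empty or all-NaN")
    above = np.flatnonzero(s > abs_thresh)
    if len(above):
        return int(above[0]), "absolute_threshold"
    rel = np.flatnonzero(s >= rel_frac * np.nanmax(s))
    return int(rel[0]), "relative_threshold"


def find_onset(
    seg: Segment,
    abs_thresh: float = ABS_THRESHOLD_MV_S,
    rel_frac: float = REL_FRACTION,
    search_window_s: float = SEARCH_WINDOW_S,
    kernel: str = "central5",
) -> KneeEstimate:
    """Locate the depolarization onset on a 128 Hz segment.

    Composes :func:`derivative`, :func:`moving_sd` and :func:`detect_knee`
    over the first ``search_window_s`` seconds of the segment; the two edge
    samples with an unsupported stencil are excluded from the scan.
    """
    n_search = int(round(search_window_s * seg.fs))
    n_search = min(n_search, len(seg.x))
    der = derivative(seg.x, seg.fs, kernel=kernel)
    lo = der.valid_range[0]
    s = moving_sd(der.xdot[:n_search])
    idx, rule = detect_knee(s[lo:], abs_thresh=abs_thresh, rel_frac=rel_frac)
    idx += lo
    return KneeEstimate(index=idx, time=(idx - seg.stim_index) / seg.fs, rule_used=rule)
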
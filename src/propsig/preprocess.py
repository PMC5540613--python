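"""Low-pass filtering, analysis-window extraction and rate conversion.

The depolarization evoked by the PROP stimulus is a slow waveform, so the
raw 2048 Hz trace is low-pass filtered at 6 Hz with an order-86 equiripple
FIR (87 taps), which also suppresses 50 Hz mains interference.  A 20 s
analysis window (5 s before stimulus application, 15 s after) is then cut
out and decimated to 128 Hz by keeping 1 sample in 16 — legitimate without
a further anti-alias stage because of the 6 Hz low-pass.  Delineation later
returns to 2048 Hz by polyphase upsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError, CoverageError, LengthError
from .recording import Recording

#: analysis window extent around stimulus application (s)
PRE_S = 5.0
POST_S = 15.0
#: decimation factor 2048 -> 128 Hz
DECIMATION = 16


@dataclass
class Segment:
    """The 20 s analysis window around stimulus application.

    ``t0`` is the time of the first sample relative to stimulus application
    (−5 s for the default window); ``stim_index`` is the sample at t = 0.
    """

    x: np.ndarray
    fs: float
    t0: float
    stim_index: int

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus application."""
        return (np.arange(len(self.x)) - self.stim_index) / self.fs


def design_lowpass(
    fs: float = 2048.0,
    order: int = 86,
    passband_hz: float = 6.0,
    stopband_hz: float = 50.0,
) -> np.ndarray:
    """Design the order-86 (87-tap) linear-phase equiripple low-pass FIR.

    Passband edge 6 Hz, stopband edge 50 Hz (mains), equal band weights.
    Returns the filter coefficients.
    """
    if fs <= 0 or not 0 < passband_hz < stopband_hz < fs / 2:
        raise ConfigurationError(
            f"infeasible filter spec: fs={fs}, pass={passband_hz}, stop={stopband_hz}"
        )
    taps = signal.remez(
        order + 1,
        bands=[0.0, passband_hz, stopband_hz, fs / 2],
        desired=[1.0, 0.0],
        fs=fs,
    )
    if not np.all(np.isfinite(taps)):
        raise ConfigurationError("equiripple design did not converge")
    # normalize to exactly unit DC gain so offsets pass through unchanged
    return taps / taps.sum()


def lowpass_filter(x: np.ndarray, fs: float, taps: np.ndarray | None = None) -> np.ndarray:
    """Apply the low-pass FIR with group-delay compensation.

    The input is reflect-padded by one filter length so start-up transients
    stay outside the analysis window, filtered causally, then shifted by the
    (order/2)-sample group delay.  Output has the same length as the input
    and preserves event timing.
    """
    x = np.asarray(x, dtype=float)
    if taps is None:
        taps = design_lowpass(fs)
    ntaps = len(taps)
    if len(x) <= 2 * ntaps:
        raise LengthError(f"input length {len(x)} <= 2 x {ntaps} taps")
    delay = (ntaps - 1) // 2
    xp = np.pad(x, ntaps, mode="reflect")
    y = signal.lfilter(taps, 1.0, xp)
    return y[ntaps + delay : ntaps + delay + len(x)]


def extract_segment(rec: Recording, pre_s: float = PRE_S, post_s: float = POST_S) -> Segment:
    """Cut the [−pre, +post) window around stimulus application."""
    fs = rec.fs
    i_stim = int(round(rec.t_stim_on * fs))
    i0 = i_stim - int(round(pre_s * fs))
    i1 = i_stim + int(round(post_s * fs))
    if i0 < 0:
        raise CoverageError(f"recording starts {-i0 / fs:.2f} s too late for the window")
    if i1 > len(rec.samples):
        raise CoverageError(
            f"recording ends {(i1 - len(rec.samples)) / fs:.2f} s before the window"
        )
    return Segment(x=rec.samples[i0:i1].copy(), fs=fs, t0=-pre_s, stim_index=i_stim - i0)


def decimate16(seg: Segment, factor: int = DECIMATION) -> Segment:
    """Downsample by exact sample selection: output[k] = input[factor*k].

    Valid only because the signal is already band-limited to 6 Hz.
    """
    if factor < 1 or seg.fs % factor != 0:
        raise ConfigurationError(f"fs={seg.fs} not divisible by factor={factor}")
    new_stim = seg.stim_index // factor
    new_fs = seg.fs / factor
    return Segment(
        x=seg.x[::factor].copy(),
        fs=new_fs,
        t0=-new_stim / new_fs,
        stim_index=new_stim,
    )


def upsample16(x: np.ndarray, factor: int = DECIMATION) -> np.ndarray:
    """Polyphase upsampling by ``factor`` (128 -> 2048 Hz).

    Band-limited inputs are reconstructed; the mean is removed before the
    polyphase stage and restored afterwards, so constant offsets pass
    through exactly.  Output length is ``factor * len(x)``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 32:
        raise LengthError(f"need at least 32 samples to upsample, got {len(x)}")
    mu = x.mean()
    return signal.resample_poly(x - mu, factor, 1, padtype="line") + mu
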
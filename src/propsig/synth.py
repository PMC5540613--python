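"""Seeded generator of synthetic tongue-biopotential recordings.

No public dataset of PROP-evoked tongue recordings exists, so this module
produces annotated recordings with the statistical structure the pipeline
assumes, together with exact ground truth for every downstream stage.

Each recording is 95 s at 2048 Hz with the stimulus applied at 30 s and
removed at 45 s.  The clean waveform is a drifting linear baseline until
the onset (a configurable delay after stimulus application), followed by a
bi-exponential depolarization

    f(t') = a exp(b t') + c exp(d t'),   a = -S, c = +S,
    b = -1/tau_slow, d = -1/tau_fast,    tau_fast <= tau_slow,

scaled so the peak excursion equals ``-delta_amp`` mV: an abrupt onset,
a negative plateau, and a slow relaxation — and, crucially, a member of
the exponential-sum model family fitted by the delineation stage, so all
feature ground truths are analytic.  Band-limited baseline wander plus a
small broadband noise floor, fixed-phase 50 Hz mains interference, a
raised-cosine stimulus-application bump and optional tongue-movement
artefacts are then added.

Class profiles (amplitude and rise-time ranges per taster class) are
invented calibrations: large/fast for supertasters, small/slow for
non-tasters, deliberately overlapping for medium tasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .delineate import detect_end
from .errors import ValidationError
from .models import EXP_SUM, FitModel
from .features import extract_features
from .recording import Recording, SubjectMeta, write_cohort_csv, write_recording

DURATION_S = 95.0
STIM_ON_S = 30.0
STIM_OFF_S = 45.0
FS = 2048.0
#: ratio of the slow (relaxation) to the fast (rise) time constant
TAU_SLOW_RATIO = 8.0


@dataclass
class SynthParams:
    """Ground-truth parameters of one synthetic recording."""

    taster_class: str  # NT | MT | ST
    delta_amp: float  # peak depolarization depth, mV (> 0)
    tau_fast: float  # rise time constant, s
    tau_slow: float  # relaxation time constant, s
    onset_delay: float = 0.3  # s after stimulus application
    baseline_slope: float = 0.0  # mV/s
    baseline_offset: float = 0.0  # mV
    noise_sd: float = 0.3  # baseline drift-noise SD, mV
    noise_band_hz: float = 0.5  # bandwidth of the drift noise
    broadband_sd_frac: float = 0.1  # broadband (amplifier) noise, fraction of noise_sd
    mains_amp: float = 0.1  # 50 Hz amplitude, mV
    artifact_spec: list[tuple[float, float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_amp <= 0:
            raise ValidationError("delta_amp must be positive")
        if not 0 < self.tau_fast <= self.tau_slow:
            raise ValidationError("require 0 < tau_fast <= tau_slow")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass
class ClassProfile:
    """Per-class uniform ranges for the waveform parameters.

    ``delta_amp`` ranges in mV and ``tau`` (rise) ranges in seconds;
    the MT ranges deliberately overlap both neighbouring classes.
    """

    delta_amp: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ST": (50.0, 110.0),
            "MT": (25.0, 70.0),
            "NT": (5.0, 45.0),
        }
    )
    tau: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ST": (0.5, 3.0),
            "MT": (2.0, 12.0),
            "NT": (8.0, 30.0),
        }
    )
    onset_delay: tuple[float, float] = (0.1, 0.8)
    baseline_slope: tuple[float, float] = (-0.15, 0.05)
    noise_sd: float = 0.3
    mains_amp: float = 0.1
    stim_bump_mv: tuple[float, float] = (0.5, 3.0)
    movement_artifact_prob: float = 0.3
    diplotype_map: dict[str, str] = field(
        default_factory=lambda: {"ST": "PAV/PAV", "MT": "PAV/AVI", "NT": "AVI/AVI"}
    )
    #: LMS bitterness rating mean/SD per class (0-100 scale)
    lms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ST": (62.0, 12.0), "MT": (29.0, 19.0), "NT": (7.0, 7.0)}
    )


def default_profile() -> ClassProfile:
    return ClassProfile()


def separable_profile() -> ClassProfile:
    """A profile with disjoint class ranges (for separability checks)."""
    p = ClassProfile()
    p.delta_amp = {"ST": (80.0, 110.0), "MT": (40.0, 60.0), "NT": (5.0, 20.0)}
    p.tau = {"ST": (0.5, 1.5), "MT": (3.0, 6.0), "NT": (12.0, 30.0)}
    return p


def truth_model(params: SynthParams) -> FitModel:
    """The clean depolarization as an exponential-sum model (onset at t=0)."""
    tf, ts = params.tau_fast, params.tau_slow
    if ts == tf:
        ts = tf * (1.0 + 1e-9)
    # peak of exp(-t/ts) - exp(-t/tf) sets the amplitude normalization
    t_star = np.log(ts / tf) * tf * ts / (ts - tf)
    peak = np.exp(-t_star / ts) - np.exp(-t_star / tf)
    s = params.delta_amp / peak
    a, b, c, d = -s, -1.0 / ts, s, -1.0 / tf
    t_cap = max(15.0 - params.onset_delay, 1.0)
    fit = FitModel(EXP_SUM, (a, b, c, d), 0.0, 0.0, t_cap)
    t_end = detect_end(fit, 0.0, t_cap)
    fit.t_end = t_end
    return fit


def _baseline_noise(
    rng: np.random.Generator, n: int, sd: float, band_hz: float
) -> np.ndarray:
    """Slow electrode-baseline wander: band-limited noise rescaled to ``sd``.

    Electrode-tissue baseline fluctuations are drift-like (sub-Hz to a few
    Hz); broadband thermal/amplifier noise is modelled separately because
    the 6 Hz acquisition low-pass removes it almost entirely.
    """
    from scipy import signal as _sig

    b, a = _sig.butter(2, band_hz, fs=FS)
    raw = _sig.filtfilt(b, a, rng.normal(0.0, 1.0, n))
    scale = raw.std()
    return raw * (sd / scale) if scale > 0 else raw


def synth_recording(params: SynthParams) -> tuple[Recording, dict]:
    """Generate one recording and its ground-truth record.

    Returns ``(recording, truth)`` where ``truth`` holds the onset time,
    the exponential-sum parameters and the analytic feature values of the
    clean waveform.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(DURATION_S * FS))
    t = np.arange(n) / FS
    x = params.baseline_offset + params.baseline_slope * t

    t_on = STIM_ON_S + params.onset_delay
    model = truth_model(params)
    after = t >= t_on
    tp = t[after] - t_on
    a, b, c, d = model.params
    x[after] += a * np.exp(b * tp) + c * np.exp(d * tp)

    if params.noise_sd > 0:
        x += _baseline_noise(rng, n, params.noise_sd, params.noise_band_hz)
        x += rng.normal(0.0, params.broadband_sd_frac * params.noise_sd, n)
    if params.mains_amp > 0:
        x += params.mains_amp * np.sin(2 * np.pi * 50.0 * t)
    for t_a, height, width in params.artifact_spec:
        mask = np.abs(t - t_a) < width / 2.0
        x[mask] += height / 2.0 * (1.0 + np.cos(2.0 * np.pi * (t[mask] - t_a) / width))

    rec = Recording(samples=x, fs=FS, t_stim_on=STIM_ON_S, t_stim_off=STIM_OFF_S)
    fv = extract_features(model)
    truth = {
        "taster_class": params.taster_class,
        "onset_time_abs": t_on,
        "onset_delay": params.onset_delay,
        "delta_amp": params.delta_amp,
        "tau_fast": params.tau_fast,
        "tau_slow": params.tau_slow,
        "baseline_slope": params.baseline_slope,
        "noise_sd": params.noise_sd,
        "a": a,
        "b": b,
        "c": c,
        "d": d,
        "t_end": model.t_end,
        **{f"f{i}": v for i, v in enumerate(fv.as_array(), start=1)},
    }
    return rec, truth


def draw_params(
    taster_class: str, profile: ClassProfile, rng: np.random.Generator, seed: int
) -> SynthParams:
    """Draw one subject's waveform parameters from the class profile."""
    lo, hi = profile.delta_amp[taster_class]
    delta = rng.uniform(lo, hi)
    lo, hi = profile.tau[taster_class]
    tau_fast = rng.uniform(lo, hi)
    artifacts = [(STIM_ON_S, rng.uniform(*profile.stim_bump_mv), 0.4)]
    if rng.random() < profile.movement_artifact_prob:
        artifacts.append((rng.uniform(33.0, 44.0), rng.uniform(2.0, 8.0), rng.uniform(0.3, 1.0)))
    return SynthParams(
        taster_class=taster_class,
        delta_amp=delta,
        tau_fast=tau_fast,
        tau_slow=TAU_SLOW_RATIO * tau_fast,
        onset_delay=rng.uniform(*profile.onset_delay),
        baseline_slope=rng.uniform(*profile.baseline_slope),
        noise_sd=profile.noise_sd,
        mains_amp=profile.mains_amp,
        artifact_spec=artifacts,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def synth_cohort(
    profile: ClassProfile | None = None,
    n_per_class: int = 13,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[Recording, dict]], pd.DataFrame, pd.DataFrame]:
    """Generate a labelled cohort (default 13 subjects per taster class).

    Returns ``(recordings, metadata, truth_table)``.  When ``out_dir`` is
    given, the recordings, the cohort metadata CSV and the truth-table CSV
    are also written there.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    profile = profile or default_profile()
    rng = np.random.default_rng(seed)
    recordings: list[tuple[Recording, dict]] = []
    meta_rows = []
    truth_rows = []
    for cls in ("NT", "MT", "ST"):
        for j in range(n_per_class):
            sid = f"{cls}{j + 1:02d}"
            params = draw_params(cls, profile, rng, seed)
            rec, truth = synth_recording(params)
            mu, sd = profile.lms[cls]
            lms = float(np.clip(rng.normal(mu, sd), 0.0, 100.0))
            rec.subject = SubjectMeta(
                subject_id=sid,
                taster_label=cls,
                diplotype=profile.diplotype_map[cls],
                lms_rating=round(lms, 1),
            )
            truth = {"subject_id": sid, **truth}
            recordings.append((rec, truth))
            meta_rows.append(
                {
                    "subject_id": sid,
                    "taster_label": cls,
                    "diplotype": rec.subject.diplotype,
                    "lms_rating": rec.subject.lms_rating,
                    "recording_path": f"{sid}.txt",
                }
            )
            truth_rows.append(truth)
    meta = pd.DataFrame(meta_rows)
    truth_table = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, truth in recordings:
            write_recording(rec, out / f"{truth['subject_id']}.txt")
        write_cohort_csv(meta, out / "cohort.csv")
        truth_table.to_csv(out / "truth.csv", index=False)
    return recordings, meta, truth_table
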
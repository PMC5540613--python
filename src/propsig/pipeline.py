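"""End-to-end processing: recording -> delineation -> feature table."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import preprocess
from .config import PipelineConfig
from .delineate import DelineationResult, delineate
from .errors import PropsigError
from .features import FeatureVector, extract_features
from .recording import Recording, read_recording

log = logging.getLogger(__name__)


def process_recording(
    rec: Recording, config: PipelineConfig | None = None
) -> tuple[FeatureVector, DelineationResult]:
    """Filter, segment, delineate and extract features for one recording."""
    cfg = config or PipelineConfig()
    taps = preprocess.design_lowpass(
        rec.fs,
        order=cfg.filter.order,
        passband_hz=cfg.filter.passband_hz,
        stopband_hz=cfg.filter.stopband_hz,
    )
    filtered = preprocess.lowpass_filter(rec.samples, rec.fs, taps=taps)
    seg = preprocess.extract_segment(
        Recording(filtered, rec.fs, rec.t_stim_on, rec.t_stim_off, rec.subject),
        pre_s=cfg.segment.pre_s,
        post_s=cfg.segment.post_s,
    )
    res = delineate(
        seg,
        fit_seed=cfg.fit.seed,
        multistarts=cfg.fit.multistarts,
        knee_abs_thresh=cfg.knee.abs_threshold_mv_s,
        knee_rel_frac=cfg.knee.rel_fraction,
        end_theta=cfg.end.theta,
        end_variant=cfg.end.variant,
        post_window_frac=cfg.trend.post_window_frac,
        derivative_kernel=cfg.knee.kernel,
    )
    fv = extract_features(res.fit, fs=rec.fs)
    return fv, res


def run_pipeline(
    paths: list[str | Path],
    config: PipelineConfig | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Process a list of recording files into a feature table.

    Per-recording failures are logged with their stage and skipped; an
    empty result (zero successes) raises.
    """
    rows = []
    for path in paths:
        try:
            rec = read_recording(path)
            fv, res = process_recording(rec, config)
        except (PropsigError, OSError, ValueError) as exc:
            log.warning("skipping %s: %s: %s", path, type(exc).__name__, exc)
            continue
        sub = rec.subject
        rows.append(
            {
                "subject_id": sub.subject_id if sub else Path(path).stem,
                "taster_label": sub.taster_label if sub else "unknown",
                "diplotype": sub.diplotype if sub else "unknown",
                "lms_rating": sub.lms_rating if sub else None,
                **{f"f{i}": v for i, v in enumerate(fv.as_array(), start=1)},
                "model_kind": res.fit.kind,
                "t_onset": res.t_onset_rel_stim,
                "t_end": res.t_onset_rel_stim + (res.n_end - res.n_k) / res.fs,
                "rmse": res.fit.rmse,
            }
        )
    if not rows:
        raise PropsigError("no recording processed successfully")
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
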
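import numpy as np
import pytest
from hypothesis import settings

import propsig as ps

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_st_recording():
    """A clean supertaster-like recording with exact ground truth."""
    params = ps.SynthParams(
        "ST",
        delta_amp=80.0,
        tau_fast=1.5,
        tau_slow=12.0,
        onset_delay=0.2,
        noise_sd=0.0,
        mains_amp=0.0,
        artifact_spec=[],
        seed=11,
    )
    rec, truth = ps.synth_recording(params)
    return params, rec, truth


@pytest.fixture(scope="session")
def small_cohort_features():
    """Feature table for a 4-per-class separable cohort run end to end."""
    from propsig.synth import separable_profile

    recs, meta, truth = ps.synth_cohort(separable_profile(), n_per_class=4, seed=5)
    import propsig.pipeline as pl

    rows = []
    for rec, tr in recs:
        fv, res = pl.process_recording(rec)
        rows.append(
            {
                "subject_id": tr["subject_id"],
                "taster_label": rec.subject.taster_label,
                "diplotype": rec.subject.diplotype,
                "lms_rating": rec.subject.lms_rating,
                **{f"f{i}": v for i, v in enumerate(fv.as_array(), start=1)},
            }
        )
    import pandas as pd

    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
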
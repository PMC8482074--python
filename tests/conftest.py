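import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rarlab import CosinorParams, EpochSeries, antilogistic_curve

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_series(
    counts,
    start="2020-01-01T00:00:00",
    epoch_length=3600,
    valid_mask=None,
    subject_id="T01",
    wave=0,
):
    counts = np.asarray(counts, dtype=float)
    if valid_mask is None:
        valid_mask = np.ones(len(counts), dtype=bool)
    return EpochSeries(
        subject_id=subject_id,
        wave=wave,
        start_time=pd.Timestamp(start),
        epoch_length=epoch_length,
        counts=counts,
        valid_mask=np.asarray(valid_mask, dtype=bool),
    )


def model_series(
    params: CosinorParams,
    days=7,
    epoch_length=60,
    noise_sd=0.0,
    rng=None,
    start="2020-01-01T00:00:00",
):
    """Epoch series sampled exactly from the anti-logistic curve,
    optionally with additive Gaussian noise clipped at zero."""
    n = days * 86400 // epoch_length
    t = (np.arange(n) * epoch_length / 3600.0) % 24.0
    y = antilogistic_curve(t, params)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        y = np.clip(y + rng.normal(0.0, noise_sd, size=n), 0.0, None)
    return make_series(y, start=start, epoch_length=epoch_length)


@pytest.fixture
def plain_epoch_file(tmp_path):
    path = tmp_path / "plain.csv"
    path.write_text(
        "subject_id,timestamp,activity,off_wrist\n"
        "A1,2020-01-01T00:00:00,0,0\n"
        "A1,2020-01-01T00:01:00,5,0\n"
        "A1,2020-01-01T00:02:00,2,0\n"
    )
    return path


@pytest.fixture
def device_export_file(tmp_path):
    path = tmp_path / "export.csv"
    preamble = "\n".join(f"-- meta line {i} --" for i in range(10))
    path.write_text(
        preamble
        + "\nsubject_id,timestamp,activity,off_wrist\n"
        "A1,2020-01-01T00:00:00,0,0\n"
        "A1,2020-01-01T00:01:00,5,0\n"
        "A1,2020-01-01T00:02:00,2,0\n"
    )
    return path
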
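from datetime import datetime

import numpy as np
import pytest

from hypocgm.config import (
    ExcursionParams,
    GroupConfig,
    GeneratorConfig,
    SmbgParams,
    TraceParams,
    default_cgm_config,
)
from hypocgm.types import GlucoseTrace, SubjectRecord

SESSION_START = datetime(2017, 1, 2, 12, 0)


def make_trace(values, start=SESSION_START, interval=5.0, subject_id="s1"):
    return GlucoseTrace(subject_id, start, interval, np.asarray(values, float))


@pytest.fixture
def subject():
    return SubjectRecord("low000", "low", 50.0, 70.0, "M", 72.0, True, 0.7)


@pytest.fixture
def cgm_config():
    return default_cgm_config(seed=0)


def quiet_group(
    label="low",
    baseline=10.0,
    ou_sd=0.0,
    amplitude=0.0,
    rate=0.0,
    days=4.0,
    **trace_kw,
):
    """A group config with all stochastic components switchable off."""
    return GroupConfig(
        label=label,
        n_subjects=1,
        trace=TraceParams(
            baseline_mmol=baseline,
            ou_sd_mmol=ou_sd,
            circadian_amplitude_mmol=amplitude,
            recording_days=days,
            **trace_kw,
        ),
        excursions=ExcursionParams(rate_per_week=rate),
    )


def quiet_config(seed=0, smbg_cv=0.0, **kw):
    return GeneratorConfig(
        study="cgm",
        groups=(quiet_group(**kw),),
        smbg=SmbgParams(per_day=4, noise_cv=smbg_cv),
        seed=seed,
    )
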
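"""Shared fixtures: pipeline config, shipped models, and synthetic records.

All fixtures are generated programmatically; session scope keeps the more
expensive simulations to one run each.
"""

import numpy as np
import pytest

from ectopy.beat_detection import beats_from_annotations, mark_noise
from ectopy.config import PipelineConfig
from ectopy.io_signals import preprocess
from ectopy.morphology import load_default_models
from ectopy.synth_ecg import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def models():
    return load_default_models()


@pytest.fixture(scope="session")
def nsr_record():
    """60 s of clean 60 bpm sinus rhythm."""
    return simulate(SyntheticConfig(duration=60, heart_rate=60, seed=1))


@pytest.fixture(scope="session")
def ectopy_record():
    """10 min at 10% burden, mixed sequence types."""
    return simulate(SyntheticConfig(duration=600, target_burden_pct=10,
                                    seq_mix=(0.5, 0.15, 0.2, 0.15), seed=42))


@pytest.fixture(scope="session")
def ectopy_pipeline_inputs(ectopy_record, cfg):
    """Preprocessed signal + bypass beats + noise for the mixed record."""
    res = ectopy_record
    work = preprocess(res.signal, cfg.preprocess.band_lo,
                      cfg.preprocess.band_hi, cfg.preprocess.target_fs)
    beats = beats_from_annotations(res.annotations, work)
    noise = mark_noise(res.signal, beats, cfg.noise)
    return res, work, beats, noise
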
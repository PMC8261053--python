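"""Shared fixtures: tiny model configurations and synthetic data.

Model sizes here are scaled far below the paper-scale architecture so the
whole suite runs on one CPU; the architecture and training procedure are
identical, only widths/depths/step counts shrink.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bendr.contextualizer import ContextualizerConfig
from bendr.encoder import EncoderConfig
from bendr.harmonization import compute_dataset_stats, harmonize, window_pretrain
from bendr.pretraining import BendrModel, PretrainConfig
from bendr.synthetic import SynthConfig, generate_recording


TINY_ENC = EncoderConfig(filters=64, norm_groups=8)
TINY_CTX = ContextualizerConfig(d_bendr=64, layers=2, heads=4, d_model=64,
                                d_ff=128)


@pytest.fixture(scope="session")
def tiny_enc_cfg() -> EncoderConfig:
    return TINY_ENC


@pytest.fixture(scope="session")
def tiny_ctx_cfg() -> ContextualizerConfig:
    return TINY_CTX


@pytest.fixture(scope="session")
def synth_corpus():
    """Structured multi-subject corpus, harmonized into 20 s windows."""
    cfg = SynthConfig(n_subjects=4, duration_s=160.0, seed=7)
    recs = [generate_recording(cfg, s) for s in range(cfg.n_subjects)]
    stats = compute_dataset_stats(recs)
    windows, subjects = [], []
    for rec in recs:
        seq = harmonize(rec, stats)
        for w in window_pretrain(seq, 20.0):
            windows.append(w.data)
            subjects.append(rec.subject_id)
    return np.stack(windows), np.asarray(subjects)


def make_tiny_model(seed: int) -> BendrModel:
    return BendrModel(TINY_ENC, TINY_CTX, np.random.default_rng(seed))


@pytest.fixture()
def tiny_model() -> BendrModel:
    return make_tiny_model(0)


@pytest.fixture(scope="session")
def tiny_pretrain_cfg() -> PretrainConfig:
    return PretrainConfig(total_steps=2000, peak_lr=1e-3, batch_size=2, seed=0)
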
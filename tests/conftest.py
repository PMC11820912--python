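import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_esm(subject_id="sub-001", timestamp=1e9, items=None, valence=3, arousal=3):
    from wearaffect.io import PANAS_ITEMS, EsmResponse

    base = {name: 3 for name in PANAS_ITEMS}
    if items:
        base.update(items)
    return EsmResponse(subject_id, timestamp, base, valence, arousal)


def make_segment(subject_id="sub-001", esm_timestamp=1e9, T=60, fill=0.0, labels=None):
    from wearaffect import labels as wl
    from wearaffect.io import Segment

    labels = labels or wl.label_set(make_esm(subject_id, esm_timestamp)).to_dict()
    return Segment(
        subject_id=subject_id,
        esm_timestamp=esm_timestamp,
        matrix=np.full((T, 3), fill),
        labels=labels,
        completeness=np.ones(3),
    )


@pytest.fixture
def tiny_model_config():
    """1-layer, 2-head model small enough for finite-difference checks."""
    from wearaffect.network import ModelConfig

    return ModelConfig(
        modalities=("hr", "gsr", "accel"),
        embed_dim=3,
        cnn_hidden=4,
        d_model=8,
        n_layers=1,
        n_heads=2,
        ffn_dim=16,
        dropout=0.0,
        n_classes=2,
    )
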
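import numpy as np
import pytest

from mirfnet.config import FusionConfig, ModelConfig
from mirfnet.encoders import CTGEncoderConfig, ImageEncoderConfig
from mirfnet.fixtures import SyntheticConfig, generate_dataset
from mirfnet.gadf import GADFConfig


def reduced_model_config(**overrides) -> ModelConfig:
    """Desk-scale model: short segments, narrow encoders, tiny image branch."""
    kwargs = dict(
        segment_length=960,
        ctg=CTGEncoderConfig(d_model=32, n_layers=1, n_heads=2, ffn_width=64),
        image=ImageEncoderConfig(depth=10, base_width=8, small_input=True,
                                 pretrained=False),
        gadf=GADFConfig(out_size=32, fast_path=True),
        fusion=FusionConfig(d_common=32, n_layers=2, n_heads=4, ffn_width=64),
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def strong_coupling_config(n_records: int, seed: int,
                           segment_length: int = 960) -> SyntheticConfig:
    """Generator settings that couple all three modalities to the label."""
    return SyntheticConfig(
        n_records=n_records, seed=seed, segment_length=segment_length,
        contraction_period=80.0, decel_depth=40.0,
        diabetes_prob_abnormal=0.55, diabetes_prob_normal=0.08,
        age_mean_abnormal=33.0, age_mean_normal=28.0,
    )


@pytest.fixture(scope="session")
def tiny_records():
    return generate_dataset(strong_coupling_config(n_records=12, seed=5,
                                                   segment_length=480))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
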
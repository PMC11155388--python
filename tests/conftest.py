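import numpy as np
import pytest

from ramanmargin.axis import default_axis
from ramanmargin.config import PipelineConfig
from ramanmargin.pipeline import run_pipeline, train_default_models
from ramanmargin.simulate import make_point_probe_training_set


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def training_set():
    """The seeded default point-probe set (93 fat / 87 cancer / 58 normal)."""
    return make_point_probe_training_set(seed=2024)


@pytest.fixture(scope="session")
def default_models():
    """Model A (fat gate, protect_cancer threshold) and model B, trained on
    the seeded default set via the pipeline's training entry point."""
    cfg = PipelineConfig(seed=11)
    train, model_a, model_b = train_default_models(cfg)
    return train, model_a, model_b


@pytest.fixture(scope="session")
def margin_run():
    """One full pipeline run on the default 40x42 mixed-margin phantom."""
    return run_pipeline(PipelineConfig(seed=7))


def small_config(seed=0, layout="mixed_margin", rows=14, cols=16, **simulate_kw):
    """A reduced-raster config for fast end-to-end tests."""
    cfg = PipelineConfig(seed=seed)
    sim = cfg.simulate.model_copy(
        update={"layout": layout, "n_rows": rows, "n_cols": cols, **simulate_kw})
    return cfg.model_copy(update={"simulate": sim})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
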
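import numpy as np
import pytest

from nucitox.synthetic import DrugEffectSpec, FieldSpec, PlateConfig, generate_field


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def neutral_effect():
    return DrugEffectSpec("DMSO", ic50_true=1.0)


@pytest.fixture()
def small_field(neutral_effect):
    """A modest 256x256 field with 12 small cells, reused across tests."""
    spec = FieldSpec(height=256, width=256, n_cells=12, seed=7)
    return spec, generate_field(spec, neutral_effect)


@pytest.fixture()
def noise_free_plate_cfg():
    return PlateConfig(noise_cv=0.0, replicates=3, seed=11)
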
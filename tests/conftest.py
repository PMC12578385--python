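import numpy as np
import pytest

from emdiff import EffectSpec, SimConfig, generate_dataset
from emdiff.qc import normalize_sqrt


@pytest.fixture(scope="session")
def small_dataset():
    """Two cell types x two groups, a handful of planted shifts."""
    effects = (
        EffectSpec(gene=0, cell_type="neuron", group="MUT",
                   kind="shift", magnitude=2.0),
        EffectSpec(gene=1, cell_type="neuron", group="MUT",
                   kind="subpop_shift", magnitude=3.0, affected_fraction=0.3),
        EffectSpec(gene=2, cell_type="neuron", group="MUT",
                   kind="scale", magnitude=4.0),
    )
    cfg = SimConfig(
        n_genes=400, n_mito_genes=8, cell_types=("neuron", "glia"),
        groups=("WT", "MUT"), cells_per_population=120,
        baseline_logmean_mu=np.log(5.0), baseline_logmean_sigma=0.4,
        nb_dispersion=10.0, effects=effects, seed=42,
    )
    cm, metadata, truth = generate_dataset(cfg)
    return cfg, cm, metadata, truth


@pytest.fixture(scope="session")
def small_expression(small_dataset):
    _, cm, metadata, _ = small_dataset
    return normalize_sqrt(cm), metadata
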
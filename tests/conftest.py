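import numpy as np
import pytest

from ftirsel import (
    SyntheticConfig,
    TrainOptions,
    generate,
    make_folds,
    scale_to_unit_interval,
)
from ftirsel.ssae import fit_ssae


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-axis 13-class dataset with planted informative bands."""
    cfg = SyntheticConfig(n_points=400, n_per_class=12, seed=11)
    dataset, ground_truth = generate(cfg)
    return dataset, ground_truth, cfg


@pytest.fixture(scope="session")
def trained_ssae(small_dataset):
    """A small fully trained SSAE on the scaled small dataset."""
    dataset, _, _ = small_dataset
    scaled, record = scale_to_unit_interval(dataset)
    model = fit_ssae(
        scaled.absorbance,
        dataset.labels,
        (32, 13),
        pretrain_opts=TrainOptions(epochs=100, learning_rate=0.2, seed=5),
        finetune_opts=TrainOptions(epochs=600, learning_rate=0.1, momentum=0.95, seed=5),
    )
    return model, scaled, record


def rel_err(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = max(np.max(np.abs(a)), np.max(np.abs(b)), 1e-12)
    return np.max(np.abs(a - b)) / denom
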
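"""Shared fixtures: the reference synthetic study and trained models.

Training the sequence model on the full reference design takes a couple of
minutes per seed, so the trained results are session-scoped and shared by
the learning, annotation, denoising and TF-activity tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from probatac.model import AccessibilityModel, desk_config
from probatac.synthetic import default_design, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

REFERENCE_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def reference_dataset():
    """The reference corrupted study: 3 cell types x 200 cells, 1000 peaks of
    300 bp, 3 planted motifs, depth-dependent dropout (nominal delta 0.3)."""
    return simulate_dataset(default_design(seed=REFERENCE_SEEDS[0]))


def train_on(dataset, seed):
    config = desk_config(dataset.design.n_cells, dataset.design.peak_length,
                         seed=seed)
    model = AccessibilityModel.from_dataset(dataset, config)
    return model, model.fit()


@pytest.fixture(scope="session")
def trained_reference(reference_dataset):
    """(model, results) trained on the reference dataset (first seed)."""
    return train_on(reference_dataset, REFERENCE_SEEDS[0])


@pytest.fixture(scope="session")
def replicate_runs(reference_dataset, trained_reference):
    """Three replicate (dataset, fitted results) pairs; the first reuses the
    session model."""
    runs = [(reference_dataset, trained_reference[1])]
    for seed in REFERENCE_SEEDS[1:]:
        ds = simulate_dataset(default_design(seed=seed))
        _, res = train_on(ds, seed)
        runs.append((ds, res))
    return runs


@pytest.fixture(scope="session")
def trained_replicates(replicate_runs):
    """Held-out auROC (vs clean truth) per replicate seed."""
    return np.array([res.evaluate_auroc("test", labels=ds.truth)
                     for ds, res in replicate_runs])


@pytest.fixture(scope="session")
def reference_types(reference_dataset):
    return np.array([int(lab[4:]) for lab in reference_dataset.cell_labels])
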
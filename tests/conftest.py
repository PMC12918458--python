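"""Shared fixtures: model specs, simulated datasets, and CFA scaffolding.

Heavier artifacts (the n = 5000 recovery dataset and its polychoric matrix)
are session-scoped so the module tests and the acceptance suite share one
computation.
"""

import numpy as np
import pytest

from nomoscan import corr, mtmm, pipeline, synthetic


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.build_model_spec()


@pytest.fixture(scope="session")
def cfa_spec(default_spec):
    cb = pipeline.codebook_from_spec(default_spec)
    factors = [f"{m}_{t}" for m in cb.methods for t in cb.traits]
    assignment = {it.column: f"{it.method}_{it.trait}" for it in cb.items}
    return mtmm.CFAModelSpec(factors=factors, assignment=assignment)


@pytest.fixture(scope="session")
def small_dataset(default_spec):
    """Preset-shaped dataset at the study's sample size."""
    items, criteria, truth = synthetic.simulate_dataset(default_spec, 504, 42)
    cb = pipeline.codebook_from_spec(default_spec)
    return pipeline.LikertDataset(items, criteria, cb)


@pytest.fixture(scope="session")
def recovery_fit(default_spec, cfa_spec):
    """DWLS fit to n = 5000 simulated data, shared across recovery tests."""
    items, _criteria, _truth = synthetic.simulate_dataset(default_spec, 5000, 7)
    poly, variances = corr.polychoric_matrix(items, with_variance=True)
    fit = mtmm.fit_dwls(poly, cfa_spec, n=5000, weights=variances, seed=0)
    return fit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
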
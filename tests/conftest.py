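"""Shared fixtures: toy organisms, built ME models, synthetic benchmarks.

Expensive artifacts (the standard feature-selection benchmark run, the toy
growth curve) are session-scoped so unit and acceptance tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from omegrow.compendium import ExpressionCompendium
from omegrow.me import build_me_model
from omegrow.ml.datasets import MLDataset
from omegrow.synthdata import (
    make_ml_benchmark,
    make_regulatory_truth,
    make_synthetic_compendium,
    make_toy_organism,
    make_two_view_benchmark,
)


@pytest.fixture(scope="session")
def toy_organism():
    return make_toy_organism(seed=0)


@pytest.fixture(scope="session")
def toy_model(toy_organism):
    org, pds, kcat = toy_organism
    return build_me_model(org, pds, kcat)


@pytest.fixture(scope="session")
def toy_model_no_ceiling():
    org, pds, kcat = make_toy_organism(seed=0, include_machinery_ceiling=False)
    return build_me_model(org, pds, kcat)


@pytest.fixture(scope="session")
def toy_growth_curve(toy_model):
    from omegrow.me import classify_regions, growth_curve

    grid = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0, 8.0,
            9.0, 10.0]
    return classify_regions(growth_curve(toy_model, "EX_glc", grid,
                                         mu_max_bracket=5.0))


@pytest.fixture(scope="session")
def regression_compendium():
    """Clean 500-array compendium with planted TF effects (σ = 0.1)."""
    org, _, _ = make_toy_organism(n_genes=30, n_enzymes=27, seed=1)
    net, rtruth = make_regulatory_truth(org, n_tfs=4, seed=3)
    tables, _, clean, truth = make_synthetic_compendium(
        org, n_arrays=500, noise_sd=0.1, missing_frac=0.0, outlier_frac=0.0,
        regulatory=(net, rtruth), seed=4,
    )
    meta = pd.concat([t.array_meta for t in tables])
    comp = ExpressionCompendium(
        values=clean,
        array_meta=meta,
        missing_mask=clean.isna(),
        outlier_mask=clean.isna(),
        provenance=clean.astype(str),
    )
    return comp, net, rtruth, truth


@pytest.fixture(scope="session")
def feature_benchmark():
    """Standard planted-feature benchmark: 500 features, 20 informative."""
    X, y, truth = make_ml_benchmark(seed=0)
    return MLDataset(X, y, "transcription"), truth


@pytest.fixture(scope="session")
def hdmppk_run(feature_benchmark):
    from omegrow.ml.hdmppk import hdmppk

    ds, truth = feature_benchmark
    out, report = hdmppk(ds, seed=0)
    return out, report, truth


@pytest.fixture(scope="session")
def two_view_benchmark():
    Xa, Xb, y, truth = make_two_view_benchmark(seed=0)
    tx = MLDataset(Xa, y, "transcription")
    tl = MLDataset(Xb, y, "translation")
    return tx, tl, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
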
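"""Shared fixtures: one small synthetic world and a quick trained model.

The session world is small (6 x 5 grid, three years, five stations) but
carries the full generative structure — GDD-bump x evaporation-band truth,
negative-binomial counts, severe imbalance — so every pipeline stage can
be exercised quickly.  The model fixture trains on the birch-like taxon,
whose higher prevalence gives enough positive days for stratified CV.
"""

import pandas as pd
import pytest

from pollenlevels import (
    ModelSpec,
    SyntheticConfig,
    assemble_features,
    assign_levels,
    delimit_all_seasons,
    generate_world,
    taxon_analysis_window,
    train_classifier,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_cells_x=6, n_cells_y=5, years=(1999, 2000, 2001), n_sites=5, seed=42
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


def labeled_taxon_features(world, taxon):
    """Window-restricted labeled feature table for one taxon."""
    sub = world.pollen[world.pollen["taxon"] == taxon]
    labeled = assign_levels(sub)
    window = taxon_analysis_window(delimit_all_seasons(sub))
    return (
        assemble_features(world.met, world.sites, labels=labeled, window=window),
        window,
    )


@pytest.fixture(scope="session")
def betula_features(small_world):
    feats, _ = labeled_taxon_features(small_world, "Betula")
    return feats


@pytest.fixture(scope="session")
def quick_spec():
    return ModelSpec(ntree=150, mtry_grid=(5, 10), cv_folds=3, cv_repeats=2, seed=0)


@pytest.fixture(scope="session")
def small_model(betula_features, quick_spec):
    return train_classifier(betula_features, quick_spec)
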
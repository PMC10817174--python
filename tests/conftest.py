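"""Shared fixtures: synthetic panels and trained models.

Expensive fits (the strong-signal recovery panel and the two models
trained on it) are session-scoped so recovery, consistency and
acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import rmsrepurpose as rr
from rmsrepurpose.aenn import panel_layers

#: conditions for the signal-recovery checks: strong pathway-level
#: signal (oracle AUC > 0.95), n = 600 lines, compact model dimensions
STRONG_CONFIG = rr.PanelConfig(
    n_cell_lines=600,
    n_genes=200,
    n_drugs=1,
    n_informative_genes=10,
    effect_size=2.0,
    sensitive_prevalence=0.15,
    seed=3,
)

AENN_PARAMS = dict(
    bottleneck_dim=16,
    ae_hidden_dims=(64,),
    classifier_hidden_dims=(32,),
    ae_epochs=15,
    learning_rate=0.01,
    batch_size=16,
    seed=0,
)

SUPERFELT_PARAMS = dict(
    embedding_dim=16,
    encoder_hidden_dims=(32,),
    classifier_hidden_dims=(16,),
    encoder_epochs=8,
    classifier_epochs=8,
    learning_rate=0.01,
    batch_size=32,
    seed=0,
)


@pytest.fixture(scope="session")
def strong_panel():
    panel, responses, truth = rr.generate_panel(STRONG_CONFIG)
    pre = rr.preprocess_panel(panel, keep_fraction=None)
    return pre, responses, truth


@pytest.fixture(scope="session")
def strong_drug(strong_panel):
    _, responses, _ = strong_panel
    return responses.index[0]


@pytest.fixture(scope="session")
def aenn_strong(strong_panel, strong_drug):
    pre, responses, _ = strong_panel
    y = responses.loc[strong_drug].to_numpy()
    model = rr.AENNClassifier(**AENN_PARAMS)
    model.fit(panel_layers(pre, ("expression", "cn_binary")), y)
    return model


@pytest.fixture(scope="session")
def superfelt_strong(strong_panel, strong_drug):
    pre, responses, _ = strong_panel
    y = responses.loc[strong_drug].to_numpy()
    model = rr.SuperFeltClassifier(**SUPERFELT_PARAMS)
    model.fit(panel_layers(pre, ("expression", "cn_binary", "mutation")), y)
    return model


@pytest.fixture(scope="session")
def small_panel():
    """A quick panel for shape/contract tests."""
    config = rr.PanelConfig(
        n_cell_lines=120, n_genes=40, n_drugs=2, n_informative_genes=5,
        effect_size=2.0, sensitive_prevalence=0.25, seed=7,
    )
    panel, responses, truth = rr.generate_panel(config)
    return rr.preprocess_panel(panel, keep_fraction=None), responses, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
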
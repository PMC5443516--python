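"""Shared fixtures: expensive synthetic datasets are built once per session."""

import numpy as np
import pandas as pd
import pytest

from tmcontact import dca, learning, msa, synthetic

PLANTED_PAIRS = [(2, 14), (5, 25), (8, 20), (11, 28), (16, 30)]


@pytest.fixture(scope="session")
def planted_dca():
    """DCA run on an MSA sampled from a 5-pair planted coupling model."""
    model = synthetic.PlantedModel(
        length=30, planted_pairs=PLANTED_PAIRS, coupling_strength=2.0, seed=7
    )
    aln = synthetic.sample_coupled_msa(model, 2000)
    weights = msa.sequence_weights(aln)
    result = dca.run_dca(aln, weights)
    return {"model": model, "alignment": aln, "weights": weights, "result": result}


@pytest.fixture(scope="session")
def independent_dca():
    """DCA run on 2000 sequences of independent, uniform columns."""
    model = synthetic.PlantedModel(
        length=30, planted_pairs=[], coupling_strength=0.0, seed=11
    )
    aln = synthetic.sample_coupled_msa(model, 2000)
    return dca.run_dca(aln)


@pytest.fixture(scope="session")
def e2e():
    """End-to-end synthetic protein plus its DCA score matrix."""
    fx = synthetic.make_end_to_end_fixture(seed=3, n_sequences=1500)
    weights = msa.sequence_weights(fx.alignment)
    result = dca.run_dca(fx.alignment, weights)
    return {"fixture": fx, "weights": weights, "di": result.di}


@pytest.fixture(scope="session")
def separable_dataset():
    """Linearly separable pair records spread over 25 pseudo-proteins."""
    rng = np.random.default_rng(42)
    n = 5000
    X = rng.normal(size=(n, 10))
    y = (X[:, 0] + X[:, 1] > 0).astype(float)
    prot = np.repeat([f"P{k:02d}" for k in range(25)], n // 25)
    df = pd.DataFrame({"protein_id": prot, "i": np.arange(n), "j": np.arange(n) + 12})
    for k in range(10):
        df[f"f{k}"] = X[:, k]
    df["label"] = y
    plan = learning.make_cv_plan(sorted(set(prot)), seed=1)
    return {"data": df, "plan": plan}


@pytest.fixture(scope="session")
def trained_ensembles(separable_dataset):
    """DT and ANN ensembles trained on the separable dataset."""
    df, plan = separable_dataset["data"], separable_dataset["plan"]
    config = learning.TrainingConfig(seed=1)
    return {
        kind: learning.train_ensemble(df, plan, kind, config) for kind in ("dt", "ann")
    }
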
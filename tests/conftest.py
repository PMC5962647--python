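import numpy as np
import pandas as pd
import pytest

import gasca


def make_balanced_dataset(levels, replicates, n_vars, seed, effect_sizes=None):
    """Random balanced dataset, optionally with per-factor level shifts on all variables."""
    spec = gasca.SimulationSpec(
        levels=tuple(levels),
        replicates=replicates,
        n_vars=n_vars,
        planted=[],
        seed=seed,
    )
    dataset, _ = gasca.simulate_planted(spec)
    if effect_sizes:
        rng = np.random.default_rng(seed + 1)
        X = dataset.X.to_numpy()
        for i, d in enumerate(effect_sizes):
            if d == 0:
                continue
            labels = dataset.design.iloc[:, i]
            codes = pd.Categorical(labels).codes
            offsets = d * np.linspace(-1, 1, levels[i])
            X = X + np.outer(offsets[codes], rng.normal(0, 1, n_vars) / np.sqrt(n_vars))
        dataset = gasca.DesignedDataset(
            X=pd.DataFrame(X, index=dataset.X.index, columns=dataset.X.columns),
            design=dataset.design,
        )
    return dataset


@pytest.fixture(scope="session")
def planted():
    """The reference simulated experiment: 4x3 design, R=8, J=50, two planted groups."""
    dataset, truth = gasca.simulate_planted(gasca.SimulationSpec(seed=0))
    return dataset, truth


@pytest.fixture(scope="session")
def planted_decomp(planted):
    dataset, _ = planted
    return gasca.decompose(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
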
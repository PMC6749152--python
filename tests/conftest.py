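import numpy as np
import pandas as pd
import pytest

from circenet.diffexpr import ExpressionDataset
from circenet.network import CIRC, MRNA, InteractionSet
from circenet.simulate import SimulationConfig, simulate_study

# A scaled-down study used wherever the full default design is not the
# point of the test.
FAST_KWARGS = dict(
    n_features=400,
    n_datasets=3,
    n_case=6,
    n_control=6,
    n_mrna=200,
    n_circ=30,
    n_mir=100,
    n_planted_circ=6,
    n_pairs_per_circ=3,
    n_known_genes=15,
    n_known_mirs=20,
    n_genesets=25,
    geneset_size=20,
)


@pytest.fixture
def fast_config():
    return SimulationConfig(seed=11, **FAST_KWARGS)


@pytest.fixture
def fast_study(fast_config):
    return simulate_study(fast_config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_dataset(rng, n_features=60, n_case=5, n_control=5, tag="ds", de_shift=None,
                 var_prior=None):
    """Small two-group dataset; ``de_shift`` adds a shift to the first
    half of features in the case group; ``var_prior=(d0, s0_sq)`` draws
    per-feature variances from the scaled inverse chi-square prior
    (otherwise all features have unit variance)."""
    cols = [f"{tag}_c{i}" for i in range(n_case)] + [
        f"{tag}_k{i}" for i in range(n_control)
    ]
    vals = rng.normal(size=(n_features, n_case + n_control))
    if var_prior is not None:
        d0, s0_sq = var_prior
        sigma2 = s0_sq * d0 / rng.chisquare(d0, size=n_features)
        vals *= np.sqrt(sigma2)[:, None]
    if de_shift:
        vals[: n_features // 2, :n_case] += de_shift
    values = pd.DataFrame(vals, index=[f"f{i:03d}" for i in range(n_features)], columns=cols)
    conditions = pd.Series(["case"] * n_case + ["control"] * n_control, index=cols)
    return ExpressionDataset(values=values, conditions=conditions, tag=tag)


def random_interactions(rng, n_circ=20, n_mrna=30, n_mir=40, p=0.08):
    """Dense-ish random typed interaction set for oracle comparisons."""
    records = []
    for i in range(n_mir):
        mir = f"m{i:02d}"
        for j in range(n_circ):
            if rng.random() < p:
                records.append((mir, f"c{j:02d}", CIRC))
        for j in range(n_mrna):
            if rng.random() < p:
                records.append((mir, f"g{j:02d}", MRNA))
    return InteractionSet.from_records(records)
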
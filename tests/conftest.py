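import numpy as np
import pytest

from koplspa import (
    SPAConfig,
    SyntheticDesign,
    generate_peak_table,
    grid_search,
    normalize_internal_standard,
    run_spa,
)

PLANTED_INDICES = (1, 2, 4, 5, 6, 10)
N_REPLICATES = 100
SPA_RUNS = 200


def make_cohort(seed, **kwargs):
    """Concentration matrix + labels for a synthetic 100+100 cohort."""
    defaults = dict(n_group1=100, n_group2=100, seed=seed)
    defaults.update(kwargs)
    table = generate_peak_table(SyntheticDesign(**defaults))
    return normalize_internal_standard(table)


@pytest.fixture(scope="session")
def separable_xy():
    """Two far-separated compact clusters (trivially classifiable)."""
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(-3, 0.15, (20, 4)), rng.normal(3, 0.15, (20, 4))])
    y = np.r_[np.zeros(20, int), np.ones(20, int)]
    return X, y


@pytest.fixture(scope="session")
def random_xy():
    """Unstructured data for algebraic/orthogonality checks."""
    rng = np.random.default_rng(11)
    X = rng.standard_normal((30, 5))
    y = np.r_[np.zeros(15, int), np.ones(15, int)]
    return X, y


@pytest.fixture(scope="session")
def spa_hyperparams():
    """(sigma, Ao) selected by cross-validated grid search on one planted cohort.

    Submodel hyperparameters are fixed at the externally CV-selected values,
    as in the full pipeline.
    """
    conc = make_cohort(seed=42, informative_indices=PLANTED_INDICES, effect_size=2.0)
    res = grid_search(
        conc.values, conc.labels, sigma_grid=(0.5, 1, 2, 5), ao_grid=(1, 2),
        seed=0, compute_stats=False,
    )
    return res.best_sigma, res.best_Ao


@pytest.fixture(scope="session")
def planted_spa_replicates(spa_hyperparams):
    """SPA score lists over replicate cohorts with 6 of 10 metabolites planted."""
    sigma, ao = spa_hyperparams
    out = []
    for seed in range(N_REPLICATES):
        conc = make_cohort(
            seed=20_000 + seed, informative_indices=PLANTED_INDICES, effect_size=2.0
        )
        scores = run_spa(
            conc.values, conc.labels, conc.metabolite_names,
            SPAConfig(N=SPA_RUNS, sigma=sigma, ao=ao, seed=seed),
        )
        out.append(scores)
    return out


@pytest.fixture(scope="session")
def null_spa_replicates(spa_hyperparams):
    """SPA score lists over replicate cohorts with no informative metabolites."""
    sigma, ao = spa_hyperparams
    out = []
    for seed in range(N_REPLICATES):
        conc = make_cohort(seed=30_000 + seed, informative_indices=(), effect_size=0.0)
        scores = run_spa(
            conc.values, conc.labels, conc.metabolite_names,
            SPAConfig(N=SPA_RUNS, sigma=sigma, ao=ao, seed=seed),
        )
        out.append(scores)
    return out
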
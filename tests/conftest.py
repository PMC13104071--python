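import numpy as np
import pytest

from permacomm.datamodel import CommunityTable
from permacomm.simulate import SimulationConfig, generate_community, generate_metadata


def make_table(counts, taxon_ids=None, sample_ids=None, lineages=None):
    counts = np.asarray(counts)
    taxon_ids = taxon_ids or [f"T{i}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(counts.shape[1])]
    lineages = lineages or ["d__Bacteria;p__Proteobacteria"] * counts.shape[0]
    return CommunityTable(taxon_ids, lineages, counts, sample_ids)


@pytest.fixture
def tiny_table():
    return make_table([[5, 0, 2], [0, 3, 2], [5, 7, 6]])


def small_config(**overrides):
    """Desk-scale profile: 2 sites x 12 depths, 150 taxa, 2000 reads.

    Migration is raised to 0.3 so that Nm_true = m * reads stays near the
    full-size default (Nm = 1000) despite the smaller read depth.
    """
    kwargs = dict(
        n_sites=2, depths_per_site=12, species_pool_size=150,
        reads_per_sample=2000, migration=0.3, seed=0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_config(seed=11)
    frame = generate_metadata(cfg)
    table, truth = generate_community(cfg, frame)
    table, _ = table.drop_zero_taxa()
    return table, frame, truth


def lognormal_compositional_counts(
    n_taxa=50, n_samples=200, rho=0.0, depth=5000, seed=0, pair=(0, 1)
):
    """Log-normal basis abundances (optionally one correlated pair),
    turned compositional by multinomial sampling - the SparCC test bed.

    The planted pair sits at slightly-above-average abundance so its
    signal is not drowned by counting noise when it lands on rare taxa.
    """
    rng = np.random.default_rng(seed)
    cov = np.eye(n_taxa)
    if rho:
        cov[pair[0], pair[1]] = cov[pair[1], pair[0]] = rho
    mu = rng.normal(0.0, 1.0, n_taxa)
    mu[pair[0]] = mu[pair[1]] = 0.5
    z = rng.multivariate_normal(np.zeros(n_taxa), cov, size=n_samples)
    x = np.exp(mu[None, :] + z)
    frac = x / x.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(depth, frac[j]) for j in range(n_samples)]
    ).T
    return counts
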
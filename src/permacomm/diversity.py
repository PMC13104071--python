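"""Alpha/beta diversity, ordination, group tests, dispersion, distance decay.

Bray-Curtis is computed on (rarefied) counts. Shannon uses the natural
logarithm. PCoA is classical scaling of the Gower-centred matrix; negative
eigenvalues are retained in the result but excluded from the
``proportion_explained`` denominator (sum of positive eigenvalues only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datamodel import CommunityTable, DistanceMatrix
from .preprocess import relative_abundance


# --------------------------------------------------------------------------
# alpha diversity
# --------------------------------------------------------------------------

def richness(table: CommunityTable) -> np.ndarray:
    """Number of taxa with count > 0, per sample."""
    return (table.counts > 0).sum(axis=0)


def shannon(table: CommunityTable) -> np.ndarray:
    """Shannon index H = -sum p ln p over positive proportions, per sample."""
    p = relative_abundance(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=0)


# --------------------------------------------------------------------------
# beta diversity
# --------------------------------------------------------------------------

def bray_curtis_matrix(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity BC(x,y) = sum|x-y| / sum(x+y)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sums = table.sample_sums()
    if (sums == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray       # samples x axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray       # all eigenvalues, descending
    proportion_explained: np.ndarray  # per positive axis, denom = sum of positives
    ids: list


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (classical scaling)."""
    g = _gower_center(dist.values)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    denom = evals[pos].sum()
    prop = evals[pos] / denom if denom > 0 else np.zeros(pos.sum())
    return OrdinationResult(coords, evals, prop, list(dist.ids))


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def _permanova_stats(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray):
    n = d2.shape[0]
    sst = d2.sum() / (2.0 * n)
    within = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / (2.0 * sizes)
    ssw = within.sum()
    ssa = sst - ssw
    a = len(sizes)
    f = (ssa / (a - 1)) / (ssw / (n - a))
    return f, ssa / sst


def permanova(
    dist: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), permuting sample labels
    freely (no strata).
    """
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inv)
    if len(labels) < 2 or (sizes < 2).any():
        raise ValueError("permanova needs >=2 groups with >=2 samples each")
    d2 = dist.values ** 2
    n = d2.shape[0]
    onehot = np.zeros((n, len(labels)))
    onehot[np.arange(n), inv] = 1.0
    f_obs, r2 = _permanova_stats(d2, onehot, sizes.astype(float))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_p, _ = _permanova_stats(d2, onehot[perm], sizes.astype(float))
        if f_p >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def group_dispersion(dist: DistanceMatrix, groups) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    Follows the standard beta-dispersion construction: centroids live in
    the full principal-coordinate space; squared distances along
    negative-eigenvalue axes are subtracted from those along positive axes
    and the result floored at zero before the square root.
    """
    groups = np.asarray(groups)
    g = _gower_center(dist.values)
    evals, evecs = np.linalg.eigh(g)
    pos = evals > 1e-10
    neg = evals < -1e-10
    xpos = evecs[:, pos] * np.sqrt(evals[pos])
    xneg = evecs[:, neg] * np.sqrt(-evals[neg])
    out = np.zeros(len(groups))
    for lab in np.unique(groups):
        m = groups == lab
        cp = xpos[m].mean(axis=0)
        cn = xneg[m].mean(axis=0)
        d2 = ((xpos[m] - cp) ** 2).sum(axis=1) - ((xneg[m] - cn) ** 2).sum(axis=1)
        out[m] = np.sqrt(np.clip(d2, 0.0, None))
    return out


# --------------------------------------------------------------------------
# distance decay
# --------------------------------------------------------------------------

def environmental_distance(env: np.ndarray, ids) -> DistanceMatrix:
    """Euclidean distance over z-standardised environmental variables."""
    env = np.asarray(env, dtype=float)
    if env.ndim == 1:
        env = env[:, None]
    sd = env.std(axis=0, ddof=1)
    if (sd == 0).all():
        raise ValueError("all environmental variables are constant")
    keep = sd > 0
    z = (env[:, keep] - env[:, keep].mean(axis=0)) / sd[keep]
    return DistanceMatrix(list(ids), squareform(pdist(z)))


def distance_decay(
    similarity: DistanceMatrix,
    env_dist: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
):
    """Least-squares decay of community similarity with environmental distance.

    ``similarity`` holds 1 - Bray-Curtis off-diagonal (stored in a
    DistanceMatrix container for alignment; its diagonal is ignored).
    Significance is a Mantel-style permutation of sample identities.

    Returns (slope, r, p).
    """
    if list(similarity.ids) != list(env_dist.ids):
        raise ValueError("similarity and env_dist must share sample ids")
    x = env_dist.condensed()
    if x.std() == 0:
        raise ValueError("environmental distances are constant")
    y = similarity.condensed()
    slope, intercept = np.polyfit(x, y, 1)
    r_obs = np.corrcoef(x, y)[0, 1]
    rng = np.random.default_rng(seed)
    n = similarity.n
    hits = 0
    sim = similarity.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = sim[np.ix_(perm, perm)][np.triu_indices(n, k=1)]
        if abs(np.corrcoef(x, yp)[0, 1]) >= abs(r_obs):
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(slope), float(r_obs), float(p)


def similarity_matrix(dist: DistanceMatrix) -> DistanceMatrix:
    """1 - dissimilarity off-diagonal, packaged for pairwise analyses."""
    s = 1.0 - dist.values
    np.fill_diagonal(s, 0.0)
    return DistanceMatrix(list(dist.ids), s)
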
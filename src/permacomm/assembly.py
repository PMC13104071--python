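"""Community-assembly inference.

Four tools quantifying how deterministic (environmental selection) versus
stochastic (drift + dispersal) processes structure communities:

* a richness-preserving, occurrence-frequency-proportional null model and
  the normalised stochasticity ratio built on it (boundary 0.5: > 0.5
  more stochastic, < 0.5 more deterministic);
* the Sloan neutral community model, predicting taxon occupancy from mean
  relative abundance through a Beta distribution parameterised by Nm;
* Levins niche overlap across samples-as-resource-states;
* a "modified Mantel" test that picks the best of four linear/log model
  forms per variable pair before permutation inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

from .datamodel import CommunityTable, DistanceMatrix
from .preprocess import relative_abundance


# --------------------------------------------------------------------------
# null model + stochasticity ratio
# --------------------------------------------------------------------------

def _pps_systematic(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """Draw exactly k units with inclusion probability k*w_i/sum(w).

    Systematic probability-proportional-to-size sampling (randomised unit
    order): inclusion probabilities are exactly proportional to the
    weights, capped at 1 (capped units are always included and the
    remainder re-scaled).
    """
    n = len(weights)
    pi = np.zeros(n)
    remaining = np.flatnonzero(weights > 0)
    k_left = k
    while True:
        w = weights[remaining]
        p = k_left * w / w.sum()
        over = p >= 1.0
        if not over.any():
            pi[remaining] = p
            break
        certain = remaining[over]
        pi[certain] = 1.0
        k_left -= len(certain)
        remaining = remaining[~over]
        if k_left <= 0 or len(remaining) == 0:
            break
    certain = np.flatnonzero(pi >= 1.0)
    frac_idx = np.flatnonzero((pi > 0) & (pi < 1.0))
    n_frac = k - len(certain)
    if n_frac <= 0:
        return certain[:k]
    order = rng.permutation(frac_idx)
    cum = np.cumsum(pi[order])
    u = rng.uniform(0.0, 1.0)
    picks = np.searchsorted(cum, u + np.arange(n_frac), side="right")
    picks = np.clip(picks, 0, len(order) - 1)
    return np.concatenate([certain, order[np.unique(picks)]])


def null_communities(
    table: CommunityTable,
    n_null: int = 200,
    seed: int | None = None,
):
    """Yield randomised abundance matrices under the occurrence-frequency null.

    Each null sample keeps its observed richness and total count; which
    taxa are present is re-drawn with inclusion probability proportional
    to each taxon's occurrence frequency in the table's sample pool
    (systematic PPS sampling, so the proportionality is exact up to
    capping at 1), and the sample total is re-allocated among the drawn
    taxa proportionally to their pool-level mean relative abundance by
    drawing individuals (one guaranteed per drawn taxon, the remainder
    multinomial), so null counts carry the same counting noise as
    observed counts.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    counts = table.counts
    n_taxa, n_samples = counts.shape
    occ_freq = (counts > 0).sum(axis=1).astype(float)
    if occ_freq.sum() == 0:
        raise ValueError("empty table")
    pool_mean = relative_abundance(table).mean(axis=1)
    rich = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    rng = np.random.default_rng(seed)
    for _ in range(n_null):
        null = np.zeros((n_taxa, n_samples))
        for j in range(n_samples):
            k = int(rich[j])
            if k == 0:
                continue
            chosen = _pps_systematic(rng, occ_freq, k)
            w = pool_mean[chosen]
            if w.sum() == 0:
                w = np.ones(len(chosen), dtype=float)
            w = w / w.sum()
            total = int(totals[j])
            if total >= len(chosen):
                alloc = 1 + rng.multinomial(total - len(chosen), w)
            else:
                alloc = total * w
            null[chosen, j] = alloc
        yield null


@dataclass
class StochasticityResult:
    pair_ratios: np.ndarray          # clamped to [0, 1], within-group pairs
    raw_ratios: np.ndarray           # unclamped, for audit
    mean_ratio: float
    null_model: str = "occurrence-frequency-proportional"
    n_null: int = 200
    seed: int | None = None


def stochasticity_ratio(
    table: CommunityTable,
    n_null: int = 200,
    seed: int | None = None,
) -> StochasticityResult:
    """Normalised stochasticity ratio for one group of samples.

    For each sample pair, similarity = 1 - Bray-Curtis. When the observed
    similarity >= the mean null similarity (selection pulls communities
    together), ratio = E[sim_null] / sim_obs; when observed < null
    (selection pushes them apart), ratio = E[dis_null] / dis_obs. Either
    form is 1 under pure stochasticity and shrinks toward 0 with stronger
    selection; values are clamped to [0, 1] and averaged over pairs.
    """
    n = table.n_samples
    if n < 3:
        raise ValueError("need >= 3 samples in the group")
    obs_d = pdist(table.counts.T.astype(float), metric="braycurtis")
    null_d = np.zeros_like(obs_d)
    for null in null_communities(table, n_null=n_null, seed=seed):
        null_d += pdist(null.T, metric="braycurtis")
    null_d /= n_null
    obs_s = 1.0 - obs_d
    null_s = 1.0 - null_d
    raw = np.empty_like(obs_d)
    sel_sim = obs_s >= null_s
    with np.errstate(divide="ignore", invalid="ignore"):
        raw[sel_sim] = null_s[sel_sim] / obs_s[sel_sim]
        raw[~sel_sim] = null_d[~sel_sim] / obs_d[~sel_sim]
    # pairs with zero observed similarity cannot be scored against the
    # null on the similarity scale; by convention they are treated as
    # maximally stochastic (ratio 1) and flagged
    undef = ~np.isfinite(raw) | ((obs_s == 0) & (null_s > 0))
    if undef.any():
        warnings.warn(
            f"{undef.sum()} pair(s) had zero observed similarity; ratio set to 1"
        )
        raw[undef] = 1.0
    ratios = np.clip(raw, 0.0, 1.0)
    return StochasticityResult(
        pair_ratios=ratios,
        raw_ratios=raw,
        mean_ratio=float(ratios.mean()),
        n_null=n_null,
        seed=seed,
    )


def stochasticity_by_group(
    table: CommunityTable, groups, n_null: int = 200, seed: int | None = None
) -> dict:
    """Stochasticity ratio per group label (nulls drawn within each group)."""
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    out = {}
    for lab in np.unique(groups):
        ids = [s for s, g in zip(table.sample_ids, groups) if g == lab]
        sub = table.select_samples(ids)
        sub, _ = sub.drop_zero_taxa()
        out[lab] = stochasticity_ratio(
            sub, n_null=n_null, seed=int(rng.integers(2 ** 31))
        )
    return out


# --------------------------------------------------------------------------
# Sloan neutral community model
# --------------------------------------------------------------------------

@dataclass
class NeutralFit:
    Nm: float
    m: float
    R2: float
    detection_limit: float
    mean_rel_abundance: np.ndarray
    observed_occupancy: np.ndarray
    predicted_occupancy: np.ndarray
    m_exceeds_one: bool = False


def sloan_occupancy(p: np.ndarray, Nm: float, d: float) -> np.ndarray:
    """Predicted occupancy 1 - BetaCDF(d; Nm*p, Nm*(1-p))."""
    p = np.asarray(p, dtype=float)
    return 1.0 - stats.beta.cdf(d, Nm * p, Nm * (1.0 - p))


def fit_sloan(p: np.ndarray, occ: np.ndarray, d: float) -> float:
    """Nm by unweighted nonlinear least squares on (p, occupancy) points."""
    p = np.asarray(p, dtype=float)
    occ = np.asarray(occ, dtype=float)
    if np.all(occ == occ[0]):
        raise ValueError("degenerate occupancies (all equal); cannot fit")

    def resid(log_nm):
        return sloan_occupancy(p, np.exp(log_nm), d) - occ

    best = None
    for start in (np.log(10.0), np.log(100.0), np.log(1000.0), np.log(10000.0)):
        try:
            sol = optimize.least_squares(resid, x0=[start], method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("neutral model fit did not converge")
    return float(np.exp(best.x[0]))


def fit_neutral_model(table: CommunityTable) -> NeutralFit:
    """Fit the Sloan neutral model to occupancy vs mean relative abundance.

    The detection limit d is 1 / (mean reads per sample); Nm is found by
    unweighted nonlinear least squares on the per-taxon (p, occupancy)
    points; m = Nm / mean reads per sample.
    """
    if table.n_taxa < 20:
        raise ValueError("need >= 20 taxa to fit the neutral model")
    rel = relative_abundance(table)
    p = rel.mean(axis=1)
    occ = (table.counts > 0).mean(axis=1)
    keep = p > 0
    p, occ = p[keep], occ[keep]
    n_reads = float(table.sample_sums().mean())
    d = 1.0 / n_reads
    nm = fit_sloan(p, occ, d)
    pred = sloan_occupancy(p, nm, d)
    sse = float(((occ - pred) ** 2).sum())
    sst = float(((occ - occ.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    m = nm / n_reads
    return NeutralFit(
        Nm=nm, m=m, R2=r2, detection_limit=d,
        mean_rel_abundance=p, observed_occupancy=occ, predicted_occupancy=pred,
        m_exceeds_one=m > 1.0,
    )


# --------------------------------------------------------------------------
# Levins niche overlap
# --------------------------------------------------------------------------

def niche_overlap(table: CommunityTable) -> float:
    """Community-mean Levins niche overlap across samples-as-resources.

    For taxa j, k with across-sample proportions p_ij: O_jk =
    sum_i p_ij p_ik / sum_i p_ij^2, symmetrised as (O_jk + O_kj)/2, then
    averaged over all taxon pairs.
    """
    counts = table.counts.astype(float)
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        warnings.warn("all-zero taxa excluded from niche overlap")
        counts = counts[row_sums > 0]
        row_sums = row_sums[row_sums > 0]
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 non-empty taxa")
    p = counts / row_sums[:, None]           # per-taxon resource utilisation
    cross = p @ p.T                          # sum_i p_ij p_ik
    denom = np.diag(cross)                   # sum_i p_ij^2
    o = cross / denom[:, None]               # O_jk (rows j)
    sym = (o + o.T) / 2.0
    iu = np.triu_indices(counts.shape[0], k=1)
    return float(sym[iu].mean())


def pairwise_niche_overlap(table: CommunityTable) -> np.ndarray:
    """Symmetrised Levins overlap matrix (diagonal 1)."""
    counts = table.counts.astype(float)
    counts = counts[counts.sum(axis=1) > 0]
    p = counts / counts.sum(axis=1, keepdims=True)
    cross = p @ p.T
    o = cross / np.diag(cross)[:, None]
    return (o + o.T) / 2.0


# --------------------------------------------------------------------------
# modified Mantel test with four model forms
# --------------------------------------------------------------------------

MANTEL_MODELS = ("Y~X", "Y~ln(X)", "ln(Y)~X", "ln(Y)~ln(X)")


@dataclass
class MantelModelFit:
    model: str
    r: float
    p: float
    candidate_r: dict = field(default_factory=dict)
    shift_applied: dict = field(default_factory=dict)
    zero_replacement: dict = field(default_factory=dict)


def _log_ready(v: np.ndarray):
    """Shift a series so ln() is defined, per the min-shift convention.

    If any value is <= 0, subtract the minimum; zeros that result are
    replaced by 0.05 x the minimum positive value of the shifted series.
    Returns (transformed, shift, zero_replacement or None).
    """
    v = np.asarray(v, dtype=float).copy()
    shift = 0.0
    if (v <= 0).any():
        shift = v.min()
        v = v - shift
    repl = None
    if (v == 0).any():
        pos = v[v > 0]
        if pos.size == 0:
            raise ValueError("series is constant at zero after shifting")
        repl = 0.05 * pos.min()
        v[v == 0] = repl
    return v, shift, repl


def modified_mantel(
    comm_dist: DistanceMatrix,
    env: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelModelFit:
    """Mantel test choosing the best of four model forms.

    Y = community pairwise distances, X = pairwise absolute differences of
    the scalar environmental variable. Each of Y~X, Y~ln(X), ln(Y)~X,
    ln(Y)~ln(X) is scored by Pearson |r| on the vectorised pairs and the
    best model reported. The permutation reference replays the whole
    selection - the statistic is max |r| over the four models - so the
    p-value stays calibrated despite the model search.
    """
    env = np.asarray(env, dtype=float)
    if env.std() == 0:
        raise ValueError("environmental variable is constant")
    n = comm_dist.n
    if len(env) != n:
        raise ValueError("env length must match distance matrix")
    x_mat = np.abs(env[:, None] - env[None, :])
    iu = np.triu_indices(n, k=1)
    x = x_mat[iu]
    y = comm_dist.values[iu]

    ln_x, sx, rx = _log_ready(x)
    ln_y, sy, ry = _log_ready(y)
    series = {
        "Y~X": (y, x),
        "Y~ln(X)": (y, np.log(ln_x)),
        "ln(Y)~X": (np.log(ln_y), x),
        "ln(Y)~ln(X)": (np.log(ln_y), np.log(ln_x)),
    }
    cand = {}
    for name, (yy, xx) in series.items():
        if np.std(xx) == 0 or np.std(yy) == 0:
            cand[name] = 0.0
        else:
            cand[name] = float(np.corrcoef(xx, yy)[0, 1])
    best = max(MANTEL_MODELS, key=lambda k: (abs(cand[k]), -MANTEL_MODELS.index(k)))
    r_obs = cand[best]

    # permutation replays the model search: statistic = max |r| over the
    # four candidate models, so selection does not inflate significance
    def max_abs_r(y_lin):
        v, _, _ = _log_ready(y_lin)
        y_log = np.log(v)
        out = 0.0
        for xx in (x, np.log(ln_x)):
            for yy in (y_lin, y_log):
                if np.std(xx) > 0 and np.std(yy) > 0:
                    out = max(out, abs(np.corrcoef(xx, yy)[0, 1]))
        return out

    stat_obs = max(abs(v) for v in cand.values())
    y_full = comm_dist.values
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = y_full[np.ix_(perm, perm)][iu]
        if max_abs_r(yp) >= stat_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MantelModelFit(
        model=best, r=r_obs, p=float(p), candidate_r=cand,
        shift_applied={"X": sx, "Y": sy},
        zero_replacement={"X": rx, "Y": ry},
    )
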
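"""Degradation gradient, taxonomic trends, group tests, and carbon storage.

The permafrost degradation index (PDI) is the first principal component of
site-level active-layer thickness (ALT) and mean annual ground temperature
(MAGT), oriented so larger PDI = more degraded. Species trends are Spearman
correlations with ordinal gradients after a 0.01% mean-abundance noise
filter. Group comparisons are Kruskal-Wallis with BH-corrected pairwise
rank tests and compact letter display. Carbon-storage change is the
consecutive-group percent change of POCD, and the stability-POCD link is a
stratum-adjusted least-squares association with permutation inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CommunityTable, SampleFrame
from .preprocess import filter_taxa_by_mean_abundance, relative_abundance
from .stability import StabilityProfile


# --------------------------------------------------------------------------
# permafrost degradation index
# --------------------------------------------------------------------------

@dataclass
class DegradationIndex:
    sites: list
    pdi: np.ndarray
    loadings: np.ndarray            # (ALT, MAGT) loading on PC1
    variance_explained: float
    flipped: bool


def compute_pdi(site_table: pd.DataFrame) -> DegradationIndex:
    """PC1 of z-standardised per-site ALT and MAGT, oriented along ALT.

    ``site_table`` needs columns ``site``, ``ALT``, ``MAGT`` (one row per
    site). The PC1 score sign is flipped if necessary so that
    corr(PDI, ALT) > 0: larger PDI means deeper thaw, i.e. more degraded.
    """
    if len(site_table) < 3:
        raise ValueError("need >= 3 sites")
    x = site_table[["ALT", "MAGT"]].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("ALT and MAGT must both vary across sites")
    z = (x - x.mean(axis=0)) / sd
    cov = np.cov(z.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    pc1 = evecs[:, -1]
    scores = z @ pc1
    flipped = False
    if np.corrcoef(scores, x[:, 0])[0, 1] < 0:
        pc1, scores, flipped = -pc1, -scores, True
    return DegradationIndex(
        sites=list(site_table["site"]),
        pdi=scores,
        loadings=pc1,
        variance_explained=float(evals[-1] / evals.sum()),
        flipped=flipped,
    )


# --------------------------------------------------------------------------
# species-level trend analysis
# --------------------------------------------------------------------------

def species_trends(
    table: CommunityTable,
    gradient,
    min_mean_rel: float = 1e-4,
    top_n: int = 20,
) -> pd.DataFrame:
    """Spearman trend of each species' relative abundance along a gradient.

    Species with mean relative abundance below ``min_mean_rel`` (default
    0.01%) are filtered out first; the remaining taxa are ranked by |r| and
    the strongest ``top_n`` responders returned with BH-adjusted p.
    """
    gradient = np.asarray(gradient, dtype=float)
    if len(np.unique(gradient)) < 3:
        raise ValueError("gradient needs >= 3 distinct levels")
    filtered = filter_taxa_by_mean_abundance(table, min_mean_rel)
    if filtered.n_taxa == 0:
        return pd.DataFrame(
            columns=["taxon_id", "r", "p", "p_adj", "rank"]
        ).assign(empty=True)
    rel = relative_abundance(filtered)
    rows = []
    for i, t in enumerate(filtered.taxon_ids):
        if np.ptp(rel[i]) == 0:       # constant taxon: no trend by definition
            r, p = 0.0, 1.0
        else:
            r, p = stats.spearmanr(rel[i], gradient)
            if np.isnan(r):
                r, p = 0.0, 1.0
        rows.append({"taxon_id": t, "r": float(r), "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df.reindex(df["r"].abs().sort_values(ascending=False, kind="mergesort").index)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(top_n).reset_index(drop=True)


# --------------------------------------------------------------------------
# group comparisons with compact letter display
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    omnibus_H: float
    omnibus_p: float
    pairwise: pd.DataFrame          # group_a, group_b, p_raw, p_adj
    letters: dict                   # group -> letter string
    excluded: list = field(default_factory=list)


def _compact_letters(groups, sig_pairs) -> dict:
    """Greedy insert-absorb compact letter display.

    Groups sharing a letter are not significantly different. Deterministic
    given the (sorted) group order.
    """
    groups = sorted(groups, key=str)
    sig = {tuple(sorted(p, key=str)) for p in sig_pairs}
    letter_sets: list[set] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(tuple(sorted((g, h), key=str)) not in sig for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb: drop letter sets fully contained in another
    keep = []
    for i, s in enumerate(letter_sets):
        if not any(i != j and s < t for j, t in enumerate(letter_sets)):
            keep.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for k, s in enumerate(keep):
        for g in sorted(s, key=str):
            out[g] += alphabet[k % len(alphabet)]
    return out


def compare_groups(values, groups, alpha: float = 0.05) -> GroupComparison:
    """Kruskal-Wallis omnibus plus BH-corrected pairwise rank tests.

    Pairwise tests are two-sided Mann-Whitney U; letters are assigned so
    that groups sharing a letter are not significantly different at
    ``alpha`` on the adjusted p-values. Groups with n < 2 are excluded.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in np.unique(groups) if (groups == g).sum() >= 2]
    excluded = [g for g in np.unique(groups) if g not in labels]
    if len(labels) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples")
    arrays = {g: values[groups == g] for g in labels}
    h, p_omni = stats.kruskal(*arrays.values())
    rows = []
    for a, b in combinations(labels, 2):
        try:
            _, p = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
        except ValueError:       # all values identical
            p = 1.0
        rows.append({"group_a": a, "group_b": b, "p_raw": float(p)})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = multipletests(pw["p_raw"], method="fdr_bh")[1]
    sig_pairs = [
        (r.group_a, r.group_b) for r in pw.itertuples() if r.p_adj < alpha
    ]
    letters = _compact_letters(labels, sig_pairs)
    return GroupComparison(float(h), float(p_omni), pw, letters, excluded)


# --------------------------------------------------------------------------
# carbon storage
# --------------------------------------------------------------------------

def pocd_percent_change(ordered_group_means) -> np.ndarray:
    """Percent change of POCD between consecutive ordered groups.

    change_k = 100 * (mean_{k+1} - mean_k) / mean_k.
    """
    means = np.asarray(ordered_group_means, dtype=float)
    if len(means) < 2:
        raise ValueError("need >= 2 ordered groups")
    if (means[:-1] <= 0).any():
        raise ValueError("previous-group POCD mean must be > 0")
    return 100.0 * np.diff(means) / means[:-1]


@dataclass
class StabilityPocdAssociation:
    slope: float
    partial_r: float
    p: float
    n_perm: int
    stratum_levels: list
    merged_strata: list = field(default_factory=list)


def stability_pocd_association(
    profile: StabilityProfile,
    frame: SampleFrame,
    stratum: str = "site",
    n_perm: int = 999,
    seed: int | None = None,
) -> StabilityPocdAssociation:
    """Stratum-adjusted association between community stability and POCD.

    POCD is regressed on stability with one fixed-effect indicator per
    stratum level (site or sub-layer); the reported effect is the stability
    coefficient, its partial correlation derived from the t statistic, and
    p obtained by permuting stability within strata. Singleton strata are
    merged into the nearest level (by stratum mean POCD) with a flag.
    """
    frame = frame.aligned_to(profile.sample_ids)
    y = frame.column("POCD").astype(float)
    s = np.asarray(profile.stability, dtype=float)
    strata = np.asarray(frame.column(stratum)).astype(str)
    merged = []
    labs, counts = np.unique(strata, return_counts=True)
    if (counts == 1).any():
        means = {l: y[strata == l].mean() for l in labs}
        for l in labs[counts == 1]:
            others = [o for o in labs if o != l and (strata == o).sum() > 1]
            tgt = min(others, key=lambda o: abs(means[o] - means[l]))
            strata[strata == l] = tgt
            merged.append((str(l), str(tgt)))
        labs = np.unique(strata)

    def fit(stab):
        dummies = pd.get_dummies(pd.Series(strata), drop_first=True).to_numpy(float)
        xmat = np.column_stack([np.ones_like(stab), stab, dummies])
        coef, _, _, _ = np.linalg.lstsq(xmat, y, rcond=None)
        resid = y - xmat @ coef
        dof = len(y) - xmat.shape[1]
        if dof <= 0:
            raise ValueError("not enough samples for stratum adjustment")
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.pinv(xmat.T @ xmat)
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        t = coef[1] / se if se > 0 else 0.0
        return float(coef[1]), float(t), dof

    slope, t_obs, dof = fit(s)
    partial_r = t_obs / np.sqrt(t_obs ** 2 + dof)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        sp = s.copy()
        for l in labs:
            m = strata == l
            sp[m] = rng.permutation(sp[m])
        _, t_p, _ = fit(sp)
        if abs(t_p) >= abs(t_obs):
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return StabilityPocdAssociation(
        slope=slope, partial_r=float(partial_r), p=float(p),
        n_perm=n_perm, stratum_levels=[str(l) for l in labs],
        merged_strata=merged,
    )
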
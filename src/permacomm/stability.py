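"""Community stability via the average variation degree (AVD) and core taxa.

AVD for a sample is the mean normalised deviation |x - mu| / sigma of its
taxa from their group means; community stability = 1 - standardised AVD,
standardised min-max over the analysis set so stability lies in [0, 1].
Core taxa are the top 5% of species by mean relative abundance that occur
in more than 70% of samples (the occupancy rule is strict).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CommunityTable
from .preprocess import relative_abundance


@dataclass
class CoreTaxaSet:
    taxon_ids: list
    top_fraction: float
    min_occupancy: float
    mean_rel_abundance: pd.Series
    occupancy: pd.Series

    def __len__(self):
        return len(self.taxon_ids)

    def __contains__(self, t):
        return t in set(self.taxon_ids)


def identify_core_taxa(
    table: CommunityTable,
    top_fraction: float = 0.05,
    min_occupancy: float = 0.70,
) -> CoreTaxaSet:
    """Core taxa: abundance-rank AND occupancy criteria, both required.

    A taxon is core when it ranks within the top ``top_fraction`` of taxa
    by mean relative abundance (rank cutoff ceil(top_fraction * S),
    deterministic tie-break by taxon id) and occurs in strictly more than
    ``min_occupancy`` of all samples.
    """
    rel = relative_abundance(table)
    mean_rel = pd.Series(rel.mean(axis=1), index=table.taxon_ids)
    occ = pd.Series((table.counts > 0).mean(axis=1), index=table.taxon_ids)
    n_top = math.ceil(top_fraction * table.n_taxa)
    ranked = mean_rel.sort_values(ascending=False, kind="mergesort")
    # tie-break deterministically: equal abundances ordered by taxon id
    order = sorted(
        range(len(ranked)), key=lambda i: (-ranked.iloc[i], str(ranked.index[i]))
    )
    top_ids = [ranked.index[i] for i in order[:n_top]]
    core = [t for t in top_ids if occ[t] > min_occupancy]
    core = [t for t in table.taxon_ids if t in set(core)]  # original order
    if not core:
        warnings.warn("no taxa satisfy both core criteria; empty core set")
    return CoreTaxaSet(core, top_fraction, min_occupancy,
                       mean_rel.loc[core], occ.loc[core])


@dataclass
class StabilityProfile:
    sample_ids: list
    avd: np.ndarray
    stability: np.ndarray
    groups: np.ndarray
    standardization: str = "min-max"
    degenerate: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(self.stability, index=self.sample_ids, name="stability")


def avd_stability(table: CommunityTable, groups) -> StabilityProfile:
    """Average variation degree and 1 - min-max-standardised AVD.

    Per group, each taxon's mean mu_i and sd sigma_i (ddof=1) are taken
    over the group's relative abundances; AVD_s averages |x_is - mu_i| /
    sigma_i over the taxa with sigma_i > 0. Stability is 1 - min-max AVD
    over the full analysis set, so the least variable sample scores 1.
    """
    groups = np.asarray(groups)
    if len(groups) != table.n_samples:
        raise ValueError("groups must align with table samples")
    rel = relative_abundance(table)
    avd = np.zeros(table.n_samples)
    degenerate = False
    for lab in np.unique(groups):
        m = groups == lab
        if m.sum() < 3:
            raise ValueError(f"group {lab!r} has < 3 samples")
        x = rel[:, m]
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        ok = sd > 1e-12          # tolerance: identical proportions can
        # leave O(1e-16) float residue in the standard deviation
        if not ok.any():
            warnings.warn(f"group {lab!r} has identical samples; AVD = 0")
            degenerate = True
            avd[m] = 0.0
            continue
        dev = np.abs(x[ok] - mu[ok, None]) / sd[ok, None]
        avd[m] = dev.mean(axis=0)
    lo, hi = avd.min(), avd.max()
    if hi > lo:
        stability = 1.0 - (avd - lo) / (hi - lo)
    else:
        stability = np.ones_like(avd)
        degenerate = True
    return StabilityProfile(
        list(table.sample_ids), avd, stability, groups, degenerate=degenerate
    )


def stability_drivers(
    profile: StabilityProfile,
    predictors: pd.DataFrame,
    strata=None,
) -> pd.DataFrame:
    """Spearman correlations of stability with candidate drivers.

    ``predictors`` is indexed by sample id (richness, stochasticity, core
    abundance, core interaction, environmental covariates...). One row per
    (stratum, predictor) with Spearman r and BH-adjusted p; constant
    predictors are skipped with a flag.
    """
    stab = profile.as_series()
    predictors = predictors.loc[stab.index]
    strata = (
        np.asarray(strata) if strata is not None
        else np.asarray(["all"] * len(stab))
    )
    rows = []
    for lab in np.unique(strata):
        m = strata == lab
        for col in predictors.columns:
            v = predictors.loc[m, col].to_numpy(dtype=float)
            s = stab.to_numpy()[m]
            if np.std(v) == 0 or np.std(s) == 0:
                rows.append({"stratum": lab, "predictor": col, "r": np.nan,
                             "p": np.nan, "skipped": True})
                continue
            r, p = stats.spearmanr(s, v)
            rows.append({"stratum": lab, "predictor": col, "r": float(r),
                         "p": float(p), "skipped": False})
    df = pd.DataFrame(rows)
    for lab in df["stratum"].unique():
        m = (df["stratum"] == lab) & ~df["skipped"]
        if m.sum() > 0:
            df.loc[m, "p_adj"] = multipletests(df.loc[m, "p"], method="fdr_bh")[1]
    return df
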
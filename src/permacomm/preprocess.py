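"""Depth normalisation and abundance filtering.

Counts are kept as integers throughout; relative abundances are computed
on demand and never persisted. All threshold comparisons in this package
are inclusive (>= / <=) unless the underlying rule is explicitly strict.
"""

from __future__ import annotations

import numpy as np

from .datamodel import CommunityTable, ValidationError


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each column is treated as an urn of its reads; ``depth`` of them are
    drawn without replacement (multivariate hypergeometric), so per-sample
    totals are conserved exactly and the expected per-taxon proportion
    equals the pre-rarefaction proportion.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    sums = table.sample_sums()
    deficient = [s for s, t in zip(table.sample_ids, sums) if t < depth]
    if deficient:
        raise ValueError(
            f"rarefaction depth {depth} exceeds total counts of samples: {deficient}"
        )
    rng = np.random.default_rng(seed)
    out = np.zeros_like(table.counts)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CommunityTable(
        list(table.taxon_ids), list(table.lineages), out, list(table.sample_ids)
    )


def relative_abundance(table_or_counts) -> np.ndarray:
    """Column-normalised proportions (taxa x samples); zeros preserved."""
    counts = (
        table_or_counts.counts
        if isinstance(table_or_counts, CommunityTable)
        else np.asarray(table_or_counts, dtype=float)
    )
    sums = counts.sum(axis=0, dtype=float)
    if (sums <= 0).any():
        raise ValidationError("cannot normalise a sample with zero total count")
    return counts / sums


def filter_taxa_by_mean_abundance(
    table: CommunityTable, min_mean_rel: float = 1e-4
) -> CommunityTable:
    """Keep taxa whose mean relative abundance is >= ``min_mean_rel``.

    The default 1e-4 (0.01%) is the conventional noise floor for
    species-level trend analyses. The comparison is inclusive: a taxon at
    exactly the threshold is retained. Row order is preserved.
    """
    if not (0 <= min_mean_rel < 1):
        raise ValueError("min_mean_rel must be in [0, 1)")
    rel = relative_abundance(table)
    keep = rel.mean(axis=1) >= min_mean_rel
    return table.select_taxa(keep)
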
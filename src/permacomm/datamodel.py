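"""Core domain containers shared by every analysis stage.

A :class:`CommunityTable` is a taxa x samples integer count matrix with
taxonomy lineages; a :class:`SampleFrame` carries per-sample positional and
environmental metadata (site, depth, layer labels, physicochemistry, carbon
density); a :class:`DistanceMatrix` is a symmetric pairwise dissimilarity
over samples. All three validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAIN_LAYERS = ("active", "permafrost")
SUB_LAYERS = ("TAL", "SAL", "FFL", "TPL", "SPL")

#: sub-layers wholly contained in each main layer; FFL straddles the
#: active/permafrost junction and carries an explicit per-sample flag.
SUB_TO_MAIN = {"TAL": "active", "SAL": "active", "TPL": "permafrost", "SPL": "permafrost"}


class ValidationError(ValueError):
    """Raised when a container violates one of its declared invariants."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CommunityTable:
    """Taxa x samples count table with per-taxon taxonomy lineages.

    Parameters
    ----------
    taxon_ids : list of str
        Stable taxon identifiers (rows).
    lineages : list of str
        Rank-labelled lineage string per taxon (``d__...;p__...;...``);
        ``"unclassified"`` is acceptable at any rank.
    counts : ndarray of int, shape (n_taxa, n_samples)
        Non-negative counts.
    sample_ids : list of str
        Unique sample identifiers (columns).
    """

    taxon_ids: list
    lineages: list
    counts: np.ndarray
    sample_ids: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D taxa x samples matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if len(self.taxon_ids) != self.counts.shape[0]:
            raise ValidationError("taxon_ids length does not match counts rows")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValidationError("sample_ids length does not match counts columns")
        if len(self.lineages) != len(self.taxon_ids):
            raise ValidationError("one lineage required per taxon")
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def lineage_rank(self, rank_prefix: str) -> list:
        """Extract one rank (e.g. ``"p__"`` for phylum) from each lineage."""
        out = []
        for lin in self.lineages:
            hit = "unclassified"
            for part in str(lin).split(";"):
                part = part.strip()
                if part.startswith(rank_prefix):
                    hit = part[len(rank_prefix):] or "unclassified"
            out.append(hit)
        return out

    def select_taxa(self, keep: np.ndarray) -> "CommunityTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CommunityTable(
            taxon_ids=[self.taxon_ids[i] for i in idx],
            lineages=[self.lineages[i] for i in idx],
            counts=self.counts[idx, :],
            sample_ids=list(self.sample_ids),
        )

    def select_samples(self, sample_ids) -> "CommunityTable":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return CommunityTable(
            taxon_ids=list(self.taxon_ids),
            lineages=list(self.lineages),
            counts=self.counts[:, idx],
            sample_ids=list(sample_ids),
        )

    def drop_zero_taxa(self) -> tuple["CommunityTable", list]:
        """Remove all-zero taxa; returns (table, dropped taxon ids)."""
        keep = self.counts.sum(axis=1) > 0
        dropped = [t for t, k in zip(self.taxon_ids, keep) if not k]
        return self.select_taxa(keep), dropped

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)
        df.index.name = "taxon_id"
        return df


REQUIRED_FRAME_COLUMNS = [
    "sample_id", "site", "depth_m", "main_layer", "sub_layer",
]
ENV_COLUMNS = ["Tp", "PWC", "pH", "Eh", "POM", "TN"]


@dataclass
class SampleFrame:
    """Per-sample metadata: position in the profile plus environment.

    Wraps a :class:`pandas.DataFrame` with one row per sample. Columns
    ``site`` (ordinal degradation rank), ``depth_m``, ``main_layer``
    (active/permafrost), ``sub_layer`` (TAL/SAL/FFL/TPL/SPL) are required;
    environmental covariates (Tp, PWC, pH, Eh, POM, TN), carbon density
    (POCD) and site-level ALT / MAGT are carried when available.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        for col in REQUIRED_FRAME_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"SampleFrame missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if (df["depth_m"] <= 0).any():
            raise ValidationError("depth_m must be > 0")
        bad_main = set(df["main_layer"]) - set(MAIN_LAYERS)
        if bad_main:
            raise ValidationError(f"unknown main_layer labels: {bad_main}")
        bad_sub = set(df["sub_layer"]) - set(SUB_LAYERS)
        if bad_sub:
            raise ValidationError(f"unknown sub_layer labels: {bad_sub}")
        for sub, main in SUB_TO_MAIN.items():
            mask = df["sub_layer"] == sub
            if (df.loc[mask, "main_layer"] != main).any():
                raise ValidationError(
                    f"sub_layer {sub} must lie within main_layer {main}"
                )
        for _, grp in df.groupby("site"):
            d = grp.sort_index()["depth_m"].to_numpy()
            if not np.all(np.diff(d) > 0):
                raise ValidationError("depth_m must strictly increase within a site")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    def aligned_to(self, sample_ids) -> "SampleFrame":
        """Reorder rows to match a table's sample order."""
        df = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleFrame(df)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity with a zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValidationError("ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal must be zero")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v
        _check_unique(self.ids, "sample")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, ids) -> "DistanceMatrix":
        pos = {s: j for j, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])
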
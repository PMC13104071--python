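"""TSV readers/writers for community tables and sample metadata.

The on-disk community format is a plain TSV: first column ``taxon_id``, an
optional ``lineage`` column, then one column per sample. Metadata is a TSV
keyed by ``sample_id``. Both round-trip losslessly for counts and ids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CommunityTable, SampleFrame, ValidationError


class ParseError(ValueError):
    pass


def read_community_table(path, fmt: str = "tsv", drop_zero: bool = True):
    """Read a taxa x samples count table.

    Parameters
    ----------
    path : path-like
        TSV file with ``taxon_id`` first column, optional ``lineage``
        column, then one integer column per sample.
    fmt : {"tsv"}
        Only TSV is supported.
    drop_zero : bool
        Drop all-zero taxa after reading (reported in the second return).

    Returns
    -------
    table : CommunityTable
    dropped : list of str
        Taxon ids removed because they had zero total count.
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported community table format: {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = _raw_header(path)
    if len(cols) < 2:
        raise ParseError("community table needs a taxon_id column and >=1 sample")
    sample_cols = [c for c in cols[1:] if c != "lineage"]
    if len(set(sample_cols)) != len(sample_cols):
        dup = next(c for c in sample_cols if sample_cols.count(c) > 1)
        raise ValidationError(f"duplicate sample id: {dup!r}")
    df = pd.read_csv(path, sep="\t", dtype={cols[0]: str})
    taxon_ids = df[cols[0]].astype(str).tolist()
    lineages = (
        df["lineage"].astype(str).tolist()
        if "lineage" in df.columns
        else ["unclassified"] * len(taxon_ids)
    )
    raw = df[sample_cols]
    try:
        counts = raw.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-numeric counts in {path}: {exc}") from exc
    if np.isnan(counts).any():
        raise ParseError(f"missing values in counts of {path}")
    if (counts < 0).any():
        raise ParseError(f"negative counts in {path}")
    if not np.allclose(counts, np.round(counts)):
        raise ParseError(f"non-integer counts in {path}")
    table = CommunityTable(taxon_ids, lineages, counts.astype(np.int64), sample_cols)
    dropped: list = []
    if drop_zero:
        table, dropped = table.drop_zero_taxa()
    return table, dropped


def write_community_table(table: CommunityTable, path) -> None:
    df = table.to_dataframe().reset_index()
    df.insert(1, "lineage", table.lineages)
    df.to_csv(path, sep="\t", index=False)


def read_sample_frame(path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t")
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path) -> None:
    frame.data.to_csv(path, sep="\t", index=False)


# Pandas duplicates get mangled by read_csv; detect them on the raw header
# line instead so the error names the offending sample id.
def _raw_header(path) -> list:
    with open(path, "r", encoding="utf-8") as fh:
        return fh.readline().rstrip("\n").split("\t")


def validate_header_unique(path) -> None:
    cols = _raw_header(path)
    seen = set()
    for c in cols:
        if c in seen:
            raise ValidationError(f"duplicate sample id: {c!r}")
        seen.add(c)
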
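"""Readers for count tables and sample metadata.

Counts are sample-by-OTU TSV (header row = OTU IDs, first column = sample
IDs) or BIOM v1 JSON; metadata is TSV with a sample-ID first column, one
outcome column and optional covariate columns.
"""

from __future__ import annotations

import json
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["read_counts", "read_counts_biom", "read_metadata", "align_samples"]


def read_counts(path) -> pd.DataFrame:
    """Read a sample-by-OTU count TSV (rows = samples, columns = OTUs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"count table {path} has no OTU columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_counts_biom(path) -> pd.DataFrame:
    """Read a BIOM v1 (JSON) OTU table into sample-by-OTU orientation.

    Supports both dense and sparse matrix encodings.  BIOM stores
    observations (OTUs) as rows; the result is transposed to match the
    TSV convention used everywhere else.
    """
    with open(path) as fh:
        doc = json.load(fh)
    otus = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    return pd.DataFrame(mat.T, index=samples, columns=otus)


def read_metadata(
    path,
    outcome: str,
    covariates: Optional[Sequence[str]] = None,
    outcome_type: str = "binary",
    reference_level: Optional[str] = None,
) -> pd.DataFrame:
    """Read the metadata TSV and encode the outcome.

    Binary outcomes may be coded {0,1} or as two string levels, in which
    case ``reference_level`` names the level mapped to 0.
    """
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if outcome not in meta.columns:
        raise ValueError(f"outcome column {outcome!r} not in metadata")
    for c in covariates or []:
        if c not in meta.columns:
            raise ValueError(f"covariate column {c!r} not in metadata")
    cols = [outcome] + list(covariates or [])
    meta = meta[cols].copy()
    y = meta[outcome]
    if outcome_type == "binary" and not np.issubdtype(y.dtype, np.number):
        levels = sorted(y.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"binary outcome has {len(levels)} levels: {levels}")
        if reference_level is None:
            raise ValueError(
                f"string-coded binary outcome {levels}; pass reference_level"
            )
        if reference_level not in levels:
            raise ValueError(f"reference level {reference_level!r} not among {levels}")
        meta[outcome] = (y != reference_level).astype(float)
    return meta


def align_samples(counts: pd.DataFrame, meta: pd.DataFrame,
                  outcome: str, covariates: Optional[Sequence[str]] = None
                  ) -> Tuple[np.ndarray, Optional[np.ndarray], pd.DataFrame]:
    """Align metadata to count-table sample order; return (Y, Z, counts)."""
    missing = [s for s in counts.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:10]}")
    meta = meta.loc[counts.index]
    if meta[[outcome] + list(covariates or [])].isna().any().any():
        bad = meta.index[meta.isna().any(axis=1)].tolist()
        raise ValueError(f"missing outcome/covariate values for samples: {bad[:10]}")
    Y = meta[outcome].to_numpy(dtype=float)
    Z = meta[list(covariates)].to_numpy(dtype=float) if covariates else None
    return Y, Z, counts
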
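"""Bias-corrected Chao1 phylotype richness on OTU abundance tables.

The estimator extrapolates unseen richness from the counts of singleton
(F1) and doubleton (F2) OTUs:

    S_Chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1))

The bias-corrected form is used always; it stays defined when no
doubletons are observed.  No variance or confidence interval is
computed.  OTU clustering, denoising and chimera checks are out of
scope: this module consumes finished abundance tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class RichnessEstimate:
    """Observed and estimated richness for one sample."""

    s_obs: int
    f1: int
    f2: int
    s_chao1: float


def _validated_counts(counts: Iterable) -> np.ndarray:
    arr = np.asarray(list(counts))
    if arr.size == 0:
        return arr.astype(np.int64)
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            # integral floats arise from pandas I/O; anything else is a bug
            arr = arr.astype(np.int64)
        else:
            raise ValidationError("OTU counts must be non-negative integers")
    if (arr < 0).any():
        raise ValidationError("OTU counts must be non-negative integers")
    return arr.astype(np.int64)


def chao1(counts: Mapping[str, int] | Iterable[int]) -> RichnessEstimate:
    """Bias-corrected Chao1 estimate from one sample's OTU counts.

    ``counts`` maps OTU id to abundance (or is a plain sequence of
    abundances); zeros do not contribute to the observed richness.  An
    empty sample yields ``s_obs = s_chao1 = 0``.
    """
    if isinstance(counts, Mapping):
        counts = counts.values()
    arr = _validated_counts(counts)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    s_chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return RichnessEstimate(s_obs=s_obs, f1=f1, f2=f2, s_chao1=s_chao1)


def richness_by_sample(table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`chao1` independently to every sample of an OTU table.

    ``table`` has OTUs as rows and samples as columns (the matrix layout
    written by most clustering pipelines).  Sample order is preserved;
    duplicate sample identifiers are rejected.  Returns one row per
    sample with ``sample, s_obs, f1, f2, s_chao1``.
    """
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample identifier(s): {dupes}")
    rows = []
    for sample in table.columns:
        est = chao1(table[sample].to_numpy())
        rows.append(
            {
                "sample": sample,
                "s_obs": est.s_obs,
                "f1": est.f1,
                "f2": est.f2,
                "s_chao1": est.s_chao1,
            }
        )
    return pd.DataFrame(rows)


def read_otu_table(path) -> pd.DataFrame:
    """Read an OTU table from TSV matrix or long-format CSV.

    Matrix layout: rows = OTUs (first column holds the OTU id), columns =
    samples, tab-delimited.  Long layout: CSV with columns
    ``sample, otu, count``.  Either way the result is an OTU × sample
    matrix of integer counts.
    """
    path = str(path)
    if path.endswith(".tsv"):
        return pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df = pd.read_csv(path, comment="#")
    if {"sample", "otu", "count"} <= set(df.columns):
        return (
            df.pivot_table(index="otu", columns="sample", values="count",
                           aggfunc="sum", fill_value=0)
            .rename_axis(columns=None)
        )
    return df.set_index(df.columns[0])
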
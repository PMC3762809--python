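"""Stage-binding helpers: joins and table builders between modules.

These functions connect the pool partition, pigment metrics and
correlation screen into one flow; the CLI is a thin wrapper around them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import DEFAULT_FUCO_THRESHOLD, RateParams, ammonification_envelope
from .partition import areal_contents

SLICE_KEY = ["core_id", "month", "top_cm", "bottom_cm"]


def join_pigments(pools: pd.DataFrame, pigments: pd.DataFrame) -> pd.DataFrame:
    """Inner-join pool and pigment tables on the slice key."""
    joined = pools.merge(pigments, on=SLICE_KEY, how="inner")
    if joined.empty and not pools.empty:
        raise ValidationError("pool and pigment tables share no slices")
    return joined


def slice_metrics(
    pools: pd.DataFrame,
    pigments: pd.DataFrame,
    threshold: float = DEFAULT_FUCO_THRESHOLD,
) -> pd.DataFrame:
    """Per-slice pigment ratios and the thresholded ICNO3/Fuco field."""
    df = join_pigments(pools, pigments)
    fu = df["fucoxanthin_umol_dm3"].to_numpy(dtype=float)
    ch = df["chlorophyll_a_umol_dm3"].to_numpy(dtype=float)
    ic = df["icno3_sed"].to_numpy(dtype=float)
    if (fu < 0).any() or (ch < 0).any() or (ic < 0).any():
        raise ValidationError("negative concentration in metrics input")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["fuco_chl"] = np.where(ch > 0, fu / ch, np.nan)
        df["icno3_fuco"] = np.where(fu > threshold, ic / fu, np.nan)
    return df


def areal_table(
    pools: pd.DataFrame,
    pigments: pd.DataFrame,
    max_depth: float | None = None,
    *,
    allow_gaps: bool = False,
) -> pd.DataFrame:
    """Wide per-core areal contents of the pools and pigments (µmol m⁻²)."""
    joined = join_pigments(pools, pigments)
    long = areal_contents(
        joined,
        variables=(
            "pwno3_sed",
            "icno3_sed",
            "fucoxanthin_umol_dm3",
            "chlorophyll_a_umol_dm3",
        ),
        max_depth=max_depth,
        allow_gaps=allow_gaps,
    )
    wide = long.pivot_table(
        index=["core_id", "month"], columns="variable", values="areal_umol_m2"
    ).reset_index()
    wide.columns.name = None
    return wide.rename(
        columns={
            "pwno3_sed": "pwno3_areal",
            "icno3_sed": "icno3_areal",
            "fucoxanthin_umol_dm3": "fucoxanthin_areal",
            "chlorophyll_a_umol_dm3": "chlorophyll_a_areal",
        }
    )


def build_seasonal_table(
    areal: pd.DataFrame, environment: pd.DataFrame
) -> pd.DataFrame:
    """Attach temperature and overlying-water nitrate to the areal table.

    ``environment`` carries one row per core or per month with columns
    ``month, temperature, owno3`` (and optionally ``core_id``).
    """
    keys = ["core_id", "month"] if "core_id" in environment.columns else ["month"]
    env = environment.drop_duplicates(subset=keys)
    out = areal.merge(env[keys + ["temperature", "owno3"]], on=keys, how="left")
    if out[["temperature", "owno3"]].isna().any().any():
        raise ValidationError("environment table does not cover all cores")
    return out


def envelope_by_month(
    areal: pd.DataFrame, rates: RateParams
) -> pd.DataFrame:
    """Areal ammonification envelope per month from mean areal fucoxanthin."""
    monthly = areal.groupby("month", as_index=False)["fucoxanthin_areal"].mean()
    lows, highs = [], []
    for f in monthly["fucoxanthin_areal"]:
        lo, hi = ammonification_envelope(float(f), rates)
        lows.append(lo)
        highs.append(hi)
    monthly["nh4_low_umol_m2_h"] = lows
    monthly["nh4_high_umol_m2_h"] = highs
    return monthly
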
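"""Diatom-specific derived quantities.

Fucoxanthin is the diagnostic carotenoid of diatoms, so the molar
fucoxanthin/chlorophyll-a ratio tracks diatom dominance of the
microphytobenthos, and the ICNO3/fucoxanthin ratio is a proxy for
diatom-specific intracellular nitrate storage.  The latter explodes at
low pigment concentrations and is therefore only defined above a
fucoxanthin threshold (default 1.5 µmol dm⁻³, strict).

Undefined ratios are represented by NaN — a dedicated missing marker
distinct from zero — and excluded from all downstream means; summaries
report the number of defined values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Fucoxanthin concentration (µmol dm⁻³) below or at which ICNO3/Fuco is
#: left undefined.
DEFAULT_FUCO_THRESHOLD = 1.5

#: Small/large benthic diatom biovolumes (pL) used for cell-volume-specific
#: nitrate concentrations.
DEFAULT_BIOVOLUMES = (0.1, 0.5)


@dataclass(frozen=True)
class CellNitrate:
    """Per-cell nitrate amount and the cell-volume-specific concentration.

    ``per_cell_amount`` in fmol cell⁻¹, ``biovolume`` in pL; dividing the
    two gives ``cell_conc`` in mmol per litre of cell volume
    (fmol pL⁻¹ ≡ mmol L⁻¹).
    """

    per_cell_amount: float
    biovolume: float
    cell_conc: float


@dataclass(frozen=True)
class RateParams:
    """Parameters of the areal nitrate-ammonification envelope.

    ``fuco_per_cell`` converts areal fucoxanthin to areal cell numbers
    (fmol fucoxanthin per cell); ``cell_rate_low``/``cell_rate_high``
    bracket the per-cell ammonium production rate (fmol NH4+ cell⁻¹ h⁻¹).
    """

    fuco_per_cell: float
    cell_rate_low: float
    cell_rate_high: float

    def __post_init__(self) -> None:
        if min(self.fuco_per_cell, self.cell_rate_low, self.cell_rate_high) <= 0:
            raise ValidationError("rate parameters must all be positive")
        if self.cell_rate_low > self.cell_rate_high:
            raise ValidationError("cell_rate_low must not exceed cell_rate_high")


def fuco_chl_ratio(fucoxanthin: float, chlorophyll_a: float) -> float:
    """Molar fucoxanthin-to-chlorophyll-a ratio; NaN when chl a is zero."""
    if fucoxanthin < 0 or chlorophyll_a < 0:
        raise ValidationError("pigment concentrations must be non-negative")
    if chlorophyll_a == 0:
        return math.nan
    return fucoxanthin / chlorophyll_a


def icno3_fuco_ratio(
    icno3: float,
    fucoxanthin: float,
    threshold: float = DEFAULT_FUCO_THRESHOLD,
) -> float:
    """Molar ICNO3/fucoxanthin ratio, defined only for fucoxanthin
    strictly above ``threshold``; NaN otherwise."""
    if icno3 < 0 or fucoxanthin < 0:
        raise ValidationError("concentrations must be non-negative")
    if not fucoxanthin > threshold:
        return math.nan
    return icno3 / fucoxanthin


def cell_specific_icno3(
    icno3: float, cell_density: float, biovolume: float
) -> CellNitrate:
    """Cell-volume-specific intracellular nitrate concentration.

    ``icno3`` in µmol per dm³ of mat, ``cell_density`` in cells per dm³,
    ``biovolume`` in pL.  The per-cell amount is
    ``icno3 / cell_density × 10⁹`` fmol (µmol→fmol), and dividing by the
    biovolume gives mmol per litre of cell volume.
    """
    if icno3 < 0:
        raise ValidationError("icno3 must be non-negative")
    if biovolume <= 0:
        raise ValidationError("biovolume must be positive")
    if cell_density <= 0:
        return CellNitrate(math.nan, biovolume, math.nan)
    per_cell = icno3 / cell_density * 1e9
    return CellNitrate(per_cell, biovolume, per_cell / biovolume)


def mat_fuco_per_cell(fucoxanthin: float, cell_density: float) -> float:
    """Fucoxanthin-to-cell conversion factor (fmol cell⁻¹) from a mat
    sample with counted cells."""
    if fucoxanthin < 0 or cell_density <= 0:
        raise ValidationError("need fucoxanthin >= 0 and cell_density > 0")
    return fucoxanthin / cell_density * 1e9


def ammonification_envelope(
    fuco_areal: float, p: RateParams
) -> tuple[float, float]:
    """Areal nitrate-ammonification envelope from areal fucoxanthin.

    Converts the depth-integrated fucoxanthin content (µmol m⁻²) to an
    areal diatom abundance with the fucoxanthin-per-cell factor, then
    multiplies by the low/high per-cell ammonium production rates.
    Returns (low, high) in µmol NH4+ m⁻² h⁻¹.
    """
    if fuco_areal < 0:
        raise ValidationError("areal fucoxanthin must be non-negative")
    cells_areal = fuco_areal / p.fuco_per_cell * 1e9  # µmol→fmol
    low = cells_areal * p.cell_rate_low * 1e-9  # fmol→µmol
    high = cells_areal * p.cell_rate_high * 1e-9
    return low, high


def mean_of_ratios(num: np.ndarray | pd.Series, den: np.ndarray | pd.Series) -> float:
    """Mean of element-wise ratios over replicates (NaN-aware)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return float(np.nanmean(r)) if np.isfinite(r).any() else math.nan


def ratio_of_means(num: np.ndarray | pd.Series, den: np.ndarray | pd.Series) -> float:
    """Ratio of replicate means (NaN-aware)."""
    d = float(np.nanmean(np.asarray(den, dtype=float)))
    if not d > 0:
        return math.nan
    return float(np.nanmean(np.asarray(num, dtype=float))) / d


def mat_summary(
    mat: pd.DataFrame,
    biovolumes: tuple[float, ...] = DEFAULT_BIOVOLUMES,
    threshold: float = DEFAULT_FUCO_THRESHOLD,
) -> pd.DataFrame:
    """Summarize a diatom-mat table into the derived metrics.

    ``mat`` carries one row per replicate with columns ``icno3_umol_dm3,
    fucoxanthin_umol_dm3, chlorophyll_a_umol_dm3, cells_dm3``.  Both ratio
    conventions (ratio of replicate means and mean of replicate ratios)
    are reported, plus one cell-volume-specific nitrate row per
    biovolume.  Returns a long frame with ``metric, convention, value, n``.
    """
    ic = mat["icno3_umol_dm3"].to_numpy(dtype=float)
    fu = mat["fucoxanthin_umol_dm3"].to_numpy(dtype=float)
    ch = mat["chlorophyll_a_umol_dm3"].to_numpy(dtype=float)
    cells = mat["cells_dm3"].to_numpy(dtype=float)

    fu_thresh = np.where(fu > threshold, fu, np.nan)
    rows = [
        ("fuco_chl_ratio", "ratio_of_means", ratio_of_means(fu, ch), len(mat)),
        ("fuco_chl_ratio", "mean_of_ratios", mean_of_ratios(fu, ch), len(mat)),
        ("icno3_fuco_ratio", "ratio_of_means", ratio_of_means(ic, fu_thresh),
         int(np.isfinite(fu_thresh).sum())),
        ("icno3_fuco_ratio", "mean_of_ratios", mean_of_ratios(ic, fu_thresh),
         int(np.isfinite(fu_thresh).sum())),
        ("fuco_per_cell_fmol", "ratio_of_means",
         mat_fuco_per_cell(float(np.nanmean(fu)), float(np.nanmean(cells))), len(mat)),
        ("fuco_per_cell_fmol", "mean_of_ratios",
         float(np.nanmean([mat_fuco_per_cell(f, c) for f, c in zip(fu, cells)])),
         len(mat)),
    ]
    for bv in biovolumes:
        cn_rom = cell_specific_icno3(
            float(np.nanmean(ic)), float(np.nanmean(cells)), bv
        )
        rows.append(
            (f"cell_conc_{bv}pL_mmolL", "ratio_of_means", cn_rom.cell_conc, len(mat))
        )
        per_rep = [
            cell_specific_icno3(i, c, bv).cell_conc for i, c in zip(ic, cells)
        ]
        rows.append(
            (f"cell_conc_{bv}pL_mmolL", "mean_of_ratios",
             float(np.nanmean(per_rep)), len(mat))
        )
    return pd.DataFrame(rows, columns=["metric", "convention", "value", "n"])


def default_rate_params(
    mat_fucoxanthin: float = 27.8,
    mat_cells: float = 1.40e10,
    cell_rate_low: float = 0.1,
    cell_rate_high: float = 2.0,
) -> RateParams:
    """RateParams with the mat-derived fucoxanthin-to-cell factor.

    The conversion factor defaults to the mat sample's ratio of mean
    fucoxanthin to mean cell density (~1.99 fmol cell⁻¹); the per-cell
    ammonium rates are user-supplied bounds with placeholder defaults and
    should be set to the rate span of the diatom culture of interest.
    """
    return RateParams(
        fuco_per_cell=mat_fuco_per_cell(mat_fucoxanthin, mat_cells),
        cell_rate_low=cell_rate_low,
        cell_rate_high=cell_rate_high,
    )
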
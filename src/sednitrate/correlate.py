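"""Spearman rank correlation screen with permutation significance.

Reproduces the structure of a seasonal correlation table: all unordered
pairs among the depth-integrated monthly variables (temperature,
overlying-water nitrate, areal PWNO3/ICNO3, areal pigments), Spearman's
rho with ties receiving average ranks, and two-sided significance flags
at 0.05 and 0.01.

Significance uses a permutation test (exact enumeration for n <= 7,
seeded Monte-Carlo otherwise) rather than the large-sample t
approximation, which is questionable at n = 36 with ties.  A
Holm-adjusted p column is emitted alongside the per-pair flags for
transparency; no correction is applied to the flags themselves.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

#: Default variable set of the seasonal screen, in table order.
SEASONAL_VARIABLES = (
    "temperature",
    "owno3",
    "pwno3_areal",
    "icno3_areal",
    "fucoxanthin_areal",
    "chlorophyll_a_areal",
)

#: Sample sizes up to which the permutation null is enumerated exactly.
EXACT_ENUMERATION_MAX_N = 7


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return math.nan
    return float(rx @ ry) / denom


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of average-ranked values.

    Returns NaN (the undefined marker) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d sequences of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    return _rho_of_ranks(rankdata(x), rankdata(y))


def permutation_p(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 9999,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p-value for Spearman's rho.

    For n <= 7 the full permutation null is enumerated and the p-value is
    the exact fraction of permutations with |rho*| >= |rho|.  For larger
    n, ``n_perm`` seeded random permutations are drawn and the p-value is
    (1 + #{|rho*| >= |rho|}) / (1 + n_perm), which never reports zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = spearman_rho(x, y)
    if math.isnan(rho):
        return math.nan
    rx, ry = rankdata(x), rankdata(y)
    target = abs(rho) - 1e-12  # guard against float ties in |rho*| == |rho|
    if x.size <= EXACT_ENUMERATION_MAX_N:
        hits = total = 0
        for perm in itertools.permutations(range(x.size)):
            r = _rho_of_ranks(rx, ry[list(perm)])
            total += 1
            if abs(r) >= target:
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = _rho_of_ranks(rx, rng.permutation(ry))
        if abs(r) >= target:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def correlation_matrix(
    table: pd.DataFrame,
    variables: Sequence[str] = SEASONAL_VARIABLES,
    n_perm: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Correlation screen over all unordered variable pairs.

    ``table`` has one row per core (month × replicate) and one column per
    variable; rows with a missing value in either member of a pair are
    dropped for that pair.  Returns a long frame with ``var1, var2, rho,
    p, p_holm, n, sig05, sig01``.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValidationError(f"missing variable column(s): {missing}")
    rows = []
    for var1, var2 in itertools.combinations(variables, 2):
        sub = table[[var1, var2]].dropna()
        if len(sub) < 3:
            raise ValidationError(
                f"fewer than 3 complete observations for ({var1}, {var2})"
            )
        x = sub[var1].to_numpy()
        y = sub[var2].to_numpy()
        rho = spearman_rho(x, y)
        p = permutation_p(x, y, n_perm=n_perm, seed=seed) if not math.isnan(rho) else math.nan
        rows.append({"var1": var1, "var2": var2, "rho": rho, "p": p, "n": len(sub)})
    out = pd.DataFrame(rows)
    finite = out["p"].notna()
    holm = np.full(len(out), np.nan)
    if finite.any():
        holm[finite.to_numpy()] = multipletests(
            out.loc[finite, "p"].to_numpy(), method="holm"
        )[1]
    out["p_holm"] = holm
    out["sig05"] = out["p"] < 0.05
    out["sig01"] = out["p"] < 0.01
    return out


def to_square(long: pd.DataFrame, variables: Sequence[str] = SEASONAL_VARIABLES) -> pd.DataFrame:
    """Pivot the long correlation frame into a symmetric rho matrix with a
    unit diagonal, mirroring the printed table layout."""
    mat = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    for _, r in long.iterrows():
        mat.loc[r["var1"], r["var2"]] = r["rho"]
        mat.loc[r["var2"], r["var1"]] = r["rho"]
    return mat
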
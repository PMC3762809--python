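"""Seasonal synthetic sediment-core generator and forward measurement model.

The generator emulates a year of monthly coring on a temperate intertidal
flat: temperature and overlying-water nitrate (OWNO3) follow anti-phase
seasonal sinusoids (riverine nitrate loads peak in winter when primary
production is low); porewater nitrate (PWNO3) at the sediment surface
tracks OWNO3 and decays exponentially with depth; intracellular nitrate
(ICNO3) is held by diatom cells whose internal concentration sits in
equilibrium with the local porewater at a configurable enrichment factor
(10²–10³); fucoxanthin follows its own seasonal + exponential depth
profile with chlorophyll a tied to it through a depth-linear Fuco/Chl a
ratio.

The forward measurement model inverts the pool-partition mass balance:
given true sediment-basis pools and slice geometry it produces the two
extract concentrations that the extraction protocol would measure, so
``partition_slice(forward_measurement(s))`` is the identity at zero
noise.  Replicate-to-replicate variability and measurement error are
both multiplicative lognormal (concentrations are positive and replicate
scatter scales with the mean), with unit mean so expectations are
preserved.

One integer seed governs all sampling; per-stage generators are spawned
deterministically from it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .partition import (
    DEFAULT_ADDED_ML,
    DEFAULT_REMOVED_ML,
    DEFAULT_SLICE_VOLUME_CM3,
    partition_table,
)

#: Quartz grain density (g cm⁻³) used to give synthetic slices realistic
#: dry masses from porosity.
GRAIN_DENSITY_G_CM3 = 2.65


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of the seasonal-depth generator.

    Defaults are calibrated to the observed ranges of a temperate
    intertidal flat: OWNO3 spanning ~5–75 µmol L⁻¹ over the year, surface
    PWNO3 up to ~30 µmol dm⁻³, surface ICNO3 up to ~22 µmol dm⁻³,
    surface fucoxanthin up to ~9 µmol dm⁻³, and Fuco/Chl a falling
    linearly from 0.8 at the surface to 0.2 at 10 cm.
    """

    months: int = 12
    replicates: int = 3
    slices: int = 10  # 1-cm slices

    # seasonal drivers; month_peak is the warmest month (cosine peak)
    temp_mean: float = 10.0  # °C
    temp_amp: float = 8.0
    month_peak: float = 8.0
    owno3_base: float = 40.0  # µmol L⁻¹, anti-phase with temperature
    owno3_amp: float = 35.0

    # porewater nitrate profile
    pw_surface_factor: float = 0.4  # surface PWNO3 (µmol dm⁻³) per unit OWNO3
    pw_decay_length: float = 2.0  # cm

    # pigment profiles
    fuco_surface: float = 6.0  # µmol dm⁻³ annual-mean surface fucoxanthin
    fuco_seasonal_amp: float = 0.5  # relative seasonal modulation
    fuco_decay_length: float = 3.0  # cm
    fuco_chl_surface: float = 0.8  # Fuco/Chl a ratio endpoints
    fuco_chl_deep: float = 0.2  # at depth ratio_depth_cm
    ratio_depth_cm: float = 10.0

    # diatom nitrate storage
    enrichment: float = 500.0  # cell-internal / porewater concentration
    cell_density_surface: float = 1.2e9  # cells dm⁻³
    cell_density_decay_length: float = 10.0  # cm
    biovolume: float = 0.5  # pL

    # sediment physics and noise
    porosity: float = 0.4  # porewater volume fraction
    noise_cv: float = 0.05  # relative lognormal noise, replicates & measurement
    seed: int = 0

    # extraction protocol geometry
    added_volume: float = DEFAULT_ADDED_ML
    removed_volume: float = DEFAULT_REMOVED_ML
    sediment_volume: float = DEFAULT_SLICE_VOLUME_CM3

    def validate(self) -> None:
        if min(self.months, self.replicates, self.slices) < 1:
            raise ValidationError("months, replicates and slices must be >= 1")
        if not (0 < self.porosity < 1):
            raise ValidationError(f"porosity {self.porosity} outside (0, 1)")
        for name in ("temp_amp", "owno3_base", "owno3_amp", "pw_surface_factor",
                     "fuco_surface", "enrichment", "cell_density_surface",
                     "noise_cv", "fuco_seasonal_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("pw_decay_length", "fuco_decay_length",
                     "cell_density_decay_length", "biovolume", "ratio_depth_cm",
                     "sediment_volume", "added_volume"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.fuco_chl_deep < self.fuco_chl_surface):
            raise ValidationError(
                "need 0 < fuco_chl_deep < fuco_chl_surface"
            )
        if self.fuco_seasonal_amp > 1:
            raise ValidationError("fuco_seasonal_amp > 1 gives negative pigments")

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)

    # -- deterministic building blocks -------------------------------------

    def seasonal_phase(self, month: np.ndarray | float) -> np.ndarray:
        return np.cos(2 * np.pi * (np.asarray(month, dtype=float) - self.month_peak) / 12.0)

    def temperature(self, month) -> np.ndarray:
        return self.temp_mean + self.temp_amp * self.seasonal_phase(month)

    def owno3(self, month) -> np.ndarray:
        return np.maximum(self.owno3_base - self.owno3_amp * self.seasonal_phase(month), 0.0)

    def pwno3_sed(self, depth_cm, month) -> np.ndarray:
        return (
            self.pw_surface_factor
            * self.owno3(month)
            * np.exp(-np.asarray(depth_cm, dtype=float) / self.pw_decay_length)
        )

    def cell_density(self, depth_cm) -> np.ndarray:
        return self.cell_density_surface * np.exp(
            -np.asarray(depth_cm, dtype=float) / self.cell_density_decay_length
        )

    def icno3_sed(self, depth_cm, month) -> np.ndarray:
        # cell-internal concentration in equilibrium with porewater
        # (enrichment × porewater-basis concentration), converted to a
        # sediment-volume pool via the cellular volume fraction
        pw_conc = self.pwno3_sed(depth_cm, month) / self.porosity  # µmol L⁻¹
        cell_internal = self.enrichment * pw_conc  # µmol per L cell volume
        volume_fraction = self.cell_density(depth_cm) * self.biovolume * 1e-12
        return cell_internal * volume_fraction

    def fucoxanthin(self, depth_cm, month) -> np.ndarray:
        seasonal = 1.0 - self.fuco_seasonal_amp * self.seasonal_phase(month)
        return (
            self.fuco_surface
            * seasonal
            * np.exp(-np.asarray(depth_cm, dtype=float) / self.fuco_decay_length)
        )

    def fuco_chl(self, depth_cm) -> np.ndarray:
        frac = np.clip(np.asarray(depth_cm, dtype=float) / self.ratio_depth_cm, 0.0, 1.0)
        return self.fuco_chl_surface + (self.fuco_chl_deep - self.fuco_chl_surface) * frac


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and relative s.d. ~cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(2)
    return {
        "replicate": np.random.default_rng(children[0]),
        "measurement": np.random.default_rng(children[1]),
    }


def simulate_truth(p: SimulationParams) -> pd.DataFrame:
    """Latent slice states for every month × replicate × depth slice.

    Depth profiles are evaluated at slice midpoints (homogenized 1-cm
    slices).  Replicate-to-replicate scatter is multiplicative lognormal
    with relative s.d. ``noise_cv`` applied independently to each
    concentration field; ``noise_cv = 0`` returns the deterministic
    expectation.  Fixed seed ⇒ bitwise-identical output.
    """
    p.validate()
    rng = _stage_rngs(p.seed)["replicate"]
    months = np.arange(1, p.months + 1)
    reps = np.arange(1, p.replicates + 1)
    tops = np.arange(p.slices, dtype=float)
    mm, rr, zz = np.meshgrid(months, reps, tops, indexing="ij")
    mm, rr, zz = mm.ravel(), rr.ravel(), zz.ravel()
    mid = zz + 0.5

    pw = p.pwno3_sed(mid, mm)
    ic = p.icno3_sed(mid, mm)
    fu = p.fucoxanthin(mid, mm)
    ch = fu / p.fuco_chl(mid)

    n = mm.size
    pw = pw * _lognormal_factors(rng, p.noise_cv, n)
    ic = ic * _lognormal_factors(rng, p.noise_cv, n)
    fu = fu * _lognormal_factors(rng, p.noise_cv, n)
    ch = ch * _lognormal_factors(rng, p.noise_cv, n)

    return pd.DataFrame(
        {
            "month": mm.astype(int),
            "replicate": rr.astype(int),
            "core_id": [f"M{m:02d}-R{r}" for m, r in zip(mm.astype(int), rr.astype(int))],
            "top_cm": zz,
            "bottom_cm": zz + 1.0,
            "pwno3_sed": pw,
            "icno3_sed": ic,
            "fucoxanthin": fu,
            "chlorophyll_a": ch,
            "temperature": p.temperature(mm),
            "owno3": p.owno3(mm),
        }
    )


def forward_measurement(
    truth: pd.DataFrame,
    p: SimulationParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run the extraction protocol's measurement model over true states.

    Slice geometry follows from porosity: porewater volume
    ``V_pw = porosity × V_sed`` (mL), dry mass from the grain density,
    wet mass = dry mass + porewater mass.  The extract concentrations
    invert the partition mass balance and are perturbed by lognormal
    noise with relative s.d. ``noise_cv`` (0 allowed).  Returns a table
    in the slice-measurement CSV schema.
    """
    p.validate()
    if rng is None:
        rng = _stage_rngs(p.seed)["measurement"]
    v_sed = p.sediment_volume
    v_pw = p.porosity * v_sed  # mL; porewater density 1.0 in synthesis
    v1 = v_pw + p.added_volume
    v2 = v1 - p.removed_volume
    if v2 <= 0:
        raise ValidationError("protocol volumes give non-positive V2")
    dry = (1.0 - p.porosity) * v_sed * GRAIN_DENSITY_G_CM3
    wet = dry + v_pw

    pw = truth["pwno3_sed"].to_numpy(dtype=float)
    ic = truth["icno3_sed"].to_numpy(dtype=float)
    e1 = pw * v_sed / v1
    e2 = e1 + ic * v_sed / v2
    n = len(truth)
    e1 = e1 * _lognormal_factors(rng, p.noise_cv, n)
    e2 = e2 * _lognormal_factors(rng, p.noise_cv, n)

    return pd.DataFrame(
        {
            "core_id": truth["core_id"].to_numpy(),
            "month": truth["month"].to_numpy(),
            "top_cm": truth["top_cm"].to_numpy(),
            "bottom_cm": truth["bottom_cm"].to_numpy(),
            "wet_g": np.full(n, wet),
            "dry_g": np.full(n, dry),
            "added_mL": np.full(n, p.added_volume),
            "removed_mL": np.full(n, p.removed_volume),
            "extract1_umolL": e1,
            "extract2_umolL": e2,
            "sed_vol_cm3": np.full(n, v_sed),
        }
    )


def simulate_dataset(
    p: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (slice measurements, pigment table, latent truth).

    The pigment table carries fucoxanthin and chlorophyll a per slice
    with measurement noise; the measurement table feeds
    :func:`sednitrate.partition.partition_table`.
    """
    p.validate()
    rngs = _stage_rngs(p.seed)
    truth = simulate_truth(p)
    measurements = forward_measurement(truth, p, rng=rngs["measurement"])
    n = len(truth)
    pigments = pd.DataFrame(
        {
            "core_id": truth["core_id"],
            "month": truth["month"],
            "top_cm": truth["top_cm"],
            "bottom_cm": truth["bottom_cm"],
            "fucoxanthin_umol_dm3": truth["fucoxanthin"].to_numpy()
            * _lognormal_factors(rngs["measurement"], p.noise_cv, n),
            "chlorophyll_a_umol_dm3": truth["chlorophyll_a"].to_numpy()
            * _lognormal_factors(rngs["measurement"], p.noise_cv, n),
        }
    )
    return measurements, pigments, truth


# -- parameter-recovery machinery ------------------------------------------


def recovery_standard_errors(
    p: SimulationParams, pw0: np.ndarray, ic0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standard errors of the monthly-mean recovered pools.

    Propagates the two lognormal noise sources (replicate scatter on the
    latent pools, measurement noise on the extract concentrations)
    through the partition mass balance.  The recovered porewater pool is
    ``pw0·t·n1`` (variance ≈ 2 cv² pw0²); the recovered intracellular
    pool is ``(ic + pw·V2/V1)·n2 − (pw·V2/V1)·n1`` whose variance, with
    b = pw0·V2/V1, is ≈ cv²·((ic0 + b)² + b² + ic0²) — the porewater
    cross-term dominates for deep slices where ic0 → 0.  Both variances
    are divided by the replicate count.
    """
    cv = p.noise_cv
    k = (p.porosity * p.sediment_volume + p.added_volume - p.removed_volume) / (
        p.porosity * p.sediment_volume + p.added_volume
    )
    b = pw0 * k
    var_pw = 2.0 * cv * cv * pw0 * pw0
    var_ic = cv * cv * ((ic0 + b) ** 2 + b * b + ic0 * ic0)
    n = p.replicates
    return np.sqrt(var_pw / n), np.sqrt(var_ic / n)


def parameter_recovery_fraction(
    p: SimulationParams, seeds: range | list[int]
) -> float:
    """Fraction of monthly-mean recovered pool values (porewater and
    intracellular counted separately, over every seed × month × slice)
    that fall within 2 propagated standard errors of the noise-free
    truth.

    The signed intracellular value (before clamping) is used so that
    near-zero deep pools are not biased upward by the clamp.
    """
    mid = np.arange(p.slices) + 0.5
    hits = 0
    total = 0
    for seed in seeds:
        ps = p.replace(seed=int(seed))
        measurements, _, _ = simulate_dataset(ps)
        pools = partition_table(measurements)
        pools = pools.merge(
            pd.DataFrame({"top_cm": np.arange(p.slices, dtype=float), "mid": mid}),
            on="top_cm",
        )
        monthly = pools.groupby(["month", "top_cm"], as_index=False).agg(
            pw_hat=("pwno3_sed", "mean"), ic_hat=("icno3_raw", "mean")
        )
        pw0 = ps.pwno3_sed(monthly["top_cm"].to_numpy() + 0.5, monthly["month"].to_numpy())
        ic0 = ps.icno3_sed(monthly["top_cm"].to_numpy() + 0.5, monthly["month"].to_numpy())
        se_pw, se_ic = recovery_standard_errors(ps, pw0, ic0)
        ok_pw = np.abs(monthly["pw_hat"].to_numpy() - pw0) <= 2 * se_pw
        ok_ic = np.abs(monthly["ic_hat"].to_numpy() - ic0) <= 2 * se_ic
        hits += int(ok_pw.sum()) + int(ok_ic.sum())
        total += ok_pw.size + ok_ic.size
    return hits / total
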
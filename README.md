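# sednitrate

Benthic diatoms on intertidal flats store nitrate inside their cells at
concentrations two to three orders of magnitude above the surrounding
porewater. That intracellular pool (ICNO₃) is invisible to conventional
porewater chemistry, yet it can double the sediment's total nitrate
inventory and may fuel anaerobic nitrate respiration (DNRA) in dark,
anoxic layers. `sednitrate` is a reduction pipeline for the sediment-core
measurements that quantify this pool, aimed at sediment biogeochemists
and benthic microbial ecologists.

## What it computes

**Pool partitioning.** Each 1-cm slice is extracted twice: a saline
extraction samples the porewater nitrate diluted by the added volume,
then repeated freeze–thaw lyses cells and releases intracellular nitrate
into the remaining liquid. With porewater volume
*V*<sub>pw</sub> = (*m*<sub>wet</sub> − *m*<sub>dry</sub>)/ρ,
first-extraction volume *V*₁ = *V*<sub>pw</sub> + *V*<sub>added</sub> and
second-extraction volume *V*₂ = *V*₁ − *V*<sub>removed</sub>:

```
PWNO₃ = c₁ · V₁ / V_sed                 [µmol dm⁻³ sediment]
ICNO₃ = max((c₂ − c₁) · V₂ / V_sed, 0)  [µmol dm⁻³ sediment]
```

where c₁, c₂ are the extract nitrate concentrations (µmol L⁻¹) and
V_sed the slice volume (cm³). Areal contents integrate the profile by
the rectangle rule (1 µmol dm⁻³ over 1 cm = 10 µmol m⁻²).

**Diatom metrics.** Molar Fuco/Chl *a* ratios (diatom dominance), the
ICNO₃/fucoxanthin ratio (diatom-specific nitrate storage, defined only
for fucoxanthin > 1.5 µmol dm⁻³), cell-volume-specific ICNO₃ for 0.1 and
0.5 pL cells, and an areal NH₄⁺-production envelope from areal
fucoxanthin via a fucoxanthin-per-cell conversion factor.

**Community statistics.** Bias-corrected Chao1 phylotype richness,
S<sub>Chao1</sub> = S<sub>obs</sub> + F₁(F₁−1)/(2(F₂+1)), and a Spearman
correlation screen over the seasonal depth-integrated variables with
permutation p-values.

**Synthetic cores.** A seasonal generator (12 months × 3 replicate cores
× 10 slices by default) with anti-phase temperature/nitrate sinusoids,
exponential depth decay of both nitrate pools, pigment covariation, a
configurable cellular enrichment factor, and the forward measurement
model of the extraction protocol — so every stage is testable without
field data.

## Worked example

```python
from sednitrate import *
from sednitrate.partition import DepthInterval

m = SliceMeasurement(core_id="c1", month=2, interval=DepthInterval(0, 1),
                     wet_mass=15.0, dry_mass=11.0,
                     extract1_conc=10.0, extract2_conc=20.0,
                     sediment_volume=10.18)
r = partition_slice(m)
print(f"PWNO3  {r.pwno3_sed:.3f} umol dm-3   (porewater basis {r.pw_conc:.1f} umol L-1)")
print(f"ICNO3  {r.icno3_sed:.3f} umol dm-3")

cn = cell_specific_icno3(65.1, 1.40e10, 0.5)   # diatom-mat means
print(f"per cell {cn.per_cell_amount:.2f} fmol -> {cn.cell_conc:.1f} mmol L-1")
print(f"Fuco/Chl a {fuco_chl_ratio(27.8, 16.8):.3f}")
print(f"ICNO3/Fuco {icno3_fuco_ratio(65.1, 27.8):.3f}")
```

prints

```
PWNO3  6.876 umol dm-3   (porewater basis 17.5 umol L-1)
ICNO3  6.385 umol dm-3
per cell 4.65 fmol -> 9.3 mmol L-1
Fuco/Chl a 1.655
ICNO3/Fuco 2.342
```

The slice holds 4 mL of porewater; 10 µmol L⁻¹ measured in 7 mL of
extract back-calculates to 17.5 µmol L⁻¹ in the undiluted porewater and
6.9 µmol per dm³ of bulk sediment. The 10 µmol L⁻¹ excess in the second
extract (6.5 mL after removing 0.5 mL of supernatant) is the cellular
pool. The mat numbers say each diatom held ~4.7 fmol nitrate — a 9.3
mmol L⁻¹ internal concentration for large (0.5 pL) cells — in a mat
whose pigment ratio (1.66) marks near-total diatom dominance.

## Command line

```
sednitrate simulate --seed 1 --out out/          # synthetic dataset
sednitrate pools --slices out/slices.csv --out out/
sednitrate run_all --simulate --seed 1 --out out/  # full pipeline
sednitrate richness --otu otus.tsv --out out/
```

Subcommands: `simulate`, `pools`, `metrics`, `richness`, `correlate`,
`run_all`. All I/O is plain CSV/TSV with a provenance header (tool
version, config hash, seed); identical seed and config give
byte-identical outputs.

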
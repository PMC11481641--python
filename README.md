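# gwquality

Groundwater-quality assessment for municipal monitoring-well networks:
composite quality indices, five-rank classification, pre/post-intervention
statistics, and kriged water-quality surfaces.

Settlements without sewerage discharge domestic wastewater into the shallow
aquifer; once a sewerage network is built, the interesting question is
whether — and where — groundwater quality actually recovers. `gwquality`
implements the standard assessment workflow for long-term well monitoring
of this kind: eight physicochemical parameters per well and year (pH, EC,
NH4+, NO2−, NO3−, PO4 3−, COD, Na+) are collapsed into two indices,
classified, tested for a period effect, and interpolated into maps.

## The two indices

**Weighted-arithmetic water quality index.** With measured value $V_n$,
ideal value $V_i$ (0 for concentrations, 7 for pH) and permissible limit
$V_s$ per parameter:

$$Q_n = 100\,\frac{|V_n - V_i|}{V_s - V_i},\qquad
  W_n = \frac{k}{V_s},\; k = \frac{1}{\sum 1/V_s},\qquad
  \mathrm{WQI} = \frac{\sum Q_n W_n}{\sum W_n}$$

Weights are inversely proportional to the limits, so tight-limit nutrients
(NH4+, NO2−, PO4 3−) dominate. WQI ranks: [0,25] Excellent, (25,50] Good,
(50,75] Poor, (75,100] Very poor, >100 Unsuitable for any use.

**Contamination degree.** A sum of exceedance factors over parameters above
their upper permissible concentration $C_{Ni}$:

$$C_d = \sum_i C_{fi},\qquad C_{fi} = \frac{C_{Ai}}{C_{Ni}} - 1
  \;\;\text{(only when } C_{Ai} > C_{Ni}\text{)}$$

Values at or below the limit contribute nothing. Cd ranks: 0 Excellent,
(0,1) Low, [1,3) Medium, [3,6] High, >6 Very high.

The default standards profile (`hu_6_2009`) carries the Hungarian joint
decree 6/2009 (IV. 14.) limits. Around the indices sit a calibrated
synthetic campaign generator (the raw survey data are not public), a
statistics stage (Spearman, exact/asymptotic Wilcoxon signed-rank, Fisher
two-group discriminant with Wilks' Λ and leave-one-out cross-validation),
and global ordinary kriging with rank-classified raster output. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Run a study-shaped synthetic campaign (40 wells, years 2013 and 2017–2022
with 2020 missing, wells dropping out as they run dry) through the whole
pipeline:

```sh
gwquality run --seed 1 --out bundle
```

```
bundle written to bundle (47 artifacts)
```

The bundle contains `samples.csv` (231 rows), `indices.csv` (both indices,
ranks and per-parameter breakdown per sample), summary and rank tables,
test results, per-year kriged `.asc` rasters with their classified and
variance companions, and a `manifest.json` that records seed, config hash
and artifact list (rerunning with the same seed reproduces every table byte
for byte). A look at the headline statistics:

```sh
$ cat bundle/wilcoxon.csv
index,W,Z,p_value,n_effective,method
wqi,87.0,-4.341...,1.414...e-05,40,normal-approximation
cd,338.0,0.725...,0.468...,39,normal-approximation
```

Each well's mean pre-sewerage WQI is paired with its mean post-sewerage
WQI; Z = −4.34 (p ≈ 1.4e-05) says the post-period index values are
systematically lower — water quality improved after the intervention built
into the generator's per-year calibration. The contamination degree shows
no significant change on this seed: Cd is driven by the parameters that did
*not* improve in the later calibration years (NO3−, EC), a divergence
between the two indices that the rank-agreement table quantifies. The
discriminant stage (`discriminant.json`) separates pre- from post-sewerage
samples from the eight chemical parameters with ~88% leave-one-out accuracy
on this seed.

The same stages are available as library calls:

```python
from gwquality import (barand_like_config, simulate_dataset,
                       MonitoringDataset, compute_indices, default_specs)

samples = simulate_dataset(barand_like_config(seed=1))
result = compute_indices(samples[0], default_specs())
print(round(result.wqi, 1), result.wqs_label, "|",
      round(result.cd, 2), result.cds_label)
# 58.5 Poor | 0 Excellent
```

`gwquality simulate`, `indices`, `stats` and `interpolate` run the
individual stages; `--input wells.csv` switches any of them from synthetic
to measured data in the documented CSV schema
(`well_id,year,x,y,pH,EC,NH4,NO2,NO3,PO4,COD,Na`).

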
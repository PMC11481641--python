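# Study-shaped synthetic monitoring campaign: 40 wells on a village-scale
# extent, sampled in 2013 (pre-sewerage) and 2017-2022 (post-sewerage, no
# 2020 campaign), with 3 wells dry in 2021 and 6 in 2022 (40/40/40/40/37/34
# samples, 231 in total). Per-year marginals are calibrated to the published
# per-year mean and quartiles of the eight parameters; the sewerage
# intervention is therefore encoded in the year-specific targets themselves
# and the explicit effect-factor mechanism is left at 1.0 here.
n_wells: 40
extent: [0.0, 0.0, 2000.0, 2000.0]
boundary_year: 2014
crs: "EPSG:23700"
spatial:
  range_m: 500.0
  sill_fraction: 0.5
dropout:
  2021: 3
  2022: 6
effects: {}
years:
  2013:
    pH:  {family: normal,    mean: 8.25,    q25: 7.92,    q75: 8.56}
    EC:  {family: lognormal, mean: 3032.65, q25: 1950.25, q75: 4310.0}
    NH4: {family: lognormal, mean: 0.69,    q25: 0.43,    q75: 0.87}
    NO2: {family: lognormal, mean: 0.31,    q25: 0.05,    q75: 0.42}
    NO3: {family: lognormal, mean: 187.83,  q25: 50.16,   q75: 341.77}
    PO4: {family: lognormal, mean: 1.22,    q25: 0.37,    q75: 1.75}
    COD: {family: lognormal, mean: 6.85,    q25: 4.03,    q75: 8.05}
    Na:  {family: lognormal, mean: 237.91,  q25: 132.18,  q75: 312.78}
  2017:
    pH:  {family: normal,    mean: 7.51,    q25: 7.29,    q75: 7.74}
    EC:  {family: lognormal, mean: 2845.78, q25: 1871.25, q75: 3507.5}
    NH4: {family: lognormal, mean: 0.53,    q25: 0.24,    q75: 0.64}
    NO2: {family: lognormal, mean: 0.20,    q25: 0.02,    q75: 0.17}
    NO3: {family: lognormal, mean: 142.65,  q25: 37.65,   q75: 221.08}
    PO4: {family: lognormal, mean: 0.39,    q25: 0.09,    q75: 0.58}
    COD: {family: lognormal, mean: 7.65,    q25: 5.24,    q75: 9.90}
    Na:  {family: lognormal, mean: 377.94,  q25: 154.15,  q75: 422.48}
  2018:
    pH:  {family: normal,    mean: 8.00,    q25: 7.68,    q75: 8.29}
    EC:  {family: lognormal, mean: 2637.8,  q25: 1874.25, q75: 3190.0}
    NH4: {family: lognormal, mean: 0.65,    q25: 0.33,    q75: 0.68}
    NO2: {family: lognormal, mean: 0.21,    q25: 0.01,    q75: 0.30}
    NO3: {family: lognormal, mean: 109.76,  q25: 23.73,   q75: 153.03}
    PO4: {family: lognormal, mean: 0.65,    q25: 0.22,    q75: 0.86}
    COD: {family: lognormal, mean: 7.16,    q25: 3.59,    q75: 8.48}
    Na:  {family: lognormal, mean: 352.37,  q25: 182.32,  q75: 447.77}
  2019:
    pH:  {family: normal,    mean: 7.21,    q25: 6.97,    q75: 7.42}
    EC:  {family: lognormal, mean: 2773.43, q25: 1511.25, q75: 3792.5}
    NH4: {family: lognormal, mean: 0.52,    q25: 0.29,    q75: 0.62}
    NO2: {family: lognormal, mean: 0.26,    q25: 0.02,    q75: 0.31}
    NO3: {family: lognormal, mean: 170.73,  q25: 43.1,    q75: 244.85}
    PO4: {family: lognormal, mean: 0.48,    q25: 0.14,    q75: 0.60}
    COD: {family: lognormal, mean: 7.68,    q25: 4.58,    q75: 10.12}
    Na:  {family: lognormal, mean: 383.68,  q25: 185.37,  q75: 477.99}
  2021:
    pH:  {family: normal,    mean: 7.23,    q25: 7.06,    q75: 7.36}
    EC:  {family: lognormal, mean: 4128.92, q25: 1808.0,  q75: 5930.0}
    NH4: {family: lognormal, mean: 0.47,    q25: 0.25,    q75: 0.51}
    NO2: {family: lognormal, mean: 0.24,    q25: 0.03,    q75: 0.31}
    NO3: {family: lognormal, mean: 164.52,  q25: 33.19,   q75: 185.0}
    PO4: {family: lognormal, mean: 0.37,    q25: 0.09,    q75: 0.48}
    COD: {family: lognormal, mean: 4.21,    q25: 2.1,     q75: 4.14}
    Na:  {family: lognormal, mean: 319.88,  q25: 157.42,  q75: 362.57}
  2022:
    pH:  {family: normal,    mean: 7.27,    q25: 7.08,    q75: 7.50}
    EC:  {family: lognormal, mean: 3664.21, q25: 2163.75, q75: 4623.75}
    NH4: {family: lognormal, mean: 0.64,    q25: 0.38,    q75: 0.77}
    NO2: {family: lognormal, mean: 0.20,    q25: 0.04,    q75: 0.25}
    NO3: {family: lognormal, mean: 296.1,   q25: 76.1,    q75: 377.27}
    PO4: {family: lognormal, mean: 0.24,    q25: 0.1,     q75: 0.32}
    COD: {family: lognormal, mean: 2.19,    q25: 1.71,    q75: 2.58}
    Na:  {family: lognormal, mean: 153.51,  q25: 94.90,   q75: 205.26}
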
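# antnest-seep

Analysis toolkit for continuous in-situ methane monitoring at red wood-ant
(*Formica* group) nests. Mound-building ants sit at a curious intersection of
biology and geology: their nests are hot-spots of microbial CH₄ production,
and — where nests overlie fault networks — possible surface expressions of
geogenic methane micro-seepage. Separating those two sources requires
matching three continuous records: nest-gas chemistry (CH₄ concentration and
its carbon-isotope ratio δ¹³C-CH₄), ant activity from a fixed camera, and the
environmental context (weather, solid-earth tides, local micro-earthquakes).

The package implements that full chain and ships a synthetic-campaign
generator with known ground truth, so every stage is testable without any
field data.

## What it computes

**Ant activity from imagery** (`antnest_seep.antcam`). Consecutive grayscale
frames are registered by an exhaustive integer-translation search maximising
mutual information of the joint intensity histogram,
MI = Σᵢⱼ p(i,j) log₂ p(i,j)/(p(i)p(j)); the absolute difference image is
summed inside a mound mask (SAD); per-sensor polynomials (degree 1 for the
daytime sensor, degree 3 for the nighttime sensor) map centred/scaled SAD
onto manual activity categories.

**Anomaly detection and source partitioning** (`antnest_seep.gaschem`).
CH₄ peaks are samples strictly above the robust threshold median + k·MAD
(raw MAD, k = 2 by default); δ¹³C peaks are flagged either by the fixed
literal bounds (< −35‰ or > 0‰) or by a robust deviation rule
|δ − median| > k·MAD. Only coincident flags form true peak windows. For each
window, the Keeling plot — OLS of δ¹³C on 1/CH₄ — estimates the isotopic
signature of the admixed source as its intercept, by two-reservoir mass
conservation:

δ_obs = δ_s + C_a(δ_a − δ_s) · (1/C_obs)

Per-window intercepts are split into source families by 1-D two-means.

**Environmental associations** (`antnest_seep.envstats`,
`antnest_seep.tides`). Correlation-matrix PCA of the six-variable weather
table; sequential (type-I) ANOVA of a response on the first three weather
PCs; additive trend/seasonal/residual decomposition; lagged cross-correlation
(standard sample CCF convention, |r| ≤ 1); harmonic earth-tide series
(M2/S2/K1/O1 cosines); 2-D Gaussian kernel density of earthquake epicenters.

**Synthetic campaigns** (`antnest_seep.synthetic_data`). Named presets
(`microbial-default` at δ_s = −69‰, `fault-default` at −37‰,
`two-source-default`, `null-default`) generate an 8-day, 1-Hz nest-gas
record with eight nightly injection events on a 1.82-ppm atmospheric
background, instrument-level noise, ambient/reference channels, weather,
tides, a quake catalog and jittered camera frames — all reproducible
bit-for-bit from one seed.

## Worked example

```python
from antnest_seep import (scenario, simulate_gas, mad_threshold,
                          flag_ch4_peaks, flag_d13c_peaks, coincident_peaks)
from antnest_seep.gaschem import keeling_per_window, cluster_intercepts

gas = simulate_gas(scenario("two-source-default", seed=42))
nest = gas[gas.channel == "nest"].reset_index(drop=True)

threshold = mad_threshold(nest.ch4, k=2)
peaks = coincident_peaks(
    nest.timestamp,
    flag_ch4_peaks(nest.ch4.to_numpy(), threshold),
    flag_d13c_peaks(nest.d13c.to_numpy(), mode="deviation"))
fits = keeling_per_window(nest, peaks)
labels, centers = cluster_intercepts([f.intercept for f in fits])
```

Output:

```
CH4 anomaly threshold: 1.827 ppm
coincident peak windows: 8
  window intercept  -69.09 permil (95% CI -69.26 .. -68.92, n=3645)  cluster 0
  window intercept  -37.09 permil (95% CI -37.38 .. -36.80, n=3588)  cluster 1
  ...
cluster centers: [-68.99 -36.91] permil
```

The threshold sits just above the 1.82-ppm background (the noise MAD is a
few thousandths of a ppm); all eight injected events are recovered as
coincident windows; the per-window Keeling intercepts cluster tightly around
the two configured end members, −69‰ (microbial) and −37‰ (fault-related),
with 95% CIs covering them.

The same chain runs from a shell:

```sh
antnest-seep simulate --scenario two-source-default --seed 42 --out bundle/
antnest-seep peaks --gas bundle/gas.csv --out peaks.csv
antnest-seep keeling --gas bundle/gas.csv --out keeling.csv
antnest-seep run --config campaign.yaml --out report/
```

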
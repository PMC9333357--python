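# nanocoloc

Nanoscale cluster and co-localization analysis for **dual-color
single-molecule localization microscopy (SMLM/dSTORM) of synapses**, plus
FRAP mobile-fraction estimation — built for neuroscientists quantifying the
subsynaptic organization of scaffold proteins (e.g. PSD95) and receptors
(e.g. the AMPA-receptor subunit GluA1).

Raw dSTORM data arrive as *localization tables*: one fitted emitter position
per row, with frame index, photon count and localization precision.
`nanocoloc` turns two such tables (one per color channel) into per-synapse
biology:

1. **Filtering** — localizations with precision > 30 nm (GluA1) / > 25 nm
   (PSD95), or photons outside 300–30,000, are removed; consecutive
   localizations within 60 nm are collapsed as re-blinks of one emitter
   (chains persisting > 10 frames lose their first member too).
2. **Synapse ROIs** — outlined at the full-width-half-maximum of spots in a
   widefield reference image; localizations are assigned by
   point-in-polygon; synapses need > 800 PSD95 and > 400 GluA1
   localizations and a PSD area between 0.02 and 0.3 µm².
3. **Nanodomains** — each localization's *local density* `LD` is its
   neighbor count within `5 × MNND` (mean nearest-neighbor distance);
   localizations with `LD > 40` are clustered (single linkage, cut at the
   LD radius), split when two density peaks > 80% of the maximum lie > 80 nm
   apart with a < 30% valley between them, and bounded by the union of
   their Voronoi cells. Domains holding < 5% of the channel's localizations
   or with diameter < 30 nm are excluded.
4. **Co-localization index** — with the effective resolution
   `d = √(MNND² + ε²)` (ε = mean localization error),

   ```
   CI_i^A(d_B) = N_{A_i}^B(d_B) / mean(LD_B)
   ```

   the number of channel-B localizations within `d_B` of localization
   `A_i`, normalized by B's mean local density at the same radius. CI = 1
   means "B is as dense around A as around itself". Per-synapse means and
   the enrichment of CI inside vs. outside the other channel's nanodomains
   are reported.
5. **FRAP** — recovery traces are background- and bleaching-corrected,
   normalized (pre-bleach mean → 1, first post-bleach frame → 0), and the
   mobile fraction is the mean of the last four frames.

Because such studies rarely deposit raw microscopy data, the package ships
a first-class, ground-truth-labeled **synthetic-data generator**
(`nanocoloc.synthetic`) that emulates the acquisition regime (20,000 frames
at 50 Hz, geometric blink runs, precision/photon distributions in the
filter window) for every pipeline stage. All tests and the acceptance
script run on it.

## Worked example

```python
import numpy as np
from nanocoloc import (SynapseGroundTruth, simulate_synapse_pair,
                       detect_nanodomains, colocalization_index, ColocParams)

table_a, table_b, truth = simulate_synapse_pair(SynapseGroundTruth(), seed=1)
print(f"simulated localizations: PSD95 {len(table_a)}, GluA1 {len(table_b)}")

for nd in detect_nanodomains(table_a.coords(), channel="PSD95"):
    print(f"PSD95 nanodomain at ({nd.center_nm[0]:.0f}, {nd.center_nm[1]:.0f}) nm, "
          f"diameter {nd.diameter_nm:.0f} nm, {len(nd.members)} localizations")
print("ground-truth centers:", np.round(truth["domain_centers"]["PSD95"]).tolist())

eps_a = float(table_a.records["precision_nm"].mean())
eps_b = float(table_b.records["precision_nm"].mean())
res = colocalization_index(table_a.coords(), table_b.coords(), ColocParams(eps_a, eps_b))
print(f"effective resolutions: d_PSD95 = {res.d_a_nm:.1f} nm, d_GluA1 = {res.d_b_nm:.1f} nm")
print(f"mean co-localization index: PSD95 {res.mean_ci_a:.2f}, GluA1 {res.mean_ci_b:.2f}")
```

prints

```
simulated localizations: PSD95 2214, GluA1 1184
PSD95 nanodomain at (121, 9) nm, diameter 95 nm, 492 localizations
PSD95 nanodomain at (-121, -9) nm, diameter 93 nm, 537 localizations
ground-truth centers: [[-121.0, -9.0], [121.0, 9.0]]
effective resolutions: d_PSD95 = 12.6 nm, d_GluA1 = 15.9 nm
mean co-localization index: PSD95 0.69, GluA1 0.93
```

The two detected nanodomains sit on the generator's true centers to the
nanometer; the diameters (~95 nm) are the equal-area-circle diameters of
their Voronoi boundaries. The GluA1 channel shares its nanodomain center
with one of PSD95's, so its localizations see an elevated PSD95 density and
its mean CI approaches 1 despite the synapse's diffuse pool; CI values well
above 1 appear inside nanodomains (see the enrichment ratios in the
pipeline output).

The same stages are scriptable from the shell:

```bash
nanocoloc simulate --n-synapses 12 --seed 1 --outdir simulated
nanocoloc run --seed 1 --outdir results_run       # full pipeline, defaults
nanocoloc frap simulated/frap_traces.csv
```

`nanocoloc run` writes the filtered table, ROI polygons (GeoJSON),
`per_synapse.csv` / `per_nanodomain.csv`, and `summary.json` with every
threshold applied, per-stage record counts and OLS regressions of PSD size
against nanodomain distance and co-localization.

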
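# Methods

This note documents the models and procedures `nanocoloc` implements, the
parameters that matter, the numerical choices made where the procedure was
genuinely open, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Coordinate conventions

All positions are in nanometers, origin at the image top-left, y increasing
downward. A rendering or camera pixel `k` of size `p` covers the half-open
interval `[k·p, (k+1)·p)`; intensity samples sit at pixel centers
`(k + 0.5)·p`. Histogram reconstructions default to 12 nm pixels.

## Localization filtering

A localization is retained iff `precision ≤ precision_max(channel)` and
`photons_min ≤ photons ≤ photons_max`. Defaults: 30 nm (GluA1), 25 nm
(PSD95), 300 and 30,000 photons. All removals require a *strict* violation,
so boundary values survive; the same strictness convention is used for
every threshold in the package.

**Repeat (blink) removal.** Within each channel, localizations are chained:
a record joins an active chain when it appears within `repeat_radius`
(60 nm) of the chain's anchor and at most `frame_gap` (1) frames after the
chain's last member. All chain members after the first are removed; when
the chain spans more than `repeat_max_frames` (10) distinct frames the
first member is removed as well. Two policy choices are deliberate and
configurable:

* *Anchor* — by default the chain's most recent member (`link_to="last"`),
  which tracks a slowly wobbling emitter. This makes the filter only
  approximately idempotent at very high densities (interleaved chains of
  adjacent emitters can let a chain tail drift away from its kept seed);
  `link_to="seed"` anchors at the first member and is exactly idempotent.
* *"Consecutive"* means a frame difference of exactly 1 by default;
  `frame_gap` tolerates off-frames when raised.

Channels are scanned independently; when a record is in range of several
chains it joins the nearest, with ties broken by chain age, so removal is
deterministic in table order.

## Synapse ROIs

ROIs are outlined on a widefield image of the scaffold channel. The image
is Gaussian-smoothed (default 100 nm ≈ 1 camera pixel); the background is
the median of the smoothed image; peaks are local maxima strictly above
`background + min_peak_height` (default: 20% of the dynamic range above
background; background estimator and peak rule are not standardized
anywhere, so both are explicit parameters here). Each
ROI is the marching-squares contour at the half-maximum level
`background + (peak − background)/2` that encloses its peak, giving a
sub-pixel polygon in nm; a region already claimed by a higher peak is not
duplicated.

Localizations are assigned by point-in-polygon membership (boundary points
count as inside). Overlapping ROIs are resolved to the nearest peak and the
overlap is flagged — separating touching synapses has no canonical rule,
so this one is the package's explicit choice.

A synapse enters the analysis only if it has strictly more than 800 PSD95
and 400 GluA1 localizations and its PSD area lies strictly between 0.02 and
0.3 µm². The size window is applied as the conjunction
0.02 µm² < area < 0.3 µm² — the only reading that excludes anything. The area criterion applies
to the PSD area (below), with the ROI polygon area as a logged fallback.

## PSD center and area

The PSD is the largest DBSCAN cluster of scaffold-channel localizations
inside the ROI (defaults: `eps = 5 × MNND` of those points, `min_samples
= 5`; both configurable). The PSD center is the
arithmetic centroid of the cluster; the PSD area is its convex-hull area.
A synapse whose scaffold channel yields no cluster is flagged and excluded.

## Nanodomain detection

For one channel within one synapse:

1. `MNND` = mean over points of the distance to the nearest other point;
   the LD radius is `5 × MNND`.
2. `LD_i` = number of *other* same-channel points within the radius
   (boundary-inclusive). Excluding the point itself makes `LD = 0` for an
   isolated point and the threshold an interpretable neighbor count.
3. Points with `LD > 40` are grouped by single-linkage hierarchical
   clustering with the dendrogram cut at the LD radius — points within the
   density-support radius are density-connected. (Linkage flavor and cut height are design
   choices of this package; both are configurable.)
4. **Subcluster rule.** Density peaks are members whose LD is maximal among
   members within half the minimum peak separation (40 nm) of themselves.
   Peaks with LD strictly above 80% of the group maximum are *retained*;
   two retained peaks split apart iff they are strictly more than 80 nm
   apart **and** the minimum LD among members within a straight 40-nm-wide
   corridor joining them is strictly below 30% of the maximum. Members are
   reassigned to the nearest retained peak. The corridor geometry for the
   "local minimum" test is this package's explicit choice (width
   configurable); a density-grid path search would be a valid alternative.
5. **Boundary.** Each group is bounded by the union of its members' Voronoi
   cells, computed over all of the synapse's channel points (cells of
   boundary members are unbounded and are clipped to the synapse ROI).
6. **Exclusions.** Groups with a member fraction strictly below 5% of the
   synapse's channel localizations, or an equal-area-circle diameter
   (`2·√(area/π)` of the boundary) strictly below 30 nm, are discarded.
   "Diameter" of an irregular cluster is ambiguous, so the maximal
   pairwise member distance is also reported (`max_extent_nm`, selectable via
   `diameter_mode`).

A nanodomain's center is the arithmetic mean of its member positions.
Topology metrics report each nanodomain's distance to the PSD center and
the center-to-center distance to the closest nanodomain of the other
channel (missing, with a flag, when the other channel has none).

Note a scale-invariance worth knowing: for a *homogeneous* point pattern
the expected LD at radius `5 × MNND` is ≈ 19.6 regardless of density, so
the `LD > 40` threshold fires only where density is locally elevated
relative to the synapse-wide spacing — i.e. the rule detects density
*contrast*, not absolute density.

## Co-localization index

Per synapse and channel pair, with `ε` the mean fitted precision of the
channel's localizations in the synapse (one natural summary of the
per-localization error) and `d = √(MNND² + ε²)` the effective resolution:

* `LD` of each B point: number of other B points within `d_B`
  (self-excluded); `mean(LD_B)` is its average.
* `CI_i^A = N_{A_i}^B(d_B) / mean(LD_B)`, where the numerator counts B
  points within `d_B` of `A_i` (boundary-inclusive); symmetrically for
  `CI_i^B`. Per-synapse values are arithmetic means over localizations.

**Self-handling.** When A and B are literally the same point set, the
numerator excludes the index-identical point, mirroring the LD convention.
The per-synapse mean is computed as `mean(N)/mean(LD)`, so a channel
against itself gives mean CI = 1 *exactly* (bitwise `m/m`), and under
spatial independence the estimator is unbiased up to the `n/(n−1)`
finite-sample factor. MNND and ε are computed per synapse per channel, not
globally.

**Nanodomain enrichment** is the ratio of the mean CI of localizations
inside any nanodomain boundary of the *other* channel to the mean CI of
those outside all of them; 1 is the no-enrichment null. Empty inside or
outside groups make the ratio undefined (NaN + flag).

## FRAP

Traces are ROI mean intensities sampled every 5 min (3 pre-bleach frames,
then 30 min post-bleach in the default protocol).

* **Correction**: `corrected(t) = (roi(t) − bg(t)) · refPre / (ref(t) −
  bg(t))` with `refPre` the pre-bleach mean of the background-subtracted
  bleach reference. Ratio correction against an unbleached reference region is the default
  (an exponential-fit correction would be the main alternative); it
  cancels any affine camera gain/offset.
* **Normalization**: pre-bleach mean → 1, first post-bleach frame → 0.
* **Mobile fraction**: mean of the last four normalized frames; per-cell
  values are means over that cell's ROIs. Note this estimates the plateau
  *at the sampled times*: for `M·(1 − e^(−t/τ))` with τ = 8 min and frames
  at 15–30 min, the expectation of the last-four mean is ≈ 0.92·M — the
  estimator is compared against that closed form, not against M.
* **Synaptic enrichment**: mean over small disc ROIs (250 nm diameter, 10
  per compartment) of synapse intensity divided by dendritic-shaft
  intensity, background-subtracted.

## The synthetic-data generator

`nanocoloc.synthetic` emulates, per synapse: a PSD disc (radius 220 nm →
area 0.15 µm², inside the 0.02–0.3 µm² window) filled with a baseline pool
of localizations (defaults 3000 /µm² for PSD95 and 2000 /µm² for GluA1,
landing the channels above the 800/400 inclusion minima) plus Gaussian
nanodomains (σ = 25 nm, 300 localizations each; PSD95 two domains, GluA1
one, sharing centers by default with a configurable offset). Emitters blink
in geometric-length runs of consecutive frames (mean 2) over a 20,000-frame
/ 50 Hz acquisition, so the 60 nm / >10-frames repeat filter is exercised,
including the long-run branch. Precision is truncated-normal (12 ± 4 nm
PSD95, 15 ± 5 nm GluA1) and photons log-normal (median ≈ 2000, log-sd 0.6),
placing most — but not all — localizations inside the filter windows.
Widefield images are the localization density blurred by a Gaussian PSF
(σ = 150 nm) on a 100 nm camera grid. FRAP traces follow a
single-exponential recovery (defaults M = 0.31 or 0.20, τ = 8 min, noise
σ = 0.02 of the bleach depth) pushed backwards through the correction
model (background 20, reference decay 0.4%/min).

It does **not** emulate: photoswitching kinetics or duty cycles, sample
drift or channel misalignment (inputs are assumed drift-corrected and
registered), astigmatic/3-D PSFs, detection failures at low photon counts,
or structured background (dendritic shafts, out-of-focus synapses).
Passing tests therefore demonstrate the correctness and statistical
behavior of the *analysis* under the stated point-process model, not
robustness to those instrument effects.

## Problem sizes and numerical choices

The default end-to-end dataset is 12 synapses (≈ 40,000 localizations
pre-filter), which the full pipeline processes in a few seconds; statistical
tests use 50–200 seeds per condition and the oracle-equivalence checks use
tables of up to 1,000 points, where brute-force all-pairs counting is
feasible. Voronoi diagrams are bounded by eight ghost points far outside
the ROI before clipping; duplicate positions share a cell. Degenerate
inputs raise typed errors rather than returning silent defaults: MNND of a
single point, DBSCAN without a cluster, a bleach reference at or below
background, zero bleach depth, fewer post-bleach frames than the plateau
window. Monte-Carlo nulls for the enrichment ratio draw the uniform channel
on a window padded beyond the ROI by several effective resolutions;
otherwise edge depletion of the CI field outside nanodomains biases the
null ratio above 1 — a test-design point, not a pipeline parameter.

## Known limitations

* Strictly 2-D; no axial information is used anywhere.
* The subcluster valley test inspects member LDs inside a straight
  corridor; a curved density ridge between peaks can in principle evade it.
* PSD area uses the convex hull, which overestimates concave PSDs;
  alpha-shapes are a possible extension.
* The repeat filter's default most-recent-member chaining is only
  approximately idempotent at extreme densities (see above).
* Linear regressions in the run summary are ordinary least squares on
  per-synapse values, reported for orientation; they are not the package's
  contribution and carry no small-sample corrections.
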
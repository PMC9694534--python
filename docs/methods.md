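# Methods

This note records the models, conventions and default parameters the
package implements, the design choices that were genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Threshold calibration

With no particle in the beam the detectors record a background
fluorescence. For each channel the threshold is the background mean plus
`k` standard deviations, `k ∈ {3, 6, 9}`. Choices made here:

* **Sample standard deviation** (ddof = 1). With hundreds of
  forced-trigger firings the difference from the population estimator is
  negligible, but the sample form is the defensible default for an
  estimated spread.
* **Daily sessions** can be combined by `mean` (default) or `latest`.
  The per-channel *relative spread* of the session thresholds
  (sample sd / mean) is always reported so drift is visible; within-day
  drift is not modelled.
* Thresholds apply campaign-wide unless per-day sets are explicitly
  supplied.

## Classification

Exceedance is **strict** (`intensity > threshold`); a value exactly at
the threshold does not fluoresce. The FL1–FL3 exceedance triple maps
bijectively onto {NonFluorescent, A, B, C, AB, AC, BC, ABC}; the FL4–FL5
pair maps onto {None, D, E, DE}. Both taxonomies partition the particle
set, so class counts always sum to the particle count.

"Fluorescent" for summary fractions means exceedance in **any of the
five channels** by default (`fluorescence_basis="fl12345"`); the
FL1–FL3-only basis is a switch, because a D-only particle is a genuine
edge case the two conventions count differently.

Saturated intensities (at the detector ceiling, default 2047 units,
configurable) classify normally and carry a `saturated` flag; the
ceiling is instrument-specific and deliberately not hard-coded.

## Proxy filters

Boundary conventions are centralised: "greater than" and "less than"
are strict; a printed range such as 10–15 µm is closed on both ends.
All criteria in a filter are conjunctive. The 2 µm comparison floor is a
separate, σ-agnostic filter applied before any instrument comparison
(impaction counting is unreliable below that size). The `total_pollen`
intensity cut (FL2, FL3 > 1300) operates on raw detector units, not on
background-subtracted values.

The `herb_pollen` (D, 10–15 µm) and `grass_pollen` (D, > 10 µm)
selections overlap by construction — a 12 µm D particle satisfies both.
The overlap is kept as defined and visible in the outputs rather than
resolved by fiat.

## Concentrations

Concentration per bin is `count / (flow × bin duration)` in m⁻³. The
WIBS sample flow defaults to **0.23 L/min** (configurable; every output
records the flow used) against the Hirst's 10 L/min — so one WIBS day
samples ≈ 0.33 m³. Bins are aligned to local campaign time; daily bins
are calendar days, matching Hirst tape segments. A bin is reported only
if at least 75 % of it (configurable) falls inside declared instrument
uptime; otherwise it is missing, never zero. Diurnal profiles are the
mean concentration per hour of day across days, divided by the maximum
hourly mean (mean-normalisation available by flag).

## Comparison statistics

Series are paired by inner join on calendar date, with missing WIBS days
dropped and the pair count always reported. Pearson r is computed on raw
(untransformed) daily values; linear R² equals r² by construction and is
verified to 1e-10; the polynomial regression defaults to degree 2 (the
smallest nesting that can capture saturation curvature). An optional
flag removes a stated number of largest-residual points before fitting;
it is off by default. "High" days strictly exceed 50 (grass), 80
(herb), 80 (tree) grains/m³ and 2500 spores/m³ (fungal); co-occurrence
is reported as the 15 disjoint Euler regions over the four groups.

## Clustering

Features are the five intensities, size and AF, z-scored to mean 0 and
sample sd 1; constant features are dropped with a warning. K-means uses
10 restarts (best inertia kept) and a mandatory seed; the cluster count
is chosen by maximising the Calinski–Harabasz index over k = 2…12 by
default, ties going to the smaller k. Cluster–taxon mapping correlates
each cluster's daily concentration with each reference series and then
greedily grows a cluster union (cap 2) per taxon, keeping the union only
if it improves the linear R² of the summed series — so the reported
union never scores below the best single cluster.

## Synthetic campaigns

The generator emulates a ~50-day spring campaign at a semi-urban site
with seven classes: ascospore-like and *Cladosporium*-like fungal
spores (FL1/FL2-fluorescent, < 10 µm, early-morning emission peak),
large tree pollen (ABC- and DE-like, ~30 µm, strongly fluorescent in
FL2/FL3), herb pollen (D-like, 10–15 µm), grass pollen (D-like, large
and heavily undersampled: capture efficiency 0.35), an anthropogenic
interferent whose FL1/FL2 intensities sit between the 3σ and 9σ
thresholds (so escalation removes it), and non-fluorescent dust.

Per day and class: a true concentration is drawn from a lognormal around
the class mean (mean-1 factors, class-specific CV), thinned by capture
efficiency, converted to an expected count through the sampled volume,
and realised as a Poisson count; timestamps follow 24 hourly emission
weights; intensities, size and AF are truncated normals (at zero / the
detector range), with saturation at the ceiling arising naturally. A
five-day power-loss gap two weeks in exercises missing-data handling:
truth and Hirst observations continue, the particle stream stops. Hirst
observations apply a multiplicative lognormal counting error (mean 1,
CV 0.30 by default) to the true per-(day, taxon) concentration.

Default mean concentrations (per m³): ascospores 2000, *Cladosporium*
1000, dust 5000, interferent 2000, tree 120, herb 60, grass 40 — fungal
spores and dust dominating by number, pollen rare but large, with
day-to-day CVs of 0.4–1.0. True labels live in a side table; the
particle stream itself is label-blind.

**What passing tests show — and don't.** The generator reproduces the
qualitative structure of real campaigns (class separations, diurnal
cycles, undersampling, counting error) with clean parametric
distributions. Real data add atmospheric ageing, humidity effects on
fluorescence, agglomerates (a *Cladosporium* cluster switch exists but
defaults off), heavy-tailed intensity distributions and weather-driven
emission; recovery results here bound what the pipeline can do under its
own assumptions, not field performance.

## Problem sizes and runtime

The default 50-day scenario yields ≈ 150 k particles and runs the full
pipeline (including two intra-categorical clustering passes over
k = 2…12 with 10 restarts each) in well under a minute on one CPU. The
test suite uses 4–10-day campaigns for structural checks and the full
50-day scenario, at the documented seed 20170421, for the recovery
checks; the Hirst CV check uses 10⁴ replicate days.

## Known limitations

* No inlet-loss or sampling-efficiency correction is applied to
  measured concentrations; undersampling is modelled only in the
  generator.
* The grass proxy (D > 10 µm) is dominated by herb-like D particles in
  the default scenario, mirroring how chlorophyll-band selections
  confound taxa with shared fluorophores; its recovery correlation is
  accordingly weak.
* Timestamps are local campaign time with no DST or timezone logic.
* The instrument's native binary format is out of scope; inputs are the
  documented CSV schemas.
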
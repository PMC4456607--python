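# Methods

This note records the models behind `unzipmap`, the defaults that matter,
and the design choices made where more than one reasonable option existed.

## The unzipping trace model

A trace is the force the instrument applies as a function of base pairs
unzipped.  We model it per base pair: bp *j* carries a disruption threshold
`T(j)`; the fork advances while the applied force is at least `T(j)` and
otherwise the force ramps linearly in time at the loading-clamp rate
(15 pN/s).  After a disruption the excess force above the baseline relaxes
exponentially as the fork advances, with bp constant `relax_bp` (default
5 bp), so an interaction shortly downstream of another is met at an elevated
entry force.  The recorded disruption force at bp *j* is therefore
`max(T(j), relaxed carry-over)`, and the per-bp dwell time is the stall
(ramp) time plus a transit time (fork speed default 200 bp/s, which only
matters for dwell histograms).

**Naked baseline.** Real unzipping forces are sequence dependent; sequence
thermodynamics is deliberately out of scope.  The baseline is a stationary
stochastic surrogate: mean 15 pN, Gaussian-filtered white noise with sd 1 pN
and 3 bp correlation length, clipped at ±4 sd so a naked trace can never
mimic a protein signature.  It is seeded per *template*, so all traces of a
template and its naked reference share one reproducible feature landscape —
exactly what cross-correlation alignment needs.

**TF signature.** One Laplace-shaped threshold bump, peak force drawn
uniformly from 18–20 pN per trace, centered 8 bp before the site center
along the unzipping direction (the front edge of the TF footprint is what
the fork feels).

**Nucleosome signature.** Two clusters of larger peaks.  Each cluster is
five Laplace sub-peaks at integer offsets {−9, −4, +1, +6, +11} bp around
the cluster centroid with decreasing relative amplitudes
{1, 0.9, 0.85, 0.8, w₅}; w₅ is solved so the prominence-weighted centroid
of the sub-peaks equals the nominal centroid exactly.  The first-cluster
centroid sits at dyad − 43 bp, the second at dyad + 5 bp; per-trace cluster
max forces are drawn from 25–35 pN.  Two further choices are deliberate:

* the Laplace decay scale equals `relax_bp`, so on the falling flank the
  threshold coincides with the relaxation curve and recorded peak
  neighborhoods stay symmetric — this makes sub-bp peak refinement, and
  hence the 43 bp dyad convention, exact on noiseless input;
* amplitudes decrease into the cluster, so the largest stall (dwell-time
  argmax) falls on the cluster's leading edge, reproducing the behavior of
  dwell histograms under a loading-rate clamp.

**Instrument.** Acquisition at ~12 kHz low-passed to 60 Hz is emulated at
the level of the reduced force-vs-position record: measurement noise is
added per bp with post-filter sd 0.15 pN and 2 bp correlation.  Instrumental
distortion maps positions x → stretch·x + shift with |shift| ≤ 10 bp and
|stretch − 1| ≤ 2% — the box the alignment search covers.

## Alignment

The fit is an exhaustive grid search (stretch step 0.001; at each stretch
the best shift on a 0.1 bp interpolation grid), scoring the normalized
(zero-mean, unit-variance per window) cross-correlation of forces over
protein-free windows, each window entering with equal weight.  Windows
flank the expected signature regions with a guard of ~12 bp + 2% of the
template length; an end-positioned nucleosome leaves only the pre-signature
window.  Grid search was chosen over gradient methods because it is exactly
reproducible, trivially testable against brute-force enumeration, and the
search space is tiny.  Ties break toward smaller |shift|, then stretch
closer to 1.  Under default noise the recovered parameters are within
0.5 bp / 0.002 across the whole distortion box.

## Signature calling

The baseline for a trace is its (aligned) naked reference, lightly smoothed
(σ = 1 bp); the detection threshold is baseline + max(k·σ_resid, 1 pN) with
k = 3.  The absolute 1 pN floor matters: after 60 Hz filtering the residual
sd is ~0.2 pN, and 3 sd alone would sit below plausible correlated-noise
excursions in a ±30 bp search window; with the floor, bound/unbound
classification is ≥99% sensitive and specific at the default signal levels,
while the smallest real signature (18 pN − 15 pN = 3 pN) clears it several
times over.

Events are local maxima of force − baseline above threshold, refined to
sub-bp by parabolic interpolation; clusters split at inter-event gaps
>15 bp, and a cluster counts as nucleosomal when its max force exceeds
22 pN (both config keys, chosen to separate the default signatures with
margin).  The cluster centroid is, by default, the prominence-weighted mean
of event-peak positions.  An alternative reading — integrating all
above-threshold samples across the cluster span — is available via
`centroid_mode="sample"`, but it is *not* the default because the
post-disruption relaxation tail is one-sided along the unzipping direction
and biases any sample-integrated centroid by 1–2 bp; the peak-weighted form
keeps the 43 bp convention exact and direction-symmetric.

Calls follow the geometry: TF center = peak + 8 bp; dyad = first qualifying
cluster centroid + 43 bp, both along the unzipping direction, so traces
unzipped from either end give the same positions in dyad coordinates.  A TF
window overlapping a nucleosome-strength cluster is flagged `masked`
(indeterminate) instead of unbound, since a nucleosome signature can hide a
TF's.

## Remodeling phenomenology

Reactions apply K ~ Poisson(λ) sequential events per molecule.  Short
(~1 min) reactions use λ = −ln 0.55, fixing the unremodeled fraction at
55%; the quoted companion numbers (~56% unremodeled vs "remaining ~45%")
are mutually inconsistent by 1%, so the generator exposes p₀ as the single
source of truth rather than resolving the discrepancy.

**ISW1a** senses flanking DNA: each event pulls the dyad halfway toward the
midpoint of the accessible segment — between the bound TF's footprint edge
and the template end (or the whole template without a TF) — plus Gaussian
step noise (sd 7 bp), rejecting any move that would place the 73 bp
half-footprint across a bound TF footprint or off an end.  Long reactions
(λ = 8) therefore converge to a stationary distribution centered on the
accessible-segment midpoint (spread ~8 bp): the TF acts as a barrier and a
reference point, and no dyad ever passes it.

**SWI/SNF** does not respect the TF.  Each event displaces the dyad by a
half-normal step (sd 60 bp) whose direction is biased toward the TF
(p = 0.65) *while the TF remains bound* — each event is a fresh remodeler
binding, and the linker-sensing subunit orients sliding the same way every
time — and symmetric otherwise, truncated to keep the nucleosome on the
template.  If the footprint swept during a move overlaps the TF footprint,
the TF is evicted (first overlap, permanently).  Long reactions use λ = 30,
chosen so a 10-minute reaction randomizes final positions across the whole
1200 bp template (walk sd ≳ 300 bp), the regime the assay operates in; a
consequence, not an input, is that essentially every remodeled molecule
sweeps the TF site at some point, so TF retention among remodeled molecules
is ~0 and final dyads appear on both sides of the TF.  A first-event-only
bias was tried and rejected: molecules that happen to step away first
self-select into never returning, leaving a ~16% retained fraction that
contradicts the observed complete eviction.

## Population statistics

* **Double-Gaussian mixture.**  Maximum likelihood by EM on raw positions
  with four fixed starts (narrow mean initialized at 0, the designed dyad),
  components relabeled so σ₁ ≤ σ₂; deterministic given the data.  A
  histogram least-squares mode (5 bp bins) is provided for fidelity to
  binned-fit practice and agrees with the MLE within tolerance on default
  data; likelihood is the default because it is binning-free and better
  behaved at small n.  A σ floor of 0.5 bp (position calls are
  measurement-limited well below 1 bp) prevents spike components on
  integer-valued calls, and the second component is flagged degenerate when
  a single Gaussian has at least as good a BIC — in that case the
  unremodeled weight reports 1.
* **Event fractions.**  λ = −ln p₀; P(K=1 | K≥1) = λe^(−λ)/(1−e^(−λ)).
  At p₀ = 0.55 this gives 73%/27% once/multiple.
* **K_d.**  Nonlinear least squares on f = c/(c+K_d), standard error from
  the Jacobian; all-bound or all-unbound titrations are rejected as
  unidentifiable.
* **Occupancy vs time.**  OLS line; "no significant dissociation" when the
  95% CI of the slope covers zero.
* **Centering / directionality.**  Midpoint deviation and distance moved
  per molecule, with seeded-bootstrap standard errors (1000 resamples).
  Molecules whose dyad passed the TF, or that lack a bound TF, are flagged
  outliers (in the real assay ~5% of templates never bound the TF) but kept
  by default.  Eviction summaries count TF retention and TF-passing among
  remodeled molecules (displacement > 2 bp).

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: a
reproducible featured baseline, signature geometry tied to the 8/43 bp
conventions, instrument shift/stretch within a declared box, Poisson event
counts, barrier/eviction rules, and isotherm-distributed occupancy.  It does
*not* model real sequence thermodynamics (the baseline is a surrogate, so
absolute naked-force profiles are not comparable to any particular
sequence), histone loss or partial unwrapping, remodeler kinetics beyond
event counts and displacement rules, or bp↔nm elasticity conversion
(positions are generated directly in bp).  Passing tests therefore
demonstrate that the *pipeline* recovers what the generator encodes at
realistic noise — not that these exact numbers would be measured on any
specific real template.

## Problem sizes and numerics

Test and acceptance runs use deliberately modest ensembles — 100–250 traces
for precision and classification checks, 150–200 molecules per remodeling
ensemble, n = 2000 for mixture recovery, 10⁶ draws for the Poisson
Monte-Carlo oracle — sizes at which the binomial/bootstrap error bands
quoted in the tests are meaningful.  All randomness flows from a single
seed through `numpy` `SeedSequence` spawning (per-molecule sub-seeds are
recorded), so (config, seed) determines every output exactly; positions are
handled in double precision with linear interpolation on a 0.1 bp grid, and
degenerate inputs (constant windows, empty manifests, corrupt trace files,
unidentifiable fits) raise or are flagged rather than silently absorbed.
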
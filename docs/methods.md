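# Methods

This note documents the models, estimators and numerical conventions
behind `mtkit`, and what its synthetic-data generators do and do not
emulate.

## Transport segmentation and metrics (`mtkit.transport`)

A trajectory is a uniformly sampled sequence of 2-D positions (um). The
instant speed of interval *i* is the Euclidean inter-frame displacement
divided by the frame interval — the quantity a manual-tracking tool
exports — not a projection onto the track axis.

Segmentation is a single speed threshold `v_pause` (default 0.2 um/s,
the conventional cutoff separating motor-driven transport from
stationary jitter at ~0.5 frames/s sampling): an interval is a *pause*
iff its speed is strictly below the threshold; a speed exactly equal to
it counts as transported, because the pause state is defined as "less
than" the cutoff. A *pause event* is a maximal stretch of consecutive
pause intervals of at least `min_pause_frames` (default 1; no minimum
duration is imposed because none is established, and the parameter is
exposed).

The *run window* spans from the first to the last interval at or above
`v_pause`; leading and trailing stationary tails are excluded from run
time. Within the window the five per-particle metrics are:

* run length `L` — sum of transport-interval displacements (um);
* run time `T` — pausing plus transporting time (s);
* total run velocity — `L / T`;
* transport velocity — mean instant speed over transport intervals;
* pausing time ratio — pausing time / `T` (in [0, 1]);
* pausing frequency — number of pause events / `L` (events per um).

A particle is *motile* iff `L` strictly exceeds `d_min_motile`
(default 2 um). Filtering order is window -> segmentation -> motility
filter. Tracks whose net axis-projected displacement is below 0.5 um are
flagged direction-ambiguous rather than forced into the
anterograde/retrograde dichotomy; bidirectional tracks are classified by
net displacement, not split.

Group comparison offers Student's unpaired two-tailed t-test and the
Mann-Whitney U test; the latter enumerates the exact null when the
smaller group has at most 8 observations and the data are tie-free,
otherwise it uses the normal approximation. Identical zero-variance
groups are reported as p = 1.0 (the t statistic is 0/0 there; no
evidence of a difference is the only defensible reading). SEM is
sd(ddof=1)/sqrt(n).

## Trajectory generator (`mtkit.simulate.trajectories`)

Particles follow a two-state Markov chain (transport/pause) with
per-interval entry and exit probabilities, so the stationary pause
probability is `p_pause / (p_pause + p_resume)`; initial states are
drawn from the stationary distribution. While transporting, the 1-D
track coordinate advances by a Gaussian speed (truncated at 0) times the
frame interval; while paused it does not move. Positions are embedded in
2-D along a unit axis and blurred with isotropic Gaussian localization
noise — the only source of apparent motion while paused, which makes the
error rate of the 0.2 um/s rule computable in closed form.

Defaults emulate spinning-disk imaging of axonal mitochondria: 0.5
frames/s for 3 min (91 points), transport speed 0.5 +- 0.1 um/s,
`p_pause` 0.1, `p_resume` 0.5 per 2-s interval, localization sd 0.05 um.
At these settings pause-interval apparent speeds are Rayleigh with mean
~0.04 um/s, five standard deviations below the threshold, so ground-truth
states are recoverable and analytic expectations hold:
pause fraction = 1/6 and pausing frequency ~ `p_pause` / (mean transport
step) = 0.1 per um.

One deliberate subtlety: the *measured* mean transport speed exceeds the
latent mean by a second-order localization-noise term
`sigma_loc^2 (1 + cv^2) / (mu dt^2)` plus the sub-threshold truncation
lift `phi((v_pause - mu)/sd) sd` — about +0.4% at defaults. Round-trip
tests compare against this measured-speed expectation, not the latent
mean; with 200 tracks the SEM (~0.2%) resolves the difference.

What the generator does not emulate: heterogeneous per-particle speeds,
photobleaching, focus drift, track fragmentation, or dwell-time
distributions beyond geometric. Passing round-trips therefore validate
the estimator chain, not tracking quality on real movies.

## Streaming movies, flow and classification (`mtkit.streaming`)

### Generator

Vesicles are advected by one of four flow archetypes in a 96x128 px
field (0.65 um/px, one frame per 2 s for 2 min, ~150 vesicles rendered
as Gaussian spots of sigma 2 px on a noisy background):

* **circular_central / circular_anterior_biased** — rigid rotation
  (exact per-frame rotation, default 0.012 rad/s, tangential speeds
  ~0.2 um/s at mid-radius) about a center at AP fraction 0.5 / 0.3;
* **disordered** — a field of per-patch (12 px) random unit directions
  at matched speed, redrawn every 20 s: a frozen random field would
  contain only ~90 independent directions, giving the coherence
  statistic a heavy tail that real, temporally decorrelating chaotic
  flow does not have;
* **partial_posterior_disrupted** — the rotation field multiplied by a
  logistic damping that falls to zero across a 2-px shear layer at 60%
  of the AP axis, so the posterior 40% has no coherent flow. The thin
  smooth layer replaces a hard velocity step, which is impossible in
  viscous (Stokes) cytoplasm and made advected vesicles pile up on the
  boundary line.

All vesicles also receive a small random velocity each frame
(0.05 um/s sd, Brownian-like) and are kept in-field by border
reflection.

### Flow estimation

Flow is measured without particle detection: for each 12-px patch on a
regular grid and each of 12 frame pairs `(t, t+5)`, the displacement is
the argmax of the normalized cross-correlation within +-6 px; patches
whose correlation peak is below 0.3 are dropped. The 5-frame gap makes
physiological displacements span ~3 px (integer NCC quantization then
costs <10 degrees of direction error), while Brownian displacements stay
sub-pixel and register as zero.

### Rotation center and coherence

The rotation center minimizes the normalized squared radial component of
the flow, by coarse grid search refined with Nelder-Mead. The tangential
coherence is

    kappa = | mean_i (v_i . t_hat_i) / |v_i| |,

with zero-velocity vectors contributing 0; kappa is 1 for perfect
unidirectional rotation, ~1/sqrt(n) for random directions, and is
invariant under uniform speed rescaling. An all-parallel field carries
no curl information; it is flagged degenerate and kappa is evaluated
about the vector centroid.

### Classification

The four-pattern call uses explicit, configurable thresholds:

1. **circular** iff kappa >= 0.6 *and* the posterior-window coherence
   (vectors at AP fraction >= 0.6, about the fitted center) is >= 0.3;
   among circular, **anterior_biased** iff the center's AP fraction
   < 0.4, else **central**.
2. otherwise **abnormal_partial** iff the anterior-window vectors alone
   are coherent (kappa >= 0.6 about their own fitted center) while the
   posterior vectors are not (< 0.3); else **abnormal_chaotic**.

The posterior condition on the circular call is load-bearing: an ideal
posterior-disrupted field has overall kappa -> 0.6 exactly (60% coherent
vectors), i.e. *on* the circular threshold, and grid quantization of the
anterior fraction pushes a well-estimated partial field slightly above
it. Posterior coherence separates the two classes with an order of
magnitude of margin (~0.8-0.97 for true rotation vs ~0.06 for a
disrupted posterior) and encodes the taxonomy's meaning: flow that dies
in the posterior is abnormal no matter how coherent the anterior
rotation. On a 4 x 40-seed sweep at default noise the classifier is
160/160 correct; the packaged benchmark asserts >= 95% over 200 movies.

Kymographs sample each frame along a polyline at 1-px arc steps,
bilinearly, averaged across `width` evenly spaced normal offsets.
Cortical unidirectionality is the fraction of structure-tensor streak
energy sharing the dominant slope sign, after discarding near-horizontal
(static) streaks, a border margin of 3 sigma, and kymographs whose
sloped-streak energy is below 0.1% of the oriented energy (featureless
or static input -> undefined).

Percentages in genotype summaries are integer-rounded half-up, which
reproduces every printed proportion checked (e.g. 5/7 -> 71%,
16/21 -> 76%).

## Glutamylation tabulation (`mtkit.ptm`)

Isotypes are assigned by complete C-terminal tail suffix:
`...GEGEGAEEY` (residues 442-450, modifiable sites E443/E445/E448/E449)
for alphaTub84B/D — whose C-terminal peptides are sequence-identical
between the two genes and are pooled — and a Phe-terminal tail for
alphaTub67C (the exact 67C tail sequence is a configurable synthetic
placeholder; only its distinctness and terminal F matter). Peptides
lacking a complete tail are "other" and excluded from totals, which
operationalizes counting only C-terminal peptides containing the entire
primary sequence.

Each modification mass delta is matched to n x 129.04259 Da (the
monoisotopic glutamyl residue mass) within 0.01 Da per added Glu.
Deltas of +57.021464 Da are flagged ambiguous — that mass is identical
for glycylation and for the cysteine-alkylation artifact of sample
preparation — and are never counted as glutamylation. Unmatched deltas
raise a warning and the record is kept with its resolvable mods.

Counts are canonical; percentages (% 1E/2E/3E and total modified per
genotype x isotype) are always recomputed from counts and rounded
half-up to whole percent. The isotype PSM ratio is reported to one
decimal as the plain quotient of totals. `enumerate_isoforms` lists the
weak compositions of n added glutamates over the four sites
(C(n+3, 3) of them).

The PSM simulator draws sidechain-length categories multinomially, or
assigns them deterministically by largest-remainder apportionment
("exact-counts" mode), which reproduces a published count table exactly;
site placement follows configurable per-site weights through the seeded
RNG.

## Oocyte imaging (`mtkit.imaging`)

All measurements anchor on a user- or simulator-supplied geometry: a
cortex polyline, an anterior-to-posterior axis line (anterior endpoint
first), a sampling band width (default 50 px, the line-profile tool
convention) and a pixel size.

* **Crescent length** — the cortical intensity profile (1-px arc steps,
  3-offset band) is thresholded at background + 0.5 x (peak -
  background), background = median; the length is the longest contiguous
  supra-threshold arc (circular continuity for a closed cortex), in um.
  The half-maximum criterion is scale-free and, for a ridge that is a
  boxcar convolved with the rendering kernel, crosses exactly at the
  boxcar edges, so simulated arc lengths are recovered nearly unbiased.
* **AP profile and inner peaks** — band-averaged intensities along the
  axis; peaks need prominence >= 0.2 x (max - min) *and* >= 2% of the
  median intensity (the absolute floor keeps featureless noise profiles
  peak-free), excluding 10% margins; one peak anterior of AP 0.5 ->
  single_anterior, else single_central; two or more -> double_peak.
* **Posterior enrichment** — a deterministic surrogate for two-person
  blind scoring: true iff the mean intensity of the posterior cortical
  band (15% of the cortex arc centered on the posterior pole, dilated
  5 px) is >= 1.3 x the mean of the rest of the oocyte polygon.

The oocyte generator renders an elliptical oocyte (image 160 x 224 px at
0.65 um/px by default; physical cortex length and AP length follow from
the configured shape and are not asserted, since stage-specific absolute
dimensions vary), a crescent ridge along a configurable cortical arc,
optional inner Gaussian accumulations on the AP axis, and Gaussian
noise. It does not emulate nurse cells, follicle-cell signal,
z-attenuation or antibody background; crescent-length recovery validates
the measurement rule, not staining variability.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); nothing reads global random state, and
fixed seeds give bit-identical outputs. Test and acceptance problem
sizes — 500/200-track cohorts, a 200-movie classifier benchmark,
exhaustive 4^6 segmentation enumeration, 21- and 17-movie cohort
experiments — were chosen so the full suite runs in a few minutes while
keeping Monte-Carlo margins (3 SEM, 10% relative) meaningful.

## Known limitations

* The streaming classifier thresholds are validated on synthetic ground
  truth only; applying them to real DIC movies will require checking the
  flow-estimation settings (patch size vs vesicle density, frame gap vs
  flow speed) against the data.
* The transport module deliberately excludes HMM/Bayesian state
  inference and particle linking; it quantifies tracks it is given.
* PSM tabulation trusts the search engine's site localization; ambiguous
  +57.021464 Da mods are flagged, never resolved.
* Absolute transport metrics and crescent lengths of the original study
  are not reproducible without the raw microscopy data; the package's
  claims are calibrated against its own generators (round-trip recovery,
  oracle equivalence, determinism).
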
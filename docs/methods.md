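# Methods

This note documents the models, estimators, defaults, and numerical
conventions implemented in `bandclust`, and what the synthetic cohort does
and does not emulate.

## Signal model of the synthetic cohort

Each participant carries one ground-truth coupling graph per band (delta
0.5–4 Hz, beta 13–30 Hz by default).  A coupling graph is a set of channel
pairs, each with a phase lag drawn uniformly from [π/8, 3π/8] — bounded
away from 0 (where wPLI is blind by design) and away from π/2 only at the
upper end to keep lags generic.  Two subgroup templates exist:

- **segregated** — stochastic-block-model wiring (default 4 communities,
  p_within = 0.8, p_between = 0.04), giving locally clustered topology;
- **integrated** — uniform-random wiring at the *same expected density*
  (the same block-weighted probability formula applied uniformly), so the
  subgroups differ in topology, never in edge count on average.  At 19
  channels the default expected density is ≈ 0.20, deliberately matched to
  the downstream binarization density so that retained edges coincide with
  planted structure.

Oscillatory sources are narrowband Gaussian processes constructed in the
frequency domain (complex Gaussian spectrum restricted to the band), i.e.
ideal bandpass-filtered white noise; pure sinusoids are avoided because
they make wPLI degenerate (exactly 0 or 1 regardless of coupling
strength).  A coupled pair shares one source; the second channel receives
the copy rotated by the edge's lag.  Confounds: independent per-channel
1/f-amplitude noise (default RMS gain 0.7) and one broadband zero-lag
source common to all channels (default gain 0.5) standing in for volume
conduction.  Coupling gain defaults to 1.0 (unit source RMS per edge).
These three gains were set once so that planted edges are clearly
recoverable through the wPLI stage while the common source is strong
enough to defeat a zero-lag-sensitive estimator; they are study
conditions, not tuning knobs.

Pre and post recordings reuse the same coupling graphs with fresh noise:
the pre/post connectivity null holds by construction, matching a design in
which a brief intervention is not expected to reorganize resting-state
networks.

The behavioral table mirrors the questionnaire schema of such studies
(working-memory trial scores and times, error counts, sex, ages, ordinal
0–3 device-use codes, own-device/played-before booleans, parent
education).  Planted effects live in one `EffectConfig`: by default the
segregated subgroup gets +5.8 points on the second working-memory trial,
+3.6 on the third, and a higher proportion of girls (0.64 vs 0.20);
device-use variables never depend on the subgroup.  WM scores are
truncated normals rounded to counts; the effect magnitudes are of the
order reported for cluster contrasts in comparable cohorts (≈ 0.9 SD on
the second trial).

**What the generator does not emulate:** electrode geometry and volume
conduction through a head model, artifacts (blinks, EMG), non-stationarity
within a recording, 50/60 Hz line noise, and any realistic spatial
correlation structure of EEG beyond the planted graph.  Passing the
recovery tests therefore shows the pipeline recovers the *kind* of
structure it is designed for, not that it would behave identically on real
recordings.

## Connectivity estimation

- **Filtering.** Zero-phase FIR bandpass: Hamming-window design with
  transition bandwidth 25 % of each band edge (clamped to the headroom
  below Nyquist), tap count N ≈ 3.3/(normalized transition), forced odd.
  The symmetric kernel is applied once by FFT convolution over
  reflect-padded data and shifted by its group delay — algebraically
  zero-phase in a single pass, with the design's ≈ 53 dB stopband.  The
  pipeline applies the broadband 0.5–45 Hz filter before epoching; band
  selection happens spectrally inside the wPLI estimator.
- **Epoching.** Non-overlapping 4 s windows; floor(duration/4 s) epochs,
  trailing remainder discarded; fewer than one epoch is an error, fewer
  than two epochs is an error for wPLI (the ratio needs multiple
  cross-spectral samples).
- **wPLI.** Per epoch: Hann taper, rfft, cross-spectra S_ij at all bins
  with low ≤ f ≤ high (inclusive).  The pooled-ratio convention is used:
  numerator |Σ Im S| and denominator Σ |Im S| are summed over *all* epochs
  and in-band bins before dividing.  Pairs with zero denominator get
  wPLI = 0 (this covers identical channels and zero-variance channels,
  which are retained, zeroed, and logged rather than dropped, so matrix
  shapes never change silently).  The estimator is the standard wPLI, not
  the debiased variant.  Frequency resolution at 4 s epochs is 0.25 Hz
  (15 delta bins, 69 beta bins).

## Graph metrics

Binarization keeps the k = floor(density·n(n−1)/2) largest upper-triangle
weights (default density 0.2); ties at the cutoff break by ascending
(i, j) index, so the edge count is exact for every subject — the point of
a fixed-density threshold.  An all-zero matrix has no rankable edges and
errors.

Global efficiency, local efficiency, and clustering coefficient follow the
standard binary-graph definitions with 1/∞ = 0 for disconnected pairs and
zero contributions from nodes of degree < 2.  Assortativity is the Pearson
correlation of endpoint degrees over the directed edge list; it is
undefined (NaN-flagged) on degree-regular graphs and an error on edgeless
ones.  Node strength alone is computed on the *weighted pre-threshold*
matrix, as mean per-node weight sum — on 62-channel matrices with mean
wPLI ≈ 0.25 this lands in the 15–19 range typical of published tables,
which supports the per-node (not global-sum) reading.  All graph
algorithms are self-contained (BFS, A³ triangle counts, degree Pearson)
and are validated against networkx to 1e-10 in the tests; networkx is
never the implementation path.

## Dimensionality reduction and clustering

- **z-scoring** uses the sample SD (ddof = 1); constant columns error,
  naming the column.
- **KMO** is computed from the inverse correlation matrix
  (q_ij = −A_ij/√(A_ii A_jj)); a singular matrix falls back to the
  Moore–Penrose pseudo-inverse with a flag.  **Bartlett's sphericity** is
  χ² = −(n−1−(2p+5)/6)·ln|R| with df = p(p−1)/2.  Inside `pca2` a singular
  |R| makes sphericity undefined (NaN, logged) instead of aborting, so
  rank-deficient feature tables (n ≤ p) still yield components; calling
  `bartlett_sphericity` directly on such a table remains an error.
- **PCA** is an eigendecomposition of the feature correlation matrix over
  the joint pre+post 10-feature table (capturing shared structure rather
  than timepoint effects).  Loadings are unit-norm; each component's sign
  is fixed so its largest-magnitude loading is positive; scores are the
  (re-)standardized data projected onto the loadings, hence exactly
  zero-mean.  Exactly two components are returned along with the full
  explained-variance spectrum.  Rank < 2 is an error: a two-component
  representation of effectively one-dimensional data would be arbitrary.
- **Ward clustering** uses scipy's Ward linkage on the 2-D PC scores.
  Cluster ids are renumbered by descending size (ties: lowest member
  index), making labels invariant to participant order.  Inertia and mean
  silhouette are reported for k in a configured range (default 2–8), but k
  itself is a configuration input: automatic selection is deliberately out
  of scope because the selection criteria routinely disagree on small
  cohorts and the decision belongs to the analyst.
- **Bootstrap stability** re-clusters floor(0.8·n) participants drawn
  without replacement (subsampling, not resampling) 300 times, holding the
  PC scores fixed rather than refitting PCA per iteration — refitting
  would confound component rotation with cluster instability, and the
  quantity of interest is the stability of the *clustering solution* in
  the fixed reduced space.  Each reference cluster scores its best Jaccard
  overlap per iteration; a subsample that misses a cluster scores 0 for it
  (logged).  Category bands assign boundary values upward:
  J ≥ 0.75 stable, 0.60 ≤ J < 0.75 consistent, 0.50 ≤ J < 0.60 unstable,
  J < 0.50 dissolved.

## Statistics

- **Mann–Whitney U**: exact null when n₁n₂ ≤ 400 with no ties, otherwise
  tie-corrected normal approximation with continuity correction.
  Effect size r_rb = 2U₁/(n₁n₂) − 1 with group 1 = first cluster; the sign
  convention is documented rather than inferred from any published table.
  95 % CI by percentile bootstrap (2000 resamples, seeded; skippable).
- **Fisher's exact test**: two-sided by the probability-ordering rule;
  φ = (ad−bc)/√((a+b)(c+d)(a+c)(b+d)), reported signed.  A zero margin is
  degenerate: p = 1, φ = 0, flagged.  CI by multinomial bootstrap of the
  table.
- **Wilcoxon signed-rank** (the pre/post test): zeros dropped; for
  n ≤ 25 an exact sign-flip distribution is computed by subset-sum dynamic
  programming over doubled midranks, which stays exact under tied absolute
  differences; larger n uses the continuity-corrected normal
  approximation.  All-zero differences give p = 1, flagged.
- **Partition agreement**: RI and Hubert–Arabie ARI from the contingency
  table by the pair-counting formulas; the concordant-participant count
  matches clusters across partitions by Hungarian assignment on overlaps.
- Significance is p < 0.05 with no multiplicity correction, mirrored from
  the exploratory design this pipeline serves; every emitted table carries
  the warning.

## Problem sizes and determinism

Default simulated cohorts are 31 participants × 2 conditions × 19 channels
× 120 s at 256 Hz (62-channel montages are a config change); the packaged
test fixture is 12 participants × 12 channels × 40 s.  These sizes were
chosen so a full cohort analysis completes in seconds on one core while
keeping ≥ 30 epochs per recording for stable wPLI estimates.  Every
stochastic operation takes an explicit seed; cohort generation spawns
per-participant child seeds from one root `SeedSequence`, so identical
seeds give bit-identical cohorts and pipeline runs are reproducible from
their manifest alone.

## Known limitations

- Band-limited lag coupling is the only planted dependence; cross-band
  coupling, amplitude correlation, and nonstationary coupling are absent.
- The wPLI pooling convention (epochs and bins pooled before the ratio) is
  one defensible reading of "averaged within the band"; a per-bin wPLI
  averaged afterwards would differ slightly.
- Delta's lower edge (0.5 Hz) follows the broadband high-pass; a 0.5–3.5 Hz
  variant is a `BandSpec` away.
- Assortativity is binary-degree based; weighted assortativity is not
  implemented.
- The φ confidence interval method is bootstrap; analytic (Fisher-z style)
  intervals are not provided.
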
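# bandclust

Band-specific EEG functional-connectivity profiling: from multichannel
resting-state recordings to weighted Phase Lag Index (wPLI) networks,
graph-theoretic metrics, PCA-reduced cluster profiles with bootstrap
stability, cluster comparison statistics, and cross-band partition
agreement.

The package is aimed at analysts studying individual differences in
resting-state network organization from small pre/post-intervention EEG
cohorts (here: children recorded before and after a brief smartphone-game
session).  Because such datasets are rarely shareable, `bandclust` ships a
first-class synthetic-cohort generator with planted, band-specific,
phase-lagged coupling and two latent subgroups, so the entire pipeline is
testable against known ground truth.

## The method

**Connectivity.** Recordings are zero-phase FIR filtered to 0.5–45 Hz and
segmented into non-overlapping 4 s epochs.  For each channel pair (i, j),
connectivity per frequency band is the weighted Phase Lag Index

    wPLI_ij = | Σ_k Im(S_ij,k) | / Σ_k | Im(S_ij,k) |

with the sum over all cross-spectral samples k = (epoch × in-band DFT bin)
from Hann-tapered per-epoch spectra.  Because only Im(S) enters, zero-lag
(volume-conduction-like) coupling is suppressed by construction; wPLI ∈
[0, 1].

**Graph metrics.** Each wPLI matrix is binarized by keeping the top 20 % of
weights (density threshold 0.2, exact edge count, deterministic
tie-breaking).  Five metrics are computed: global efficiency
E_glob = ⟨1/d_ij⟩, local efficiency E_loc (mean neighbor-subgraph
efficiency), clustering coefficient C = ⟨2t_i / k_i(k_i−1)⟩, degree
assortativity r (Pearson correlation of endpoint degrees), and node
strength s = mean per-node sum of *pre-threshold* weights.

**Cluster profiles.** Per band, the 10 features (5 metrics × pre/post) are
z-scored; sampling adequacy is checked with the Kaiser–Meyer–Olkin measure
and Bartlett's test of sphericity; two principal components of the feature
correlation matrix are extracted; participants are clustered on the PC
scores with Ward's minimum-variance method (Euclidean distance).  Cluster
reliability is the per-cluster mean Jaccard overlap under bootstrap
subsampling (default 300 iterations, 80 % of participants without
replacement): J ≥ 0.75 stable, ≥ 0.60 consistent, ≥ 0.50 unstable,
otherwise dissolved.

**Statistics.** Clusters are compared with Mann–Whitney U
(rank-biserial r_rb = 2U₁/(n₁n₂) − 1, bootstrap 95 % CI) for continuous
variables and Fisher's exact test (phi coefficient) for binary ones; paired
pre/post contrasts use the exact Wilcoxon signed-rank test.  Agreement
between two partitions is summarized by the contingency table, the Rand
Index, and the Hubert–Arabie Adjusted Rand Index.  No multiple-comparison
correction is applied anywhere, and every output table says so.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (31 participants, 19 channels, 120 s at 256 Hz, 11 participants
carrying the "segregated" coupling template):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_connectivity_metrics.py
python analysis/03_cluster_profiles.py
python analysis/04_cluster_comparisons.py
python analysis/05_band_agreement.py
```

which prints, among other things:

```
delta: KMO 0.718, Bartlett chi2 365.8 (p 7.63e-52); PC1 48.4%, PC2 16.1%
  k=2 clusters sized [23, 8]; Jaccard 0.92±0.11 (stable), 0.84±0.19 (stable)
beta: KMO 0.670, Bartlett chi2 530.4 (p 3.91e-84); PC1 60.9%, PC2 16.4%
  k=2 clusters sized [21, 10]; Jaccard 0.99±0.03 (stable), 0.98±0.05 (stable)
...
           comparison  rand_index  adjusted_rand_index  n_concordant  n
        delta_vs_beta       0.768                0.526            27 31
delta_vs_ground_truth       0.819                0.635            28 31
 beta_vs_ground_truth       0.935                0.870            30 31
```

Reading: both bands pass the KMO ≥ 0.5 adequacy floor, the k = 2 Ward
solutions are bootstrap-stable, the delta and beta partitions agree well
above chance (ARI 0.53), and each band's partition recovers the planted
subgroups (ARI 0.64 and 0.87 against ground truth).  The between-cluster
tables in `results/cluster_<band>/comparisons.csv` show the planted
topology contrast (higher local efficiency and clustering in the
segregated cluster, higher global efficiency in the integrated one), and
the paired pre/post tests are consistent with the generator's built-in
pre/post null.

The same stages are available programmatically (`bandclust.run_pipeline`
with a `RunConfig`) and as a CLI (`bandclust run|simulate|connectivity|
metrics|cluster|compare|agreement`).

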
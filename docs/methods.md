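# Methods

This note documents the statistical models, conventions and numerical
choices behind `sfcoupling`, and what the synthetic-data generator does and
does not emulate.

## Structure–function coupling

For each subject, functional connectivity (FC) is the Pearson correlation
matrix of regional resting-state time series, Fisher-z transformed
(`z = arctanh(r)`); the diagonal is defined as 0. Structural connectivity
(SC) is a symmetric, nonnegative fiber-count matrix with zero diagonal.

The regional coupling statistic for region *i* is

```
SFC_i = corr( f(SC_i,E) , z_i,E ),   E = { j ≠ i : SC_ij > 0 }
```

the Pearson correlation across region *i*'s nonzero structural edges
between its (transformed) structural profile and its FC z-profile. Network
blocks pool all unordered qualifying region pairs between two networks;
the whole-brain value pools every qualifying pair.

Where published descriptions of this statistic are ambiguous, the choices
are exposed as flags rather than hard-coded:

* **Edge set** — only SC > 0 edges enter the correlation (default). A zero
  fiber count carries no profile information and would otherwise dominate
  the correlation through the sparsity pattern.
* **Count transform** — `f = log(1 + count)` by default (`log_transform`);
  fiber counts are heavy-tailed and a log transform keeps single massive
  tracts from controlling the profile. Raw counts are available.
* **FC scale** — coupling is computed on Fisher-z values; negative z edges
  are retained (no sign-thresholding step is part of the statistic).
* **`min_edges = 3`** — below three edges a Pearson correlation is
  meaningless; such regions are reported missing (NaN) and excluded from
  the test family, with a log line.
* **Fisher clip** — `fisher_z` rejects |r| ≥ 1 by default; a `clip` flag
  clips at 1 − 1e−7 for pipelines that tolerate collinear inputs.
  Degenerate inputs failing loudly is the default because a perfect
  empirical correlation almost always indicates duplicated columns.

## Group inference

Group comparison is a single OLS GLM per outcome:

```
y = β0 + β1·group(patient=1) + β2·age + β3·education + β4·FD + β5·handedness(left=1) + ε
```

reported as the t of `β1` with df = n − 6 (ANCOVA-style). A joint model is
used instead of residualize-then-test because it is unbiased when group
correlates with the covariates; the two agree on orthogonal designs, which
is tested. Covariate columns that are constant in the analyzed sample
(e.g. an all-right-handed subsample) are dropped with a log line; genuinely
collinear designs are rejected naming the columns.

Correction families are per analysis level: the whole-brain scalar (family
1), the K(K+1)/2 unique network blocks, and the testable regions.
Bonferroni is the default (`p_corr = min(1, p·m)`); BH-FDR is available.
Both uncorrected and corrected p-values are always reported.

Clinical correlations are pairwise-complete Pearson correlations between
coupling values and symptom scores, computed within the patient group by
default and reported uncorrected (an `fdr` flag adds BH q-values). Cells
with fewer than three complete pairs are missing.

## Graph topology

FC matrices are binarized by proportional thresholding of the positive z
edges over a sparsity sweep (default 0.10–0.34, step 0.01), with ties at
the cutoff broken lexicographically by (i, j) so edge sets are
reproducible. Per subject, each metric is summarized as the trapezoidal
area under its sparsity curve, avoiding a single arbitrary threshold.

Metrics follow the dominant conventions: characteristic path length
averages over connected pairs only (the excluded pair count is logged);
global and nodal efficiency give disconnected pairs an inverse distance of
0; local efficiency is the mean over nodes of the global efficiency of the
neighbor subgraph; an isolated node has degree and efficiency 0.
Small-world normalization uses `n_rand` (default 100) degree-preserving
Maslov–Sneppen rewired graphs (5 accepted swaps per edge, bounded
attempts): gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda.
Distances come from unweighted Dijkstra on sparse adjacency; clustering
from direct triangle counts — both are validated against an exhaustive
Floyd–Warshall/triangle oracle on small graphs in the test suite.

## PLS imaging transcriptomics

Genes are pre-filtered by differential stability (DS): the mean over donor
pairs of the Spearman correlation between the two donors' regional
expression profiles of the gene; the top fraction (default 50%) is kept,
with boundary ties all retained. Donor pairs with a constant profile are
skipped for that gene.

The regional group-difference t-map (unthresholded) is the PLS response.
Expression columns and the response are standardized across regions; for a
univariate response the first PLS component's weight vector is
`w ∝ X'y`, and the component score is `Xw`. Variance explained is defined
on the response — the squared Pearson correlation between the PLS1 score
and the response — because the quantity of interest is how much of the
group-difference pattern the expression component captures. The sign of
the component is fixed so the score–response correlation is positive.

Significance of the component is a permutation test that uniformly
shuffles the region assignment of the response (add-one estimator,
default 5000 permutations). Spatial autocorrelation is *not* preserved by
the default null; user-supplied region orderings (e.g. spin permutations)
are accepted wherever permutations are drawn.

Gene significance uses bootstrap z-scores: regions are resampled with
replacement (default 5000 replicates), the weight vector is recomputed per
replicate and sign-aligned to the original fit, and `z = weight /
bootstrap SE`. Two conventions matter here:

* **Sign alignment** — PLS weights are sign-indeterminate per replicate;
  without alignment the SEs would be inflated by arbitrary flips.
* **Scale** — replicates are computed on the covariance scale
  (`corr(gene, response)` per gene) rather than renormalized to unit norm.
  Renormalizing each replicate shrinks the replicate spread by roughly
  `sqrt(1 + (g/n)/‖r‖²)` (exactly √2 under a global null), which makes the
  z-scores anticonservative; on the common covariance scale the null z
  distribution is close to standard normal and BH selection controls the
  false discovery rate in the planted-gene simulations.

Selected genes (BH-FDR q < 0.05 on two-sided normal p) are split by weight
sign into PLS+ and PLS− lists. Only the first component is modeled.

## Receptor-map correlation

The unthresholded regional t-map is Spearman-correlated (average ranks for
ties) with each receptor/transporter density map. Significance is a
two-sided add-one permutation p on |rho| from uniform region-label
permutations of the t-map, shared across maps within a run, with BH-FDR
across the map family (the 19 standard PET-derived maps by default) and a
significance flag at q < 0.05. Two-sided testing is used because negative
spatial correlations are substantively interpretable.

## Synthetic data generator

The generator produces cohorts with planted truth so every stage has a
recovery test.

* **Atlas** — even region count split into L/R halves; networks assigned
  in contiguous blocks per hemisphere.
* **Structural matrices** — a random symmetric support at exactly the
  requested density (every region first seeded with three edges, the rest
  drawn uniformly), with rounded-lognormal counts (median ≈ 20 fibers,
  σ_log = 1) giving heavy tails without anatomical modeling.
* **Functional time series** — a target-covariance construction, not a
  dynamical model. On SC > 0 edges the planted matrix blends the
  standardized log-count profile with symmetric noise at per-edge weight
  `c_ij = t_i·t_j / mean(t)`, which makes the expected row-profile
  correlation exactly the target `t_i` for any target vector with nonzero
  mean; a heterogeneous zero-mean target has no symmetric realization and
  is rejected. The blend is scaled to off-diagonal amplitude
  `0.6/√n_regions` (the largest scale at which this dense random-sign
  structure stays near positive definite), projected to the nearest
  positive-definite correlation matrix by eigenvalue clipping at 1e−6 plus
  diagonal rescaling (a congruence transform, so definiteness is exact),
  and sampled as multivariate normal draws. Targets are clipped to
  |t| ≤ 0.985. Empirical coupling therefore converges to the target as the
  number of timepoints grows; at T = 10,000 the mean recovered value is
  within 0.05 of the target.
* **Cohort** — patients get `coupling_base + effect_delta` on the effect
  regions (defaults 0.45 and −0.3), controls `coupling_base` everywhere.
  Covariates (age, education, mean FD, handedness) enter additively on the
  target scale with known, centered coefficients, so covariate adjustment
  is testable; independent per-subject jitter (SD 0.08) creates
  between-subject variance. One configurable clinical score is generated
  to correlate at a set strength with the measured coupling of a named
  region within patients; all other scores are group-typical independent
  noise in symptom-scale ranges.
* **Expression** — coupled genes are `loading·z(map) + √(1−loading²)·noise`
  per donor with donor-independent noise (high DS); a configurable block of
  genes gets a structured profile redrawn per donor (near-zero DS); the
  rest are noise.
* **Receptor maps** — coupled maps are `strength·z(map)` plus matched
  noise (signed strength; the default plants negative correlations on the
  serotonergic maps), other maps independent noise.

Randomness is handled by spawning named `SeedSequence` children from the
master seed in a fixed order (covariates, structural, functional, scores),
so every artifact is a pure function of the configuration and reruns are
bit-reproducible regardless of which components are consumed.

What the generator does **not** emulate: spatial autocorrelation of
cortical maps (permutation nulls are exactly calibrated here, which real
spatially smooth maps violate), hemodynamics and temporal autocorrelation
of fMRI, realistic connectome topology (modular, geometrically embedded
networks), scanner/site effects, and missing data. Passing recovery tests
therefore demonstrates correctness of the estimators and calibration under
the stated model, not robustness to those realistic features.

## Problem sizes in tests and the acceptance script

Simulated cohorts for recovery and calibration checks use 60 regions in 6
networks at structural density 0.4 (≈ 24 structural edges per region),
40/40 subjects and 500 timepoints; calibration sweeps use 100 replicates.
PLS checks use 200 regions × 1000 genes with 50 planted genes at loading
0.8 and 500 bootstrap replicates; receptor-map checks use 19 maps over 200
regions with 1000 permutations. These sizes keep full calibration sweeps
runnable on a laptop while leaving all planted effects comfortably
detectable; every quantity scales to larger atlases unchanged.

## Known limitations

* The PLS permutation and receptor-map nulls are uniform; with spatially
  autocorrelated real maps they are anticonservative unless spin-style
  permutations are supplied.
* Bootstrap z-scores assume approximate normality of the replicate
  distribution; with very few regions (< ~30) the normal p-values on z are
  rough.
* The whole-brain and network-block coupling statistics pool heterogeneous
  edges; they are reported for completeness but are far less sensitive
  than regional coupling to focal effects (by design of the statistic, not
  a bug).
* Proportional thresholding with very weak positive connectivity can
  produce graphs sparser than requested; the achieved sparsity is logged
  and used.
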
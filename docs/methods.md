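# Methods

## Scope and data model

The package analyses a developmental time course measured on two omics
layers: metabolite peak areas (GC-MS and LC-MS) and protein spectral
counts, collected at ordered stages with a small number of biological
replicates per stage. The canonical design is 12 Eichhorn–Lorenz stages
(EL 27–38) × 3 replicates. Stages are treated as equally spaced integer
time; lags in the causality analysis are therefore in units of stages,
not days, even though the calendar spacing of E-L stages is uneven.

All tabular I/O uses a fixed dialect (UTF-8 TSV, `.` decimal). Zeros are
the only absence marker; the token `NA` is rejected on input so that
"not detected" and "not measured" cannot silently diverge. Stage order is
the design file's row order, never lexicographic — `EL37.5` must sort
between `EL37` and `EL38`.

## Quantification

**NSAF.** Per sample, `NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j)`; columns
sum to 1 exactly (verified to 1e-12 in tests). A sample with zero total
counts has no defined NSAF and is a hard error naming the sample.

**Metabolite normalization.** `value' = value / (fresh_weight × reference)`
with the reference being the internal-standard intensity (GC-MS,
dodecane) or the total ion intensity (LC-MS). The composition is
multiplicative division by the product — the conventional reading of
normalizing "to fresh weight and an internal standard"; the operator is
not otherwise constrained. Fresh-weight normalization is not applied to
NSAFs: NSAF is already a per-sample relative measure.

**Presence filter.** A feature is kept iff it has value > 0 in every
replicate of at least one stage. "Present" means strictly positive: zeros
are the dialect's only absence marker, so this is the sharpest available
reading. The rule is monotone (adding detections never removes a kept
feature) and is tested against exhaustive enumeration.

**Retention indices.** Kovats-style linear interpolation between the
bracketing alkanes: `RI = 100·(n + (rt − RT_n)/(RT_{n+1} − RT_n))`,
generalized to non-consecutive carbon numbers. No extrapolation outside
the calibrated range — an out-of-range retention time is an error, not a
guess.

**Replicate reduction.** Time-series analyses (PCA, clustering, Granger)
run on stage-averaged series (arithmetic mean of replicates); replicate
resolution is kept only for ANOVA/Duncan. Z-scoring uses the sample
standard deviation (ddof = 1); rows with zero variance are flagged and
left unstandardized rather than producing NaNs. Metabolites and proteins
are z-scored per feature before integration because peak areas and NSAFs
live on incommensurable scales; the switch is exposed
(`RunConfig.zscore`) for users who prefer raw-scale analysis.

## Stage statistics

**ANOVA.** Classical one-way decomposition over stages,
`F = (SS_between/df_b)/(SS_within/df_w)`. Degenerate layouts are flagged
rather than erroring: all-identical values report F = 0, p = 1; zero
within-stage variance with non-zero between-stage variance reports
F = ∞, p = 0.

**Duncan's multiple range test.** Critical ranges use studentized-range
quantiles at the span-wise protection level `α_p = 1 − (1−α)^(p−1)`,
computed from the distribution itself (scipy) rather than table lookup,
so any error df is supported; the harmonic mean of group sizes handles
mild imbalance. The letter display comes from the standard step-down
recursion: the full range of ordered means is tested against its
critical range; non-significant stretches are declared homogeneous and
not subdivided; maximal homogeneous stretches share a letter. Limits
behave as expected: MSE → ∞ collapses to a single letter, MSE → 0 with
distinct means gives all-distinct letters. Quantiles are cached on
(k, df_e, α) since a balanced design shares them across all features.

**PCA.** SVD of the column-centered (optionally unit-scaled) sample ×
feature matrix; scores = U·S, variance explained = squared singular
values as percentages (sums to 100 by construction). An all-constant
matrix is an error.

**Hierarchical bi-clustering.** Agglomerative trees on both axes:
correlation distance with average linkage for features, Euclidean with
average linkage for samples. Neither metric nor linkage is canonical for
this workflow, so both are arguments; the defaults reflect common
practice for expression-profile heat maps (correlation for shapes,
Euclidean for samples). The sample tree is cut into `k_groups` (default
3 — the early/middle/late grouping) and groups are renumbered in stage
order.

**K-means.** Lloyd iterations (scikit-learn, k-means++ initialization,
one init per restart) from `restarts` independent seeds; the model with
minimal total within-cluster squared Euclidean distance is returned,
with the winning restart seed recorded. Restart seeds form a
prefix-stable stream derived from the user seed, so the best distance is
non-increasing in the restart count and partial re-runs are consistent.
Empty clusters cannot arise (the backend relocates them), keeping k
fixed. Default k = 12 and 100 restarts.

**Venn counting.** A feature is "detected in group g" iff the presence
rule holds within g's stages. All 2^k − 1 regions are reported; features
detected in no group are listed separately (after the global presence
filter this set is empty by construction).

## Granger causality

For series x, y of length N and lag L, both models are fit by OLS on the
T = N − L aligned observations:

    restricted:    y_t = a₀ + Σ_{i=1..L} a_i y_{t−i}
    unrestricted:  + Σ_{i=1..L} b_i x_{t−i}
    F = ((SSR_r − SSR_u)/L) / (SSR_u/(T − 2L − 1)),  p = F(L, T−2L−1) upper tail

An intercept is always included; no trend term. Preconditions are
enforced, not patched: T − 2L − 1 ≥ 1 (so N = 12 supports lags 1–3 with
8/5/2 residual df), finite values, non-constant windows. A perfect
unrestricted fit (SSR_u relatively ≤ 1e-12) reports p = 0 with a
degeneracy flag instead of dividing by zero. The statistic is invariant
to affine rescaling of either series, so z-scoring upstream changes
nothing but conditioning. In the all-pairs scan the restricted model is
fit once per (effect, lag) — it does not depend on the cause — which
roughly halves the cost.

Each (pair, lag) is retained independently at p < α (default 0.05), both
directions tested separately, with no multiple-testing correction by
default; a Benjamini–Hochberg per-lag adjustment is available
(`fdr="bh"`). Network assembly keeps parallel edges (same pair,
different lag) as distinct attributed edges but collapses them to one
adjacency for the neighbor count, which is direction-blind distinct
adjacency; in/out degree count distinct predecessors/successors. Hub
ranking sorts by neighbor count, ties broken lexicographically by id.

## Synthetic data generator

The generator defines the study conditions that all recovery statements
refer to.

**Archetypes.** A fixed library of 16 smooth parametric unit-variance
shapes over the stage axis — mirrored linear ramps, sharp veraison
switches (up/down, mid / early / late), Gaussian stage peaks at six
centers, a mid valley, convex late-accumulating and early-decay curves,
and a skewed late hump. The first `n_archetypes` (default 12) are used;
shapes whose pairwise correlation exceeds 0.999 on the requested stage
grid are rejected as indistinguishable. At the default 12 stages all
pairwise correlations are below 0.95 (the mirrored ramps are exactly −1,
which is distinct, not degenerate).

**Features.** Feature i follows archetype i mod n_archetypes, shifted to
a positive baseline (min + 0.5). Each measurement is the profile value ×
a lognormal factor with mean 1 and coefficient of variation `noise_cv`
(default 0.15, a typical biological-replicate CV for these platforms),
then zeroed with probability `dropout_rate` (dropout after noise,
independent per cell; zeros, not missing markers, because zeros are the
dialect's absence marker). Per-feature RNG streams are spawned from the
single global seed, so adding features never perturbs existing ones.
Metabolite raw values are multiplied by each sample's fresh weight and
reference intensity, making the normalization step exactly invertible;
protein profiles are scaled to a target mean spectral count (default 25)
and rounded half-up to integers, as NSAF needs integral counts.

**Planted causality.** A link (cause, effect, lag, c) makes the effect a
convex mixture: `effect = (1−|c|)·own + c·lagged(cause)`, built from the
cause's *realized* (noisy) values replicate by replicate, with chains
propagating through realized profiles so each edge is a clean one-step
dependency. The mixture — rather than adding the lagged term on top of a
full-amplitude own shape — is deliberate: with only 12 stages the lag
regression has 2–5 residual df, and an unreduced nonlinear own component
dominates the residual of both models, capping the F-statistic well
below significance no matter how strong the injected signal. Under the
mixture, c = 0.9 reads as "90% driven by the lagged cause", the planted
direction is recovered essentially always at noise CV 0.05, and the
reverse direction stays at the false-positive floor. Archetype-level
links modify the archetype profile itself, so every member feature — and
hence the cluster centroid — inherits the dependency.

**Chain emulation.** The five-edge lag-1 cascade used in the acceptance
checks is planted along the six peak archetypes with successive centers.
This mirrors the biological picture of a developmental cascade
(sequentially shifted abundance waves) and is also the identifiable
choice: a 1-stage shift of a ramp or sigmoid correlates > 0.99 with the
original, so cause and effect clusters of such shapes would be merged by
any clustering method and the chain would be unrecoverable by
construction.

**What the generator does not emulate.** Peptide-level identification,
missingness that is intensity-dependent (dropout here is uniform),
correlated noise across features, batch effects, uneven stage spacing,
and annotation ambiguity. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under clean co-regulation
structure, not performance on real data with structured artifacts.

## Pipeline and reproducibility

Stage order: quantify → presence filter → stage averaging/integration →
ANOVA + Duncan → PCA → bi-clustering + Venn → k-means → Granger
(features, then centroids) → network assembly → exports. One seed in the
config drives both the synthetic generator and an independently derived
k-means restart stream; identical config + seed reproduces every output
file byte for byte (the manifest records a config hash over the analysis
settings, excluding the output path, plus per-stage record counts and
package versions; wall times go to the log only). Any stage failure
aborts with the stage name and offending record.

## Problem sizes in the shipped checks

The acceptance script and tests use deliberately moderate sizes chosen
to exercise every code path at the study's design scale (12 × 3): oracle
agreement on 200 random pairs × 3 lags; null calibration with 5000
replicates per lag; planted-edge recovery over 200 seeds; the cluster
cascade over 100 seeds of a 144-feature dataset with 100-restart
k-means; the full pipeline demonstration on 180 features. Feature counts
are an order of magnitude below the original study's ~950 candidates;
all statistics per feature/pair are identical, only the number of pairs
scales.

## Known limitations

- Bivariate Granger only: no conditional/multivariate variant, so common
  drivers produce indirect edges (visible as dense networks on smooth
  synthetic data).
- With N = 12 and L = 3 the denominator df is 2; p-values at the largest
  lag are correspondingly coarse.
- Duncan letters use the harmonic-mean group size; heavily unbalanced
  designs deserve a proper multiple-comparison procedure instead.
- The decision of whether to z-score before clustering/PCA materially
  changes results on real data; the default (z-score on) is documented,
  not canonical.
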
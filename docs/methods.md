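# Methods

This note documents the statistical model, the synthetic-cohort generator,
the search algorithm and the numerical choices behind `lrrksig`, in the
order the pipeline runs.

## Synthetic cohort

The generator emulates a multi-centre LRRK2 PBMC cohort profiled by DIA
mass spectrometry at the level of its *processed* tables; no spectra,
retention times or library search are simulated.

**Sample sheet.** Six groups with default post-quality-control sizes
G2019S L2PD 32, G2019S L2NMC 22, R1441G L2PD 13, R1441G L2NMC 7, iPD 39,
controls 42 (155 samples); per-group recruiting-centre proportions, age
distributions, sex ratios and baseline UPDRS-III/MoCA scores follow the
cohort demographics of the emulated study design.  Each artifact (sheet,
proteome, phospho report, missingness, scores) draws from its own RNG
stream derived from the master seed, so stages are individually
reproducible.

**Intensities.** Feature baselines are log-normal on the log2 scale
(mean 20, sd 2 — a typical DIA dynamic range); within-feature noise sd is
uniform on (0.4, 0.8).  Planted group effects are additive log2 shifts.

**Planted markers.** The default truth profile plants two marker classes:
carrier-wide effects nearly equal in manifesting and non-manifesting
carriers (the headline phospho-site at +0.95 in both carrier groups, so the
pooled-carriers contrast sees exactly 0.95; two proteins at ~−1.0/−1.3),
and disease-restricted effects that separate manifesting from
non-manifesting carriers (two proteins and one phospho-site, near-zero in
non-manifesting carriers).  Planted markers are generated as *reliably
quantified* features: baseline abundance drawn above the low-intensity
dropout zone and the low end of the noise-sd range.  This mirrors how such
a study reports markers — candidates that fail quality-control coverage are
discarded — and makes the planted signal-to-noise a defined study condition
rather than a per-seed accident.  The resulting three-class problem
(manifesting carriers / non-manifesting carriers / controls) is nearly
separable given the six planted features, which is the regime a
high-accuracy published signature implies.  Consequences for
interpretation: passing recovery tests show the pipeline finds a strong,
mostly non-redundant signal among hundreds of null features; they do not
show it would recover weak or heavily redundant signals, and they cannot
certify behaviour on real data with batch structure, which the generator
does not model.

**Missingness.** Two channels: missing-at-random at rate 0.05 and a
not-at-random channel whose per-cell dropout probability is a logistic
function decreasing in log2 intensity (midpoint at the 10th intensity
percentile, slope 2 per log2 unit; slope ≤ 0 disables it).  Defaults are
deliberately low: in the emulated design a 30 % row-missingness cutoff
retains over 99 % of the rows a 70 % cutoff retains, i.e. the processed
tables are mostly complete.  The expected overall missing fraction is the
mean per-cell removal probability; realized fractions concentrate within
±2 % of it for tables of ≥ 200×50 (binomial concentration).

**Severity scores.** UPDRS-III is built from a unit-variance latent:
a patient-status component (weight 0.45 before rescaling) plus weighted
standardized planted features plus Gaussian noise.  Weights solve a linear
system in the empirical feature covariance so the in-sample Pearson
correlation with each linked feature equals 2·sin(πρ_s/6) — the Gaussian
equivalent of the target Spearman ρ_s.  The latent maps monotonically to a
non-negative integer scale (monotone maps preserve Spearman; rounding and
the floor at zero attenuate it mildly).  Realized ρ for a 0.8 target is
typically 0.75–0.83 over the 155-sample cohort.

## Preprocessing

Proteome: peptide filter (≥ 2 peptides) → row filter (drop rows with ≥ 70 %
missing) → KNN imputation → log2 → quantile normalization (on by default;
config `normalize_proteome`).  Phospho: site collapse → column blank filter
(drop samples with **strictly more than** 70 % blanks, satisfying the
imputer's < 80 % requirement) → row filter (≥ 30 %) → KNN imputation → log2
→ quantile normalization.  Features use the ≥ rule and samples the > rule
deliberately — the two filters are worded differently in the workflow this
reproduces.

**Site collapse.** Records with localization confidence ≤ 0.75 are
discarded (strictly-greater rule); survivors group by (protein, residue,
position); per site and sample the default aggregate is the maximum across
contributing peptides, which avoids double-counting shared peptides (sum
and mean are available).  Output ids are `PROTEIN_<residue><position>`,
e.g. `RAB12_S106`.

**KNN imputation.** Neighbours are features (rows), the standard choice
for omics matrices: a missing cell is filled with the inverse-distance-
weighted mean of the k = 10 nearest feature rows, using Euclidean distance
over mutually observed samples rescaled by the overlap count
(scikit-learn's `nan_euclidean`; `KNNImputer` provides the computation).
A row with zero observed overlap with every other row raises an error
naming the row rather than silently receiving a column mean.  Observed
values are never altered.

**Quantile normalization.** Each column's order statistics are replaced by
the across-column mean of order statistics; ties within a column receive
the mean of the target values their positions span, so the map is monotone
and well defined.  Afterwards all columns share one empirical distribution
(sorted columns agree to < 1e-9).

## Moderated differential testing

For a two-sided contrast (pooled sides are relabelled to one pseudo-group
each), the per-feature pooled residual variance s²_g with d_g = n_a+n_b−2
df is shrunk toward a prior: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g).  The
hyperparameters come from moment-matching log s²_g under the scaled-F
model, with the trigamma equation inverted by Newton iteration; when the
observed dispersion of log s²_g does not exceed its sampling component,
d₀ = ∞ and s₀² is the arithmetic mean of the sample variances (full
pooling).  t = log2FC / (s̃_g √(1/n_a + 1/n_b)) with d₀ + d_g df, capped at
the pooled df across all features.  Setting d₀ = 0 reduces exactly to the
ordinary pooled two-sample t — a tested identity — and the whole procedure
is cross-checked against R limma's `eBayes` to 1e-6 relative tolerance in
the test suite.

BH adjustment is the step-up adj_i = min_{j≥i} (m·p_(j)/j), applied within
each contrast separately.  Significance uses strict inequalities
(|log2FC| > 0.6, adjusted P < 0.05); `adjp_inclusive` admits the boundary
for users who want the looser published-style call.  The ANOVA screen is a
vectorized fixed-effects one-way F; features constant across all samples
get F = 0, p = 1 by convention, and zero within-group variance with
non-zero between-group variance maps to p = 0.

## Signature search

**Reward.** Cross-validated balanced accuracy of an SVM (default: linear
kernel, C = 1) on the candidate subset.  Folds are stratified 5-fold,
fixed per seed so subset scores are paired, and averaged over three
repeated partitions — a variance-reduction step that makes ~0.01-level
score differences meaningful.  SMOTE (own implementation: each synthetic
point is x + u·(neighbour − x), u ~ U(0,1), neighbour among the k = 5
nearest same-class points) runs on the training portion of each fold only;
synthetic rows carry provenance flags and never reach a test fold.
Rewards are memoized by frozen subset, which both makes the 10×-candidates
budget tractable and the search fully deterministic given (data, config,
seed).

**Funnel.** One-way ANOVA keeps features at p < 0.05 (raw by default); the
15 smallest-p candidates are retained when more pass (a runtime bound on
the combinatorial stage); backwards recursive feature elimination drops the
lowest-importance 10 % per iteration (importance = mean |coefficient| for
linear models, impurity/permutation importance otherwise, lexicographic
tie-break) and returns the best-scoring set seen.

**MCTS.** For every candidate as a first feature, the subset grows one
feature per round.  A round spends 10 × n_candidates simulations of a
UCB1 tree (exploration constant √2) whose actions are add-a-feature or an
explicit STOP; lookahead depth is fixed at five.  The tree policy uses
mean-value UCB1; the round's decision uses max-backup: the appended feature
is the root child whose subtree achieved the best reward.  Growth halts
when STOP wins, when no explored extension within the lookahead improves on
the current subset by ≥ 1e-3, or when the chosen feature's own one-step
gain is < 1e-3 — the lookahead finds promising features, the one-step gate
keeps subsets minimal when deeper "improvements" are noise.  Each start's
terminal subset is recorded; those scoring > 0.90 qualify.

**Refinement.** Features are ranked by frequency across qualifying
subsets (ties broken by single-feature score, then name); the top five
(`refine_init_size`, default = depth) seed a second growth, and the
signature is the best subset this refinement produces — never below the
initial set's own score.  With no qualifying subsets the first search's
best terminal is kept, with a log notice.

**Reported score.** The headline balanced accuracy is the *held-out*
out-of-fold evaluation of the final subset (with per-class one-vs-rest
ROC AUC from out-of-fold decision scores and a 2-component PCA of the
standardized signature features).  The search's own maximized CV score is
kept separately (`search_score`): because it is a maximum over many noisy
evaluations it is optimistic.  Both numbers still inherit the optimism of
screening features on the full data set (as the reproduced workflow does);
under label permutation this inflates the null score above 1/k by an
amount that decays with cohort size — about +0.08 at 210 samples with 30
null features.  Users estimating generalization error on real data should
wrap the *entire* funnel in an outer validation split.

## Clinical correlation

Spearman ρ (average ranks, tie-corrected; two-sided p via the
t-approximation on n−2 df, as `scipy.stats.spearmanr` computes) between
each differential feature and UPDRS-III over the selected groups, BH
adjustment across the tested set, pass at |ρ| > 0.5 and adjusted P < 0.05
(strict; `rho_inclusive_margin` loosens the ρ rule for reproducing looser
published calls).  Constant features are skipped with a log entry rather
than propagating undefined correlations.

## Numerical and degenerate-input choices

- Strict inequalities at every published threshold; boundary-inclusive
  variants are config flags, never defaults.
- SVC iteration count capped at 1e5: degenerate oversampled subsets can
  otherwise stall libsvm indefinitely without improving the solution.
- Zero standard error with zero effect → t = 0, p = 1.
- Tie-breaks are deterministic everywhere (declaration order in the model
  grid, lexicographic ids in result files and eliminations, smallest-then-
  lexicographic among equal-scoring subsets).
- Result files serialize floats at six significant digits and sort by
  (adjusted p, feature id), so reruns are byte-identical.

## Problem sizes used in tests

The default test cohort is 155 samples with 800 proteins and 1500
phospho-sites for differential and correlation recovery; the signature
recovery search runs on a 300-feature matrix (the six planted informative
features plus a deterministic slice of the rest), reflecting the size of a
post-screen candidate pool.  The chance-floor check uses a 210-sample null
cohort.  A `paper-scale` profile (3815 proteins / 10288 sites) is available
in the pipeline for full-size runs.

## Known limitations

- No batch-effect modelling or correction; the generator draws all centres
  from one distribution, and the pipeline applies none (beyond what
  quantile normalization absorbs).
- The generator starts at quantified intensities; peptide-to-protein
  roll-up, retention-time alignment and match-between-runs are out of
  scope.
- Gene-name disambiguation against remote databases is not performed;
  feature ids are treated as opaque symbols (an optional local two-column
  mapping table can be applied upstream).
- The selection-bias caveat above: all reported scores share the data used
  for screening, as in the reproduced design.
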
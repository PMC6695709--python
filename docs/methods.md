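# Methods

## Problem setting

Ensemble docking scores every compound against n conformationally distinct
structures of one target, giving a compounds × structures matrix of docking
scores (dimensionless, lower = better). For retrospective evaluation each
compound carries a binary activity label (active vs inactive/decoy). The
package answers two questions: *how should the n per-structure scores be
fused into one consensus score*, and *does the choice of fusion rule matter
statistically*.

## Fusion rules and orientation

The seven rules are MIN, MAX, arithmetic mean (SUM), geometric mean (GEOM),
harmonic mean (HARM), median (MED) and Euclidean norm (EUC). Docking scores
are negative, which makes two of the textbook formulas ill-defined:

* **GEOM / HARM on negative scores** are computed on magnitudes with the
  common sign restored: GEOM = sign·(∏|DSᵢ|)^{1/n}, HARM = sign·n/Σ|DSᵢ|⁻¹.
  The textbook product form would be sign-ambiguous for even n and the
  harmonic form unstable around zero; both rules therefore require strictly
  nonzero, uniform-sign inputs and raise otherwise.
* **EUC orientation**: for all-negative scores a *larger* Euclidean norm
  means more-negative, i.e. better, scores, so the EUC column is negated to
  the shared lower-is-better orientation before any ranking. Without this
  flip its ROC curve would be inverted. Positive-valued "higher = better"
  inputs are not supported anywhere in the pipeline; the input convention is
  part of the file format contract.

For all-negative inputs the mean-type rules obey
MIN ≤ SUM ≤ GEOM ≤ HARM ≤ MAX element-wise (the AM–GM–HM inequality on
magnitudes with signs flipped); the test suite asserts this on random rows.

Missing scores (a compound that failed to dock against one structure) are a
hard error: every rule's formula assumes a complete row, and silently
aggregating over available values would make rules incomparable across
compounds.

## Enrichment metrics

All three metrics are rank-based and consume the canonical lower-is-better
scores (negated internally where a library expects higher = more active).

* **AUC** is the Mann–Whitney probability that a random active outranks a
  random inactive, ties counted half (midrank convention); computed via
  scikit-learn's `roc_auc_score`, which the tests check against exhaustive
  pair counting.
* **AP** is the step-integrated area under the precision-recall curve
  (`average_precision_score`); tied scores are grouped at one threshold,
  the standard deterministic convention.
* **BEDROC(α)** uses the Truchon–Bayly closed form: with fractional (average)
  ranks rᵢ of the actives, RIE = Σᵢ e^{−αrᵢ/N} / [ (n/N)(1−e^{−α})/(e^{α/N}−1) ]
  and BEDROC = RIE·Ra·sinh(α/2)/(cosh(α/2)−cosh(α/2−αRa)) + 1/(1−e^{α(1−Ra)}).
  This closed form equals the direct (RIE−RIE_min)/(RIE_max−RIE_min)
  rescaling with actives packed at the worst/best ranks to machine precision;
  the tests verify both that identity and agreement with rdkit's
  implementation. Default α = 20 — roughly 80% of the weight on the top 8%
  of the ranking — the field's usual early-recognition setting.

## Sum of ranking differences

SRD scores a method column by the Manhattan distance between its rank vector
and a reference rank vector, both rank-transformed with rank 1 = best and
average ranks on ties. Normalization divides by the maximum attainable
distance srd_max(n) = n²/2 (even n) or (n²−1)/2 (odd n) and multiplies by
100, so 0 = identical to the reference and 100 = reversed.

**Reference (minimax).** Each structure column is rank transformed across
compounds first — this removes per-structure score offsets — and the
reference value of an active is the minimum (best) of its per-structure
ranks, that of an inactive the maximum (worst). This is the hypothetical
ideal consensus that treats every active as favorably and every inactive as
unfavorably as the ensemble allows.

**Standardization.** Method columns are z-scored before the analysis because
the fusion rules produce values in different ranges. Since SRD only sees
ranks, any strictly monotone transform — z-scoring included — provably leaves
SRD unchanged; the step is kept for pipeline parity and the invariance is
asserted explicitly in the tests. Single-structure columns, when included,
enter after their within-subset rank transform and the same z-scoring.

**Random-ranking null.** The null is the distribution of SRD between a
uniformly random permutation and a fixed reference. It is computed exactly by
full enumeration for n ≤ 8 and by a bitmask dynamic program with exact
integer counts for 9 ≤ n ≤ 12; larger n uses seeded Monte Carlo (default
10⁵ permutation draws, batched). A method is called better than random when
its normalized SRD falls below the null's 5th percentile (smallest value
whose cumulative probability reaches 5%). Ties in real data make SRD
non-integer; the null is computed on tie-free permutations, the standard
convention.

**Cross-validation.** Compounds are split into k = 7 disjoint random folds,
stratified by activity label so every fold and every complement contains
actives (with fewer actives than folds a warning is issued and stratification
is best-effort). Each fold's SRD is recomputed from scratch on the *retained*
(k−1)/k subset — reference rebuilt, columns re-ranked, normalized by the
subset's srd_max — yielding k values per method. Recomputing on the retained
subset rather than the held-out 1/k keeps per-fold n large and stable; the
enrichment metrics use the same folds and the same retained-subset
convention by default, with a `held_out` flag on the metric side switching
to the 1/k subset.

## Statistical comparison

Per metric (AUC, AP, BEDROC, normalized SRD), a one-way ANOVA with the
fusion rule as the single factor runs over the per-fold values, followed by
Tukey HSD on the same cells (statsmodels, studentized-range distribution,
family-wise α = 0.05). If every rule's per-fold values are constant the F
statistic is undefined; the result is flagged degenerate rather than raised,
since this legitimately occurs on perfectly separable toy data. Single-
structure score columns can be pooled in as extra factor levels via
`include_single_structures`; the default compares only the seven rules.
The bubble table reduces the metric table to one row per rule (fold means of
AUC, AP, SRD, BEDROC — the four axes of the summary plot), optionally
dropping rules that sit far from the cluster of interest.

## Synthetic data generator

`DSᵢⱼ = bᵢ + δⱼ + eᵢⱼ`, with per-compound latent quality
bᵢ ~ N(μ_class, τ²) (μ_act = −9, μ_inact = −7 by default, in docking-score
units), fixed per-structure offsets δⱼ, and i.i.d. noise eᵢⱼ ~ N(0, σ²).
Defaults τ = σ = 1 give a single-structure AUC of Φ(2/√4) ≈ 0.84 and an
inter-structure correlation of τ²/(τ²+σ²) = 0.5, in the range typical of
published retrospective screens. Two closed forms calibrate the generator:

* single-structure AUC = Φ((μ_inact−μ_act)/√(2(τ²+σ²)));
* SUM-fusion AUC = Φ((μ_inact−μ_act)/√(2(τ²+σ²/n))) — averaging shrinks
  only the independent noise, which is exactly the mechanism by which fusion
  helps and why the benefit vanishes at σ = 0.

Presets `jak1`, `jak2`, `5ht6`, `alr2`, `er` fix the compound and structure
counts of five published case studies (e.g. jak2: 82 actives, 1437
inactives, 5 structures). Each preset's offsets δ are drawn once from
N(0, 1) under a preset-specific fixed sub-seed, so they are nontrivial (the
rank transform in the reference construction has work to do) yet stable
across simulation seeds.

Scores are truncated at a ceiling of −0.01: the fusion rules require the
strictly-negative score convention, and the unbounded Gaussian would emit a
positive cell in the far inactive tail roughly once per few datasets at the
default parameters. The truncation touches a ~3·10⁻⁴ fraction of cells and
is immaterial to the rank-based analysis.

**What the generator does not emulate.** Real docking scores are heavy-
tailed, heteroscedastic across chemotypes, and — importantly — *asymmetric*:
an active's advantage is typically expressed only in binding-competent
conformations, and failed poses corrupt the worst scores more than the best.
The symmetric Gaussian model has none of this; in particular, negating the
noise and reflecting the offsets maps MIN onto MAX, so the two extreme rules
perform identically in distribution and their empirical ordering on any one
simulated dataset is a coin flip decided by the seed. Passing tests on this
generator therefore demonstrate the pipeline's correctness and the
noise-averaging advantage of the mean-type rules, but cannot by themselves
establish real-data claims that hinge on score asymmetry (such as MAX being
reliably the worst rule). Heavy-tailed or skewed variants are natural config
extensions, deliberately not defaults.

## Numerical and design choices

* Rank ties: average (midrank) everywhere — deterministic and standard.
* Exact-null boundaries (enumeration ≤ 8, DP ≤ 12) keep exact mode under a
  second; the DP uses Python integers, so counts are exact up to 12!.
* Monte-Carlo nulls batch permutation draws to bound memory at ~20M cells.
* Fold assignment deals shuffled class members round-robin, so fold sizes
  differ by at most one per class.
* z-scoring a constant column degenerates to centering (guarded division).
* Problem sizes: the shipped tests and the acceptance script run the full
  JAK2-size preset (1519 compounds) with a 10⁵-draw Monte-Carlo null,
  sevenfold CV and 1000-replicate ANOVA calibration — a few tens of seconds
  end to end; all smaller oracles (enumeration, pair counting) are
  instantaneous.

## Known limitations

* Only complete score matrices; no missing-value mode.
* No enrichment factor at fixed %, pROC/logAUC, or learned/weighted
  consensus variants.
* The SRD method-pair comparison is limited to exporting per-fold values;
  no Wilcoxon machinery on top of them.
* The generator's symmetry limitation described above.
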
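# Methods

`oxsar` implements a complete structure–activity analysis for an
oxidative-stress reporter assay: hit calling from plate-based
fluorescence readouts, QSAR classification with conformal applicability
domains, consensus modeling, and a budgeted prospective compound
selection over a clustered reference chemical space. Because the
original assay measurements and commercial screening collections are
not distributable, the pipeline runs on synthetic data whose generator
is itself a first-class, tested component; this note records the models,
the defaults, and the reasoning behind the design choices.

## Synthetic study conditions

**Library.** The generator emits drug-like molecules from a scaffold +
substituent grammar (12 benign aromatic/heteroaromatic scaffolds, ~20
substituents), validated with RDKit. A compound is "alerted" with a
calibrated probability by being built on or decorated with one of six
redox-alert motifs — para-quinone, catechol, hydroquinone,
nitroaromatic, Michael acceptor, aromatic aldehyde — each with its own
activity log-odds (quinoid motifs strongest). Latent activity is
Bernoulli: P(active | alert) = 0.85 against a 0.03 baseline, and the
final flag is flipped with `label_noise` (default 0.05). The alert rate
is solved so that the marginal activity rate equals the requested
`active_fraction` (default 316/2191 ≈ 0.144, a 2,191-compound library
with roughly 14% actives). Defaults emulate the screening-library
composition the analysis assumes; they are fixed, not tuned.

**Plates.** Wells follow a log-normal intensity model,
`log I ~ N(6.0 + plate_effect, 0.25²)` with a per-plate random effect
(sd 0.10) — the plate effect is what makes per-plate robust
normalization necessary. Actives are shifted multiplicatively
(`effect_size`, default 3.0 ≈ 12 plate MADs). Three replicate plates of
96 wells; 2% of wells are artifacts, either sparse (< 100 cells) or
grossly saturated (15–30× intensity, i.e. ~80–170 MADs). Ground-truth
artifact labels are returned for QC testing. The generator does not
model the co-treatment baseline explicitly, only its net effect on the
dynamic range, and simulates single-concentration exposure (no
dose–response).

**Screening collection.** Relative to a training library, the screening
generator emits three strata: single-edit analogs (halogen swaps —
invisible to feature-class fingerprints — re-issues, and aromatic
methylations; enriched in max-Tc ≥ 0.7), disjoint aliphatic/alicyclic
chemotypes (enriched in max-Tc ≤ 0.3), and hybrid structures populating
the intermediate 0.3–0.7 band so the exclusion branch of the similarity
classifier is exercised (default 10%).

**What the generator does not emulate.** Real chemical space is far
more diverse than a finite grammar; real activity mechanisms are not
reducible to six substructures plus independent label noise; assay
artifacts can be correlated within plates. Passing tests therefore
demonstrate the pipeline's statistical machinery (calibration,
thresholds, bookkeeping, reproducibility) under known ground truth — not
predictive performance on real chemistry.

## Activity calling

Wells with fewer than 100 cells are discarded. The artifact-intensity
filter removes wells whose intensity strictly exceeds
`plate median + mad_mult × raw MAD`. Two multipliers coexist
deliberately: `qc_filter` defaults to the conventional `mad_mult = 3`,
but the integrated `call_activity_table` uses `mad_mult = 25`. The
activity rule (median modified Z-score strictly above 1.96) places hits
at > 2.91 raw MADs, and genuine reporter responses extend to tens of
robust SDs, so an artifact cut at 3 MADs on the hit-calling statistic
would silently delete every strong hit; 25 MADs sits above the
biological dynamic range yet far below simulated artifacts. The filter
is one-sided high — its purpose is artifact removal, and a low-side cut
would have no target in this assay.

Modified Z-scores are computed per plate as `(x − median)/(k·MAD)` with
the raw (unscaled) MAD and k = 1.4826 exactly as conventionally printed;
the score is affine-invariant. The per-compound response is the median
Z across replicate plates; `active ⇔ median Z > 1.96` (strict).
Compounds whose wells all fail QC are excluded as not evaluable rather
than imputed. Plates with fewer than two wells skip the intensity QC
(MAD undefined); a constant plate (MAD = 0) raises a degenerate-plate
error rather than returning infinities.

## Representation

Structures are standardized before anything else: charges neutralized
where chemically valid, recognized counterions and inorganic salt
partners stripped, and inputs rejected as inorganic (no carbon-bearing
component), organometallic (metal–carbon bond) or mixtures (≥ 2 non-salt
organic components). Standardization is idempotent. The counterion
dictionary is a fixed list of common salt formers; it is configuration,
not chemistry, and can be extended.

Two circular fingerprints serve different roles: feature-class
(pharmacophoric atom typing) radius 2 on 1024 bits for the reference
chemical space and similarity classes, and feature-class radius 3 on
2048 bits for modeling and nearest-neighbour diagnostics. Feature-class
typing approximates functional-class fingerprints from proprietary
software; bitwise equality with any particular implementation is not
assumed anywhere. Tanimoto similarity is |a∧b|/|a∨b| with the empty-set
convention Tc(∅,∅) = 1; bulk similarity uses an exact-integer matrix
product with the final division in float64 so boundary ratios (7/10 vs
0.7) compare exactly.

The physicochemical descriptor set is ~29 open 2D descriptors (MW,
Crippen log P and MR, TPSA, H-bond counts, rotatable bonds, ring
counts, fraction Csp³, heteroatom counts, topological indices, partial
charge extremes, ...). No 3D descriptors are computed. Descriptor
matrices are pruned by constant and semi-constant columns (modal
frequency ≥ 95%) and by pairwise |Pearson r| strictly above 0.90,
keeping the lower-index column for determinism. Log P stratification
uses four bins, (−∞,0], (0,2.5], (2.5,5], (5,∞); the printed-table
overlap at exactly 5 is resolved by assigning 5.0 to the third bin.

## Splitting and balancing

Compounds are clustered by affinity propagation on the Tanimoto matrix
(damping 0.9, preference = median similarity — standard defaults, since
none are prescribed). Duplicate structures create exactly tied
similarities on which AP's message passing can oscillate forever, so a
seeded symmetric jitter of ±1e-6 (far below any meaningful Tanimoto
difference) breaks ties deterministically; on non-convergence the
damping is raised stepwise to 0.99 before erroring.

The 70/30 split is proportionate stratified sampling by structural
cluster: floor(0.7·size) per cluster plus largest-remainder top-up to
the global target, singleton clusters wholly to train. Stratification
error is at most one compound per cluster. A label-proportionate
variant is deliberately not the default: the strata are the structural
clusters.

Balanced undersampling deletes majority-class (inactive) compounds
until classes are even, with deletions apportioned across k-means
structural clusters of the majority class (largest-remainder quotas) so
every chemotype keeps representatives. The output is exactly
2 × minority-count rows and a subset of the input.

## Model zoo and conformal layer

The roster covers random forest (500 trees), balanced random forest
(class-balanced per-tree bootstraps of size 2×minority), RBF SVM,
naive Bayes (Bernoulli on fingerprints, Gaussian on descriptors), kNN
(k = 1 and 3, Jaccard distance on fingerprints), PLS regression on 0/1
labels thresholded at 0.5, logistic regression, gradient-boosted trees,
a single decision tree, and a randomized-descriptor baseline that
permutes descriptor rows against the labels before fitting — its
held-out MCC is the empirical floor any real model must clear.
Hyperparameters are fixed in the registry; there is no search, because
the analysis compares a panel under common conditions rather than
optimizing any single member.

The conformal wrapper is inductive and Mondrian (label-conditional):
30% of the training data, class-stratified, is held out for
calibration; nonconformity is 1 − P(candidate class) from the base
learner (the standard inductive choice); the p-value of a test item for
class c is `(#{α_i ≥ α} + 1)/(n_c + 1)` over class-c calibration
scores. A prediction set at significance ε contains every class with
p > ε; singleton sets define the applicability domain. Under
exchangeability the per-class error of these sets is at most ε — this
is the module's core guarantee and is verified empirically at ε = 0.25
and 0.30 (see Benchmarks).

Consensus rules: a quorum vote (e.g. 5-of-6) returns a label only when
reached, otherwise "suspicious"; out-of-AD members abstain and the
quorum refers to submitted votes. The simple majority resolves ties to
"active" — hazard-averse, because in a toxicity screen a false alarm is
cheaper than a missed inducer. Probability ensembles take the mean or
median of member probabilities with a 0.5 threshold. The pipeline's
consensus model is in-AD when at least half its members are.

## Evaluation

Metrics (SN, SP, ACC, BACC, MCC) are computed over in-AD compounds
only, with AD coverage reported alongside — a conformal model is neither
rewarded nor punished for abstentions. MCC uses the zero-denominator
convention (→ 0), which keeps one-class strata defined; BACC is NA when
a truth class is absent. Reported tables round to two decimals;
internals keep full precision. Stratified evaluation aggregates
mean ± sd across models per chemical-space cluster and per log P bin,
together with in-AD active/inactive counts. The misprediction census
counts erroneous model predictions per compound and profiles the worst
offenders by their five nearest training neighbours (descending Tc,
ties by id) with the neighbours' response Z-scores.

Model selection for prospective prediction disregards any model with
sensitivity or specificity below 0.50, ranks survivors by MCC and caps
the panel at 11; if fewer than three survive, the top-MCC models are
taken so a consensus remains possible.

## Prospective selection

The reference space is PCA (2 components) on the unit-variance-scaled
fingerprint matrix (constant bits dropped) followed by k-means with
k = 6, k-means++ initialization and the best of 100 restarts by inertia
("100 seeds" is read as 100 restarts). Cluster numbering is made stable
by ordering centroids by (PC1, PC2). Projection assigns the nearest
centroid, ties to the lowest index. The reference collection is a
synthetic stand-in with configurable size; nothing downstream depends
on its provenance.

Screening compounds are classified by max Tanimoto to the training set:
similar (≥ 0.7), dissimilar (≤ 0.3), excluded otherwise. The
dissimilar class is subsampled uniformly to 20,000. Candidates must
pass per-category concordance and AD-inclusion thresholds —
similar-active 70%/70%, dissimilar-active 80%/80%, similar-inactive
90%/90%, dissimilar-inactive 100%/100% — reflecting the higher prior
odds of inactivity; concordance is over all panel models and the AD
fraction is a separate condition. Survivors are grouped by similarity ×
predicted activity × cluster (≤ 24 groups); groups under 25 members are
taken whole, larger ones are k-means-split into 5 subclusters, each
contributing its 5 members nearest the subcentroid (deterministic;
undersized subclusters contribute all members). Compounds failing
standardization or descriptor computation are dropped with logging.

The selected set is then "tested" against the generator's latent-
activity oracle — a SMARTS-based re-derivation of the planted mechanism
that works for any structure, including screening compounds never seen
by the library generator — and scored overall, per cluster and per
log P bin.

## Benchmarks and problem sizes

The repeatable benchmarks fix the problem sizes the package uses for
its own verification: conformal validity on 2,000-compound libraries
over 20 independent repetitions (fresh library per repetition, so the
pooled binomial Monte-Carlo σ is exact); signal-vs-null separation on a
2,191-compound library with a canonical 70/30 split for the real model
and 20 resplits for the randomized baseline; a 20,000-compound
selection audit that re-verifies every selected compound against its
category thresholds and checks bit-identical reruns. The end-to-end
demo workflow defaults to the same 2,191-compound scale and completes
in minutes on one CPU.

## Numerical and reproducibility notes

- Every stochastic stage takes an explicit seed; the workflow derives
  per-stage seeds from one global seed and records SHA-256 hashes of
  every artifact in a manifest, so reruns are verifiably identical.
- Nearest-neighbour and centroid ties resolve to the lowest index/id.
- The randomized baseline's holdout MCC on ~660 test compounds has a
  null σ of ≈ 0.04; across 20 splits its |MCC| occasionally grazes 0.1
  under some seeds — expected fluctuation, not signal.
- Known limitations: the alert grammar gives models an unusually clean
  learnable signal (real MCCs will be lower than synthetic ones);
  feature-class fingerprints make halogen-swap analogs exact duplicates
  (intended, to enrich the similar class); the AP clustering step is
  O(n²) memory and is the practical bound on library size (~10⁴).
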
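# oxsar — oxidative-stress SAR pipeline

`oxsar` is an end-to-end structure–activity analysis for cell-based
oxidative-stress reporter screens, written for computational
toxicologists and cheminformaticians who want every step — hit calling,
QSAR modeling, applicability domains, consensus, and prospective
compound selection — reproducible from one seed.

The pipeline covers:

1. **Activity calling** from plate-based GFP-intensity readouts. Wells
   are QC-filtered (sparse wells, artifact intensities), intensities are
   converted to per-plate *modified Z-scores*
   `z = (x − median) / (1.4826 · MAD)`, and a compound is **active** iff
   the median z across replicate plates exceeds 1.96.
2. **Representation**: SMILES standardization (neutralize, desalt,
   reject inorganics/organometallics/mixtures), feature-class circular
   fingerprints (radius 2/1024 bits for chemical space, radius 3/2048
   for modeling), ~29 open 2D physicochemical descriptors with
   constant/correlation pruning, Crippen log P.
3. **Cluster-aware splitting**: affinity-propagation clustering on
   Tanimoto similarity, proportionate stratified 70/30 train/test
   sampling, k-means-guided balanced undersampling, nearest-neighbour
   concordance diagnostics.
4. **Model zoo**: RF, balanced RF, SVM, naive Bayes, kNN (Tanimoto),
   PLS, logistic regression, gradient-boosted trees, decision tree, and
   a randomized-descriptor baseline — plus inductive **Mondrian
   conformal** wrappers whose prediction sets at significance ε define
   each model's applicability domain (AD) with a guaranteed per-class
   error ≤ ε, and consensus/probability ensembles.
5. **Evaluation**: SN/SP/ACC/BACC/MCC over in-AD compounds with AD
   coverage, stratified by chemical-space cluster and log P bin, and a
   per-compound misprediction census with nearest-neighbour context.
6. **Prospective selection**: a PCA + k-means(6) reference chemical
   space, similarity classes against the training set (Tc ≥ 0.7 /
   ≤ 0.3), per-category concordance + AD thresholds (70/80/90/100%),
   and a ≤ 25-per-group budgeted pick via 5×5 subclustering.

Because real assay measurements and vendor collections are not
distributable, a tested synthetic-data module generates the study
inputs: a ~2,200-compound drug-like library whose ~14% actives are
driven by planted redox-alert substructures (quinones, catechols,
nitroaromatics, Michael acceptors, …) plus label noise, triplicate
plates with QC artifacts, and a 20,000-compound screening collection
with similar/intermediate/dissimilar strata. See `docs/methods.md` for
the models, defaults and design decisions.

## Worked example

The numbered scripts under `analysis/` run the whole study and write
their tables under `results/` (about 15 minutes on one CPU at full
scale):

```bash
python analysis/01_simulate.py            --seed 1   # library, plates, screening set
python analysis/02_call_activity.py                  # wells -> activity calls
python analysis/03_curate_split.py        --seed 1   # standardize, cluster, 70/30 split
python analysis/04_train_models.py        --seed 1   # fit zoo, predict holdout + screening
python analysis/05_evaluate_models.py                # leaderboard, census, model selection
python analysis/06_prospective_selection.py --seed 1 # chemical space, budgeted selection
```

With `--seed 1` the run prints, among other things:

```
library: 2191 compounds, 349 latent actives (15.9%), 209 alert-bearing
2191 compounds called, 354 active, 0 not evaluable
split: 1534 train / 657 test over 292 clusters
NN concordance 82.19%; active-with-inactive-NN 8.83%, inactive-with-active-NN 8.98%
```

and a holdout leaderboard (excerpt):

```
          model    SN    SP   ACC  BACC    AD    MCC
       pls_both 0.524 0.995 0.921 0.759 1.000  0.670
  logistic_both 0.553 0.977 0.910 0.765 1.000  0.624
       cp_rf_fp 0.711 0.696 0.698 0.703 0.798  0.326
random_baseline 0.049 0.933 0.795 0.491 1.000 -0.027
```

Read: real-descriptor models clearly beat the randomized-descriptor
baseline (MCC 0.67 vs −0.03); conformal models (`cp_*`) trade AD
coverage (≈ 0.74–0.80) for a more balanced sensitivity/specificity, the
same pattern subsampling strategies show on real screens. The
prospective stage then selects 371 screening compounds in 15 groups
(every group capped at 25), "tests" them against the generator's latent
activity oracle (91 actives / 280 inactives, ratio 1:3.08) and scores
the selected model panel prospectively (mean MCC 0.378).

The same pipeline is available as one orchestrated run with a manifest
of artifact hashes:

```bash
oxsar run config.yaml --out runs/demo    # config: seed plus optional overrides
```

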
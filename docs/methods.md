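# Methods

This package implements a representational similarity analysis (RSA) of
structural lesion patterns: given binary lesion masks on a voxel template of
named white-matter connections and an items × patients binary picture-naming
table, it asks **which connections carry semantic structure** — i.e., in which
connections do lesion patterns that disrupt naming of one item also disrupt
naming of semantically similar items?

## The pipeline

1. **Lesion features.** Each patient's binary mask is restricted to each
   connection's voxels, giving a binary V × N (voxels × patients) matrix per
   connection. A connection is analyzed only if at least `min_patients` (5)
   patients each have strictly more than `min_voxels` (20) lesioned voxels in
   it.
2. **Item-wise decoding.** For every item, patients are split into correct
   (1) and wrong (0) responders. Because item accuracy is rarely 50%, a
   *balanced bootstrap* draws training sets containing all minority-class
   patients plus an equal-size random draw from the majority class (so every
   training set has exactly 50% accuracy), repeated `reps` times (100 at
   paper scale, 20 in the desk demo). A linear SVM (hinge loss, C = 1, no
   feature scaling — features are binary) is fit per training set; patients
   outside the training set are scored by that model, training patients by a
   leave-two-out scheme (random one-per-class pairing, each patient held out
   exactly once, the model refit without the pair).
3. **Neural RDM.** The simple matching coefficient (SMC) between the
   predicted scores of item-i models and the *actual* scores of item j,
   averaged over repetitions and symmetrized, is the cross-item prediction
   similarity; the neural representational dissimilarity matrix (RDM) is
   1 − similarity. The diagonal (within-item correspondence) is stored
   separately and never enters RSA.
4. **Decoding gate.** The mean within-item correspondence is tested with a
   patient-shuffle permutation test (naming rows permuted jointly across
   items, preserving inter-item correlations; 10,000 permutations at paper
   scale, 1,000 in the demo, at a reduced internal repetition count).
   Benjamini–Hochberg FDR across connections (q < 0.05) selects the
   decodable connections; only those enter RSA.
5. **RSA screen.** Each neural RDM is vectorized (upper triangle; 4,950
   pairs for 100 items) and Spearman-correlated with a behavioral model RDM,
   optionally partialling out nuisance RDMs (rank transform → OLS
   residualization → Pearson on residuals; df = n − 2 − k). One-sided
   positive tests, BH-FDR across connections, and item-bootstrap standard
   errors (items resampled with replacement; self-pairs excluded).

Behavioral RDMs: the semantic and four modality-specific attribute RDMs
(shape, manipulation, color, motion) come from multi-arrangement trials
(per-trial screen distances scaled to unit RMS, then averaged cell-wise —
invariant to per-trial rotation/translation/scale); control RDMs are
silhouette overlap (1 − Jaccard), shared sub-syllabic units
(1 − Dice over pooled onset/rhyme multisets), and category membership
(within = 0, between = 1). Attribute cells undefined for unrated items are
either set to 1 ("most dissimilar") or left missing for complete-case
deletion.

## The SVM intercept (a deliberate deviation)

Under the balanced bootstrap, most training patients carry *no* lesion in
the connection being decoded, and their hinge cost is constant for any
intercept in [−1, 1]. A free or L2-regularized intercept then drifts to
whichever extreme grants free margin to the feature-bearing class (sklearn's
`SVC(kernel="linear")` lands at exactly b = −1 on such data), so every
unlesioned patient is predicted into that class. This inverts the
within-item statistic for exactly the connections that decode best, and it
is not a solver artifact but a degeneracy of the max-margin objective on
region-sparse designs. The decoder here therefore fits the weight vector
without an intercept and places the decision threshold at the **median
training decision value** — the operating point the 50/50 balanced design
implies. Patients at the threshold (in particular all zero-feature patients)
deterministically receive the "correct" class. With this rule the
permutation gate separates planted informative from null connections at
z ≈ 4 vs z ≈ 0–1.

## p-values for the RSA screen

The parametric p treats the pair vector (e.g., 435 pairs for 30 items) as
independent observations. Pairs sharing an item are not independent, and all
connections of one cohort share the naming labels, so their RDMs carry a
common item-level (additive) component; the parametric false-positive rate
under a fully null world is inflated several-fold, in whole-cohort blocks.
This limitation is inherited from the original analysis and kept as the
default for fidelity. `rsa_screen(..., p_mode="item_permutation")` provides
the calibrated alternative: item labels of the neural RDM are permuted
jointly over rows and columns and r recomputed (add-one estimator). The null
calibration acceptance test uses this mode; measured over 20 null cohorts
the p < 0.05 rate is 20/240 with the permutation p versus 53/240 with the
parametric p (99% binomial band: [4, 21]).

## The synthetic world

The generator plants ground truth so that every downstream stage is testable
without patient data. Its defaults are the demonstration world used by the
acceptance tests.

- **Semantic item space** (`make_item_space`): 30 items in 5 categories,
  embedded in a low-dimensional (d = 3) non-negative feature-intensity
  space. Categories sit on well-separated directions of the non-negative
  orthant; items scatter around their category center (sd 0.4) and rows are
  normalized to a common norm. Non-negativity matters because the naming
  model consumes loading *magnitudes*: with signed embeddings, items at E
  and −E would receive identical damage profiles and the planted geometry
  would fold. Equal row norms decouple overall item difficulty from semantic
  position, so lesion burden alone predicts nothing about *which* items
  fail. Attribute spaces are `w·E + (1−w)·noise` with w found by bisection
  so the attribute-RDM/semantic-RDM Spearman correlation hits its target
  (defaults 0.35/0.47/0.23/0.27 for shape/manipulation/color/motion —
  observed behavioral levels); targets above 0.9 are rejected as outside the
  emulated world, and `coupling_override` pins w directly (w = 1 makes an
  attribute space identical to the semantic space, used by the nulling
  test).
- **Template** (`make_template`): 12 pairwise-disjoint, 6-connected blobs of
  150 voxels grown on a 13³ grid.
- **Connection loadings** (`make_loadings`): every voxel carries
  `gain · E[:, dim(v)] + noise` — a fixed sparse linear projection of the
  embedding — with the projected dimension constant over compact spatial
  cells of the connection (k-means on voxel coordinates): different segments
  of a tract carry different aspects of the represented space, so *where* a
  lesion falls inside a connection determines *which* items suffer. Null
  connections get pure noise; at gain = 0 the two constructions coincide.
  Each loading column is rescaled so its item-averaged magnitude is
  `damage_scale / V` (damage_scale = 24): the item-averaged damage of any
  lesion is then an exact function of its size, so overall lesion burden
  carries no item information and only the hit pattern does.
- **Lesions** (`simulate_lesions`): the default model is one contiguous
  blob per patient grown from a uniform random seed voxel (6-connectivity),
  size uniform in `size_range`. The demonstration world uses the multifocal
  extension: 3 foci of 30–34 voxels, each confined to a distinct randomly
  chosen connection. Confinement makes lesion patterns causally independent
  across connections, which is what lets the null connections be genuinely
  null: in single-blob worlds either lesions span adjacent connections
  (spatial leakage makes null connections semantically decodable) or
  per-connection patient counts fall too low to decode at all. Etiology
  labels emulate a 67 stroke / 13 TBI cohort; hemisphere comes from the
  lesion centroid.
- **Naming** (`simulate_naming`): P(item i wrong for patient p) =
  logistic(β0 + β1 · Σ lesioned-voxel |loading|), sampled independently per
  cell. β1 = 1.5; β0 is solved by bisection so the grand mean accuracy is
  70% (the cohort the generator emulates implies a mean around 70–74%:
  balanced training sizes of 12–78, mean ≈ 42, over 80 patients). The
  resulting item accuracies span roughly 0.55–0.90; an optional per-item
  difficulty intercept (`item_difficulty_sd`) widens the span toward the
  15–95% of real naming batteries but is off by default because difficulty
  heterogeneity adds item-level RDM structure without semantic content.
- **Arrangements** (`simulate_arrangements`): the canonical 2-D layout is
  the classical (Torgerson) MDS of the chosen embedding, normalized to unit
  RMS pairwise distance; each trial applies a random rotation and scale
  (which the aggregator must undo) plus Gaussian coordinate noise (sd 0.1);
  per rater the first trial shows all items and later trials random subsets;
  20 raters, 8 trials each. A 2-D arrangement faithfully expresses a 2-D
  space exactly and a 3-D space approximately; higher-dimensional planted
  spaces are increasingly distorted by the projection, which is a property
  of the task, not the aggregator.
- **Stimulus descriptors**: silhouettes are filled ellipses whose geometry
  follows the shape-attribute embedding; transcriptions are random
  Mandarin-like onset/rhyme syllables. Both exist so the control RDMs have
  inputs, not to emulate real stimulus statistics.

All generators are pure functions of their arguments including the seed;
random streams are keyed by (master seed, stage name, entity id,
repetition), so any stage reproduces in isolation and results do not depend
on execution order.

### What a green planted-recovery test does and does not establish

It establishes that the full chain — coverage filter, balanced-bootstrap SVM
decoding with the median-threshold rule, SMC cross-prediction, symmetrized
1−similarity RDMs, permutation-FDR gating, Spearman RSA with BH-FDR —
recovers connections whose voxel loadings were built from the semantic
embedding, and rejects connections with statistically identical but
semantically unstructured loadings, at n = 80 patients and 30 items. It does
not establish sensitivity at real effect sizes (reported correlations at 100
items are an order of magnitude smaller than the planted ones), robustness
to registration error, multi-tract lesion anatomy, or graded (non-binary)
naming scores, none of which the generator emulates.

## Numerical choices

- Spearman via scipy (average ranks, t-approximation p); partial Spearman as
  rank → OLS residualization → Pearson with df = n − 2 − k; collinear
  nuisance columns dropped with a warning.
- Fully-explained guard: when the nuisance set captures more than 99% of a
  vector's rank variance, `partial_spearman` returns r = 0, p = 1 (with a
  warning) instead of renormalizing the residual. Rank-linear residualization
  cannot absorb the curvature between near-duplicate monotone measurements of
  the same structure, so in that regime the "partial correlation" is a
  sign-arbitrary artifact computed on ~0.2% of the variance (any other
  monotone measurement of the same structure, e.g. a neural RDM, correlates
  with the curvature at r ≈ 0.1 despite nothing higher-order existing).
  Realistic nuisance sets — attribute couplings of 0.2–0.5 leave residual
  shares above 50% — never trigger the guard.
- BH-FDR via statsmodels `multipletests(method="fdr_bh")`.
- The SVM solver is a liblinear-style dual coordinate descent (numba, CSR)
  with tolerance 0.1 on the projected gradient and warm-started
  leave-two-out refits; duplicate voxel columns are merged with
  √multiplicity scaling (identical optimum). It is cross-checked against
  `sklearn.svm.SVC(kernel="linear")` in the tests. The custom solver exists
  because the permutation gate needs ~10⁶ fits of tiny problems.
- Permutation p is the literal fraction of permuted statistics strictly
  greater than the observed one (`add_one=True` switches to (k+1)/(n+1)).
- The percentile transform of RDMs is display-only (rank-preserving) and is
  never applied before correlation.
- Degenerate items (minority class below `min_minority` = 2) are skipped;
  their RDM rows stay missing and downstream RSA uses complete-case pairs.

## Known limitations

- Parametric RSA p-values ignore pair non-independence (see above); use
  `p_mode="item_permutation"` when calibration matters.
- The demo world's item accuracy span (0.55–0.90) is narrower than real
  naming batteries; `item_difficulty_sd` exists but trades calibration for
  span.
- The multi-arrangement aggregator uses per-trial unit-RMS scaling and
  cell-wise averaging, not a full inverse-MDS estimator; rank structure is
  preserved, absolute scale is not.
- Whether the original phonological "proportion of shared units" is
  Dice-normalized (implemented) or max-normalized is not documented in the
  source analysis; the Dice convention is symmetric and equals the natural
  proportion for equal-length names.
- Real lesion masks must already be on the template grid; no resampling is
  performed, and a grid mismatch is a hard error.
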
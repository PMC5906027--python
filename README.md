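# lesion-rsa

Representational similarity analysis (RSA) of structural lesion patterns.

**The scientific problem.** Multivariate lesion–symptom mapping usually asks
*where* damage impairs a behavior. This package asks a finer question: *what
information* does a white-matter connection carry? Given binary lesion masks
from a patient cohort and their item-level picture-naming responses (1
correct / 0 wrong), it builds a "neural" representational dissimilarity
matrix (RDM) for every connection from lesion→naming decoding models, and
then tests which connections represent **semantic space** — and whether that
survives controlling modality-specific attribute spaces (shape,
manipulation, color, motion) and peripheral/categorical structure.

**The core statistic.** For each connection with adequate lesion coverage
(≥ 5 patients with > 20 lesioned voxels), an item-wise linear SVM is trained
on the binary voxel lesion pattern under a *balanced bootstrap* (all
minority-class patients plus an equal-size majority draw, so every training
set has 50% accuracy; repeated `reps` times). Cross-item prediction
correspondence — the simple matching coefficient (SMC) between item-*i*
model predictions and item-*j* actual scores, averaged over repetitions and
symmetrized — defines the neural similarity `s(i,j)`; the neural RDM is
`1 − s`. Within-item (diagonal) correspondence is tested by a patient-shuffle
permutation test with Benjamini–Hochberg FDR; the decodable connections'
RDMs are vectorized (4,950 pairs at 100 items) and Spearman-correlated with
behavioral model RDMs, with optional partial correlation against nuisance
RDMs and item-bootstrap standard errors:

    r(c) = Spearman( vec(neural RDM_c), vec(model RDM) | nuisance RDMs )

A synthetic-cohort generator with planted ground truth (informative vs null
connections, controllable attribute–semantic coupling) stands in for patient
data, so the whole pipeline is testable end to end. See `docs/methods.md`
for the model, the generator, and every numerical choice.

## Worked example

The numbered scripts under `analysis/` run the demonstration study (80
patients, 30 items in 5 categories, 12 connections of which 4 are planted
informative at gain 2, decoding at 20 repetitions, 1,000 permutations):

```bash
python analysis/01_simulate_cohort.py    # world -> results/demo/ (NIfTI + CSV)
python analysis/02_behavioral_rdms.py    # semantic/attribute/control RDMs
python analysis/03_decode_connections.py # neural RDMs + permutation gate
python analysis/04_rsa_screen.py         # semantic + higher-order screens
python analysis/05_report.py             # tables + heatmaps
```

Script 01 prints the cohort summary:

```
template: 12 connections x 150 voxels on (13, 13, 13)
informative connections: conn_000, conn_001, conn_002, conn_003
cohort: 80 patients, lesion sizes 91-102 voxels, 67 stroke / 13 TBI
naming: 30 items, grand mean accuracy 0.70, item accuracy span 0.49-0.82
```

Script 03 shows the two-stage gate at work — the four planted connections
decode their own items far above the permuted null, the eight null
connections do not:

```
conn_000: within-item 0.703, permutation p = 0.0000
...
conn_004: within-item 0.650, permutation p = 0.1810
decodable connections (within-item FDR q < 0.05): 4/12
```

and script 04 recovers exactly the planted set, before and after partialling
out all seven control RDMs (four attributes + visual + phonological +
categorical):

```
semantic screen: kept ['conn_000', 'conn_001', 'conn_002', 'conn_003']
  true positives 4, false positives 0
  * conn_003: r=+0.558 p=2.52e-37 se=0.103
  * conn_000: r=+0.501 p=2.39e-29 se=0.130
higher-order screen: kept ['conn_000', 'conn_001', 'conn_002', 'conn_003']
  * conn_003: r=+0.488 p=2.76e-27 se=0.116
```

`r` is the (partial) Spearman correlation between a connection's neural RDM
and the semantic model over the 435 item pairs; `se` is the ±1 standard
error from 1,000-draw item bootstrap; `fdr_kept` (the `*`) marks connections
surviving BH-FDR at q < 0.05. That the *partial* correlations stay positive
means these connections carry semantic structure beyond what shape,
manipulation, color, motion, early-visual, phonological, and categorical
models explain — the "higher-order semantic" effect the method is designed
to isolate.

Everything is also available as a single call:

```python
from lesion_rsa.pipeline import demo_config, run_all
result = run_all(demo_config("my_run", seed=1))
```

and for real data, `RunConfig(synthetic=False, template_dir=..., cohort_dir=...,
naming_csv=..., behavioral_dir=...)` consumes a NIfTI label template + region
table, per-patient binary NIfTI masks, a patients × items CSV, and CSV model
RDMs on the same machinery.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main analysis from scratch at the given seed — it
simulates the cohort, builds the behavioral RDMs, extracts features, runs
the gated decoding and the semantic RSA screen, writes the run artifacts and
report next to `--out`, and prints the recovered connections. The
quantitative acceptance checks themselves (combinatorial constants,
bootstrap balance, brute-force oracle equivalence, exact permutation
calibration, planted-effect recovery, null calibration, higher-order
nulling) live in `tests/test_acceptance.py`.

## Layout

```
src/lesion_rsa/     core.py     grids, template, cohort, naming containers
                    rdm.py      the RDM container (+ display percentile)
                    synth.py    synthetic world with planted ground truth
                    behavior.py behavioral RDM construction
                    features.py lesion features, coverage filter, subsets
                    decoding.py balanced-bootstrap SVM decoding, neural RDMs,
                                permutation gate, BH-FDR
                    rsa.py      (partial) Spearman RSA, item bootstrap, screen
                    pipeline.py RunConfig, staged runner, report
                    io.py       NIfTI / TSV / CSV readers and writers
analysis/           numbered study drivers (simulate -> ... -> report)
scripts/            acceptance.py
tests/              pytest suite incl. test_acceptance.py
docs/methods.md     models, assumptions, parameters, limitations
```
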
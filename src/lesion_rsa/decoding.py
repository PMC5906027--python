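"""Neural RDM construction by item-wise lesion-to-naming decoding.

For each region, a balanced-bootstrap linear SVM is trained per item on the
binary voxel lesion features; the simple matching coefficient between the
predicted scores of item-i models and the actual scores of item j, averaged
over bootstrap repetitions and symmetrized, gives the cross-item prediction
similarity; the neural RDM is 1 - similarity. Within-item (diagonal)
correspondence is tested with a patient-shuffle permutation test, and
Benjamini-Hochberg FDR selects decodable regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._rng import stream
from ._svm import csr_parts, predict_patient_scores
from .core import NamingMatrix
from .features import ConnectionFeatureMatrix
from .rdm import RDM

__all__ = [
    "BootstrapPlan",
    "NeuralRDM",
    "smc",
    "balanced_bootstrap",
    "predict_scores",
    "build_similarity",
    "assemble_neural_rdm",
    "permutation_test",
    "fdr_select",
    "decode_connection",
]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def smc(a, b) -> float:
    """Simple matching coefficient: fraction of agreeing positions."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError(f"smc needs two equal-length vectors, got {a.shape}, {b.shape}")
    return float((a == b).mean())


@dataclass(frozen=True)
class BootstrapPlan:
    """Balanced training subsets for one item (all minority patients plus an
    equal-size random draw from the majority class, per repetition)."""

    item_id: str
    subsets: list  # list of (2 * minority,) int arrays of patient indices
    minority_count: int
    skipped: bool

    @property
    def n_reps(self) -> int:
        return len(self.subsets)


def balanced_bootstrap(labels, reps: int, min_minority: int = 2,
                       seed: int = 0, item_id: str = "") -> BootstrapPlan:
    """Build the balanced-bootstrap plan for one item's binary labels.

    Items whose minority class has fewer than ``min_minority`` patients
    (including all-0 / all-1 items) are marked skipped, never raised.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    n0 = int((labels == 0).sum())
    n1 = int((labels == 1).sum())
    minority_label = 0 if n0 <= n1 else 1
    k = min(n0, n1)
    if k < min_minority:
        return BootstrapPlan(item_id, [], k, skipped=True)
    minority = np.flatnonzero(labels == minority_label)
    majority = np.flatnonzero(labels != minority_label)
    rng = stream(seed, "bootstrap", item_id)
    subsets = []
    for _ in range(reps):
        draw = rng.choice(majority, size=k, replace=False)
        subsets.append(np.sort(np.concatenate([minority, draw])))
    return BootstrapPlan(item_id, subsets, k, skipped=False)


# ---------------------------------------------------------------------------
# classifier driver
# ---------------------------------------------------------------------------

class _Design:
    """CSR patients x features design for one region (bias column included)."""

    __slots__ = ("csr", "n_features", "n_patients")

    def __init__(self, csr, n_features, n_patients):
        self.csr = csr
        self.n_features = n_features
        self.n_patients = n_patients


def _design_matrix(features: ConnectionFeatureMatrix) -> _Design:
    """Patients x features design with duplicate voxel columns merged.

    Voxels with identical lesion patterns across the cohort are collapsed to a
    single column scaled by sqrt(multiplicity) — the L2-regularized hinge
    optimum is provably identical. No intercept column: the decision threshold
    is the median training decision value (see lesion_rsa._svm).
    """
    if features.n_voxels == 0:
        raise ValueError(f"region {features.region!r} has zero voxels")
    uniq, counts = np.unique(features.values, axis=0, return_counts=True)
    nonzero = uniq.any(axis=1)
    uniq, counts = uniq[nonzero], counts[nonzero]
    dense = np.ascontiguousarray(uniq.T.astype(np.float64)
                                 * np.sqrt(counts)[None, :])
    if dense.shape[1] == 0:  # no voxel ever lesioned: degenerate but legal
        dense = np.zeros((features.n_patients, 1))
    return _Design(csr_parts(dense), dense.shape[1], dense.shape[0])


def _pairing(labels, subset, rng):
    """Random one-per-class pairing of the training subset (positions within subset)."""
    sub_labels = labels[subset]
    pos0 = np.flatnonzero(sub_labels == 0)
    pos1 = np.flatnonzero(sub_labels == 1)
    if len(pos0) != len(pos1):
        raise ValueError("training subset is not balanced")
    return rng.permutation(pos0).astype(np.int64), rng.permutation(pos1).astype(np.int64)


def _predict(design: _Design, labels, subset, rng, C=1.0):
    pairs_a, pairs_b = _pairing(labels, subset, rng)
    return predict_patient_scores(
        design.csr, design.n_features, labels.astype(np.uint8),
        subset.astype(np.int64), pairs_a, pairs_b,
        C=C, shuffle_seed=int(rng.integers(1, 2**31 - 1)),
    )


def predict_scores(features: ConnectionFeatureMatrix, labels,
                   training_subset, seed: int = 0, C: float = 1.0) -> np.ndarray:
    """Predicted binary naming score for every patient from one training subset.

    Non-training patients are scored by the model fit on the whole (balanced)
    subset; training patients are scored leave-two-out, each held out with a
    randomly paired patient of the other class.
    """
    labels = np.asarray(labels)
    design = _design_matrix(features)
    subset = np.asarray(training_subset, dtype=np.int64)
    return _predict(design, labels, subset, stream(seed, "predict"), C=C)


# ---------------------------------------------------------------------------
# similarity matrix and neural RDM
# ---------------------------------------------------------------------------

def build_similarity(features: ConnectionFeatureMatrix, naming: NamingMatrix,
                     plans: list[BootstrapPlan], seed: int = 0,
                     C: float = 1.0) -> np.ndarray:
    """Items x items cross-prediction similarity, averaged over repetitions.

    cell(i, j) = SMC(predictions of item-i models, actual scores of item j);
    rows of skipped items are NaN.
    """
    design = _design_matrix(features)
    vals = naming.values
    n_items = naming.n_items
    sim = np.full((n_items, n_items), np.nan)
    if all(p.skipped for p in plans):
        raise ValueError("every item was skipped; nothing to decode")
    for i, plan in enumerate(plans):
        if plan.skipped:
            continue
        labels = vals[:, i]
        acc = np.zeros(n_items)
        for rep, subset in enumerate(plan.subsets):
            rng = stream(seed, "pairing", features.region, plan.item_id, rep)
            preds = _predict(design, labels, subset, rng, C=C)
            acc += (preds[:, None] == vals).mean(axis=0)
        sim[i] = acc / plan.n_reps
    return sim


@dataclass
class NeuralRDM:
    """Per-region decoding output: the (1 - similarity) RDM plus diagnostics."""

    connection: str
    rdm: RDM
    within_item: np.ndarray        # per-item diagonal correspondence (NaN if skipped)
    n_boot: int
    permutation_p: float | None = None
    fdr_kept: bool | None = None

    @property
    def mean_within_item(self) -> float:
        return float(np.nanmean(self.within_item))


def assemble_neural_rdm(similarity: np.ndarray, item_ids: list[str],
                        connection: str = "", n_boot: int = 0) -> NeuralRDM:
    """Symmetrize the raw similarity matrix and convert to dissimilarity.

    Symmetric cells are averaged, (M + M.T) / 2, where both directions are
    defined; pairs involving a skipped item stay missing. The diagonal
    (within-item correspondence) is stored separately — downstream RSA never
    consumes it — and the RDM diagonal is fixed at 0 by convention.
    """
    similarity = np.asarray(similarity, dtype=float)
    if similarity.ndim != 2 or similarity.shape[0] != similarity.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {similarity.shape}")
    within = np.diagonal(similarity).copy()
    sym = 0.5 * (similarity + similarity.T)  # NaN where either direction missing
    dissim = 1.0 - sym
    defined_diag = ~np.isnan(within)
    diag_vals = np.where(defined_diag, 0.0, np.nan)
    np.fill_diagonal(dissim, diag_vals)
    rdm = RDM(list(item_ids), np.clip(dissim, 0.0, 1.0), "neural")
    return NeuralRDM(connection=connection, rdm=rdm, within_item=within,
                     n_boot=n_boot)


# ---------------------------------------------------------------------------
# within-item permutation test
# ---------------------------------------------------------------------------

def _within_item_accuracy(design, values, reps, rng, min_minority, C=1.0):
    """Mean over items of within-item SMC at the given rep count.

    All subset draws and pairings come from the single ``rng`` (in item
    order), keeping the permutation loop deterministic without the cost of
    one keyed stream per item and repetition.
    """
    accs = []
    n_items = values.shape[1]
    for i in range(n_items):
        labels = values[:, i]
        n0 = int((labels == 0).sum())
        k = min(n0, len(labels) - n0)
        if k < min_minority:
            continue
        minority_label = 0 if n0 <= len(labels) - n0 else 1
        minority = np.flatnonzero(labels == minority_label)
        majority = np.flatnonzero(labels != minority_label)
        a = 0.0
        for _rep in range(reps):
            draw = rng.choice(majority, size=k, replace=False)
            subset = np.sort(np.concatenate([minority, draw]))
            preds = _predict(design, labels, subset, rng, C=C)
            a += (preds == labels).mean()
        accs.append(a / reps)
    return float(np.mean(accs)) if accs else np.nan


def permutation_test(features: ConnectionFeatureMatrix, naming: NamingMatrix,
                     reps: int, n_perm: int, seed: int = 0,
                     observed: float | None = None, min_minority: int = 2,
                     add_one: bool = False, C: float = 1.0) -> tuple[float, np.ndarray]:
    """Permutation p-value for the mean within-item prediction correspondence.

    Each permutation shuffles patient identity (whole naming rows, preserving
    inter-item correlations) and reruns the within-item pipeline at ``reps``
    internal repetitions. p is the fraction of permuted means strictly greater
    than the observed mean; ``add_one`` switches to the (k+1)/(n+1) estimator.
    Returns (p, permuted means).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    design = _design_matrix(features)
    if observed is None:
        observed = _within_item_accuracy(
            design, naming.values, reps,
            stream(seed, "within", features.region), min_minority, C=C)
    perm_stats = np.empty(n_perm)
    n = naming.n_patients
    for k in range(n_perm):
        rng = stream(seed, "perm", features.region, k)
        perm = rng.permutation(n)
        perm_stats[k] = _within_item_accuracy(
            design, naming.values[perm], reps, rng, min_minority, C=C)
    greater = int((perm_stats > observed).sum())
    p = (greater + 1) / (n_perm + 1) if add_one else greater / n_perm
    return float(p), perm_stats


def fdr_select(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if (pvals < 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    keep, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return keep


# ---------------------------------------------------------------------------
# one-call per-region driver used by the pipeline
# ---------------------------------------------------------------------------

def decode_connection(features: ConnectionFeatureMatrix, naming: NamingMatrix,
                      reps: int = 100, min_minority: int = 2, seed: int = 0,
                      n_perm: int = 0, perm_reps: int = 10,
                      add_one: bool = False, C: float = 1.0) -> NeuralRDM:
    """Full decoding of one region: balanced bootstrap, similarity matrix,
    neural RDM, and (optionally) the within-item permutation test."""
    plans = [balanced_bootstrap(naming.values[:, i], reps,
                                min_minority=min_minority, seed=seed, item_id=item)
             for i, item in enumerate(naming.item_ids)]
    sim = build_similarity(features, naming, plans, seed=seed, C=C)
    out = assemble_neural_rdm(sim, naming.item_ids, connection=features.region,
                              n_boot=reps)
    if n_perm > 0:
        p, _ = permutation_test(features, naming, perm_reps, n_perm, seed=seed,
                                observed=out.mean_within_item,
                                min_minority=min_minority, add_one=add_one, C=C)
        out.permutation_p = p
    return out
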
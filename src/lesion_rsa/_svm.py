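"""Minimal liblinear-style linear SVM (dual coordinate descent, L1 hinge loss).

The decoding stage needs on the order of 10^6 fits of tiny problems
(tens of patients x tens-to-hundreds of binary voxel features) for the
permutation test, which rules out per-fit library call overhead. This solver
implements the standard dual CD for

    min_w  0.5 ||w||^2 + C * sum_i max(0, 1 - y_i w.x_i)

The intercept needs care. Under the balanced bootstrap most training
patients carry no lesion in the region being decoded, and their hinge cost is
constant for any intercept in [-1, 1]; a free (or L2-regularized) intercept
then drifts to whichever extreme grants free margin to the feature-bearing
class — sklearn's SVC lands at exactly b = -1 on such data — and every
unlesioned patient inherits that class. The decoder therefore fits the weight
vector without an intercept and places the decision threshold at the *median
training decision value*: the operating point the 50/50 balanced design
implies, with patients at the threshold (in particular all zero-feature
patients) deterministically assigned the "correct" class.

The patient-by-feature design is stored CSR (lesion features are mostly
zero), so a coordinate-descent pass costs the number of nonzeros, not rows x
columns. Warm starts make the leave-two-out refits cheap. The weight solver
is cross-checked against sklearn.svm.SVC(kernel="linear") in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fit_svm", "predict_patient_scores", "csr_parts"]


def csr_parts(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(data, indices, indptr) of a dense patients x features design."""
    from scipy.sparse import csr_matrix

    m = csr_matrix(np.asarray(X, dtype=np.float64))
    return (m.data.astype(np.float64), m.indices.astype(np.int64),
            m.indptr.astype(np.int64))


@njit(cache=True)
def _cd_solve_csr(data, indices, indptr, rows, y, C, alpha, w, active,
                  max_passes, tol, shuffle_seed):
    """In-place dual CD over the active training samples (CSR rows)."""
    n = rows.shape[0]
    qii = np.empty(n)
    for i in range(n):
        s = 0.0
        r = rows[i]
        for k in range(indptr[r], indptr[r + 1]):
            s += data[k] * data[k]
        qii[i] = s
    order = np.arange(n)
    state = np.uint64(shuffle_seed * 2654435761 + 1)
    for _ in range(max_passes):
        # Fisher-Yates with a tiny LCG: deterministic, independent of numpy
        for i in range(n - 1, 0, -1):
            state = state * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
            j = int(state >> np.uint64(33)) % (i + 1)
            order[i], order[j] = order[j], order[i]
        max_viol = 0.0
        for oi in range(n):
            i = order[oi]
            if not active[i] or qii[i] == 0.0:
                continue
            r = rows[i]
            g = 0.0
            for k in range(indptr[r], indptr[r + 1]):
                g += w[indices[k]] * data[k]
            g = y[i] * g - 1.0
            # projected gradient for the box constraint [0, C]
            if alpha[i] == 0.0:
                pg = min(g, 0.0)
            elif alpha[i] == C:
                pg = max(g, 0.0)
            else:
                pg = g
            if abs(pg) > max_viol:
                max_viol = abs(pg)
            if pg != 0.0:
                old = alpha[i]
                new = min(max(old - g / qii[i], 0.0), C)
                if new != old:
                    alpha[i] = new
                    d = (new - old) * y[i]
                    for k in range(indptr[r], indptr[r + 1]):
                        w[indices[k]] += d * data[k]
        if max_viol < tol:
            break


@njit(cache=True)
def _value_csr(data, indices, indptr, r, w):
    s = 0.0
    for k in range(indptr[r], indptr[r + 1]):
        s += w[indices[k]] * data[k]
    return s


@njit(cache=True)
def _median_threshold(data, indices, indptr, rows, w, skip_a, skip_b):
    """Median decision value over training rows (optionally excluding a pair)."""
    vals = np.empty(rows.shape[0])
    m = 0
    for i in range(rows.shape[0]):
        if i == skip_a or i == skip_b:
            continue
        vals[m] = _value_csr(data, indices, indptr, rows[i], w)
        m += 1
    v = np.sort(vals[:m])
    if m % 2 == 1:
        return v[m // 2]
    return 0.5 * (v[m // 2 - 1] + v[m // 2])


@njit(cache=True)
def _scores_csr(data, indices, indptr, n_features, y01, subset, pairs_a,
                pairs_b, C, max_passes, tol, lpo_passes, shuffle_seed):
    n = indptr.shape[0] - 1
    s = subset.shape[0]
    ys = np.empty(s)
    for i in range(s):
        ys[i] = 2.0 * y01[subset[i]] - 1.0
    alpha = np.zeros(s)
    w = np.zeros(n_features)
    active = np.ones(s, dtype=np.bool_)
    _cd_solve_csr(data, indices, indptr, subset, ys, C, alpha, w, active,
                  max_passes, tol, shuffle_seed)

    tau = _median_threshold(data, indices, indptr, subset, w, -1, -1)
    preds = np.zeros(n, dtype=np.uint8)
    in_subset = np.zeros(n, dtype=np.bool_)
    for i in range(s):
        in_subset[subset[i]] = True
    for r in range(n):
        if not in_subset[r]:
            v = _value_csr(data, indices, indptr, r, w)
            preds[r] = 1 if v >= tau else 0

    for p in range(pairs_a.shape[0]):
        ia, ib = pairs_a[p], pairs_b[p]
        alpha2 = alpha.copy()
        w2 = w.copy()
        for i2, coef in ((ia, alpha[ia] * ys[ia]), (ib, alpha[ib] * ys[ib])):
            if coef != 0.0:
                r = subset[i2]
                for k in range(indptr[r], indptr[r + 1]):
                    w2[indices[k]] -= coef * data[k]
        alpha2[ia] = 0.0
        alpha2[ib] = 0.0
        active2 = active.copy()
        active2[ia] = False
        active2[ib] = False
        _cd_solve_csr(data, indices, indptr, subset, ys, C, alpha2, w2,
                      active2, lpo_passes, tol, shuffle_seed + p + 1)
        tau2 = _median_threshold(data, indices, indptr, subset, w2, ia, ib)
        va = _value_csr(data, indices, indptr, subset[ia], w2)
        vb = _value_csr(data, indices, indptr, subset[ib], w2)
        preds[subset[ia]] = 1 if va >= tau2 else 0
        preds[subset[ib]] = 1 if vb >= tau2 else 0
    return preds


def fit_svm(X, y, C=1.0, max_passes=100, tol=0.1, shuffle_seed=1):
    """Fresh fit on a dense design; returns (w, alpha).

    Generic solver entry point: append a constant column yourself if you want
    a (regularized) intercept; the decoding pipeline instead thresholds at
    the median training decision value (see module docstring).
    """
    X = np.asarray(X, dtype=np.float64)
    data, indices, indptr = csr_parts(X)
    n = X.shape[0]
    rows = np.arange(n, dtype=np.int64)
    yf = np.asarray(y, dtype=np.float64)
    alpha = np.zeros(n)
    w = np.zeros(X.shape[1])
    active = np.ones(n, dtype=np.bool_)
    _cd_solve_csr(data, indices, indptr, rows, yf, C, alpha, w, active,
                  max_passes, tol, shuffle_seed)
    return w, alpha


def predict_patient_scores(csr, n_features, y01, subset, pairs_a, pairs_b,
                           C=1.0, max_passes=100, tol=0.1, lpo_passes=20,
                           shuffle_seed=1):
    """Predicted binary naming score for every patient.

    csr : (data, indices, indptr) of the (N, F) design (no intercept column).
    subset : (S,) int64 training patient indices (balanced).
    pairs_a, pairs_b : (S/2,) positions *within subset* pairing one patient per
    class; each training patient is predicted by the model refit without their
    pair (leave-two-out), every non-training patient by the full-subset model.
    """
    data, indices, indptr = csr
    return _scores_csr(data, indices, indptr, n_features,
                       np.asarray(y01, dtype=np.uint8),
                       np.asarray(subset, dtype=np.int64),
                       np.asarray(pairs_a, dtype=np.int64),
                       np.asarray(pairs_b, dtype=np.int64),
                       C, max_passes, tol, lpo_passes, shuffle_seed)
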
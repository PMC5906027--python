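"""Representational similarity statistics.

RDMs are vectorized to their upper triangle, correlated by Spearman rank
correlation (optionally partialling out nuisance RDMs by rank-space OLS
residualization), item-bootstrap standard errors are attached, and
Benjamini-Hochberg FDR is applied across regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .decoding import fdr_select
from .rdm import RDM

__all__ = [
    "RSAResult",
    "item_permutation_p",
    "vectorize_rdm",
    "spearman",
    "partial_spearman",
    "bootstrap_se",
    "rsa_screen",
]


#: residual rank-variance share below which a vector counts as fully
#: explained by the nuisance set (see partial_spearman)
FULLY_EXPLAINED_SHARE = 0.01


def vectorize_rdm(rdm: RDM) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Off-diagonal upper-triangle values in row-major order (+ pair index map).

    Missing cells propagate as NaN. Defined cells must be symmetric to 1e-9.
    """
    vals = rdm.values
    both = ~np.isnan(vals) & ~np.isnan(vals.T)
    if not np.allclose(vals[both], vals.T[both], rtol=0, atol=1e-9):
        raise ValueError("RDM has asymmetric defined cells beyond tolerance 1e-9")
    iu = np.triu_indices(rdm.n_items, k=1)
    pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    return vals[iu].astype(float), pairs


def _complete_cases(*vectors) -> np.ndarray:
    ok = np.ones(len(vectors[0]), dtype=bool)
    for v in vectors:
        ok &= ~np.isnan(np.asarray(v, dtype=float))
    return ok


def _t_pvalue(r: float, df: int, alternative: str) -> float:
    if df <= 0 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 and alternative != "two-sided" else np.nan
    t = r * np.sqrt(df / (1.0 - r * r))
    if alternative == "two-sided":
        return float(2 * stats.t.sf(abs(t), df))
    if alternative == "greater":
        return float(stats.t.sf(t, df))
    if alternative == "less":
        return float(stats.t.cdf(t, df))
    raise ValueError(f"unknown alternative {alternative!r}")


def spearman(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Spearman rank correlation with average ranks and the t-approximation p.

    Complete-case deletion is applied first; a constant input yields
    (nan, nan) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = _complete_cases(x, y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(f"need >= 4 complete-case pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman r undefined", stacklevel=2)
        return np.nan, np.nan
    res = stats.spearmanr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def partial_spearman(x, y, nuisance=(), alternative: str = "two-sided"
                     ) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given nuisance vectors.

    All vectors are rank-transformed (average ranks), x and y are residualized
    on the nuisance ranks plus an intercept by least squares, and Pearson
    correlation of the residuals is tested on t with df = n - 2 - k nuisance
    regressors. With an empty nuisance set this reduces to plain Spearman
    exactly. Collinear nuisance columns are dropped with a warning.
    """
    nuisance = [np.asarray(z, dtype=float) for z in nuisance]
    if not nuisance:
        return spearman(x, y, alternative=alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = _complete_cases(x, y, *nuisance)
    x, y = x[ok], y[ok]
    nuisance = [z[ok] for z in nuisance]
    n = x.size
    if n < len(nuisance) + 4:
        raise ValueError(
            f"need >= {len(nuisance) + 4} complete-case pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: partial Spearman r undefined", stacklevel=2)
        return np.nan, np.nan

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    Z = np.column_stack([np.ones(n)] + [stats.rankdata(z) for z in nuisance])
    # drop linearly dependent nuisance columns
    _, R = np.linalg.qr(Z)
    diag = np.abs(np.diagonal(R))
    if (diag <= 1e-9 * max(diag.max(), 1.0)).any():
        warnings.warn("collinear nuisance set: dropping dependent columns",
                      stacklevel=2)
        cols = [Z[:, 0]]
        for j in range(1, Z.shape[1]):
            trial = np.column_stack(cols + [Z[:, j]])
            if np.linalg.matrix_rank(trial) > len(cols):
                cols.append(Z[:, j])
        Z = np.column_stack(cols)
    k = Z.shape[1] - 1
    beta_x, *_ = np.linalg.lstsq(Z, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    ex = rx - Z @ beta_x
    ey = ry - Z @ beta_y
    # A vector whose rank variance is (almost) fully captured by the nuisance
    # set has no partial effect to estimate. Below 1% residual share the
    # "residual" of near-duplicate monotone measurements is measurement noise
    # plus the curvature that rank-LINEAR regression cannot absorb, and the
    # renormalized partial r reports a sizable, sign-arbitrary artifact.
    # Realistic nuisance sets (couplings well below 0.9) leave residual
    # shares of tens of percent and never trigger this guard.
    var_x = ((rx - rx.mean()) ** 2).sum()
    var_y = ((ry - ry.mean()) ** 2).sum()
    if ((ex ** 2).sum() < FULLY_EXPLAINED_SHARE * var_x
            or (ey ** 2).sum() < FULLY_EXPLAINED_SHARE * var_y):
        warnings.warn("vector fully explained by the nuisance set "
                      "(residual rank-variance share < 1%): partial r = 0",
                      stacklevel=2)
        return 0.0, 1.0
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    r = float((ex * ey).sum() / denom)
    return r, _t_pvalue(r, n - 2 - k, alternative)


def bootstrap_se(neural: RDM, model: RDM, nuisance: list[RDM] | None = None,
                 n_boot: int = 1000, seed: int = 0,
                 alternative: str = "two-sided") -> float:
    """Item-bootstrap standard error of the (partial) Spearman correlation.

    Items are resampled with replacement; pairs formed by two copies of the
    same original item (self-pairs, dissimilarity 0 by construction) are
    excluded, since they would artificially inflate r.
    """
    if neural.item_ids != model.item_ids:
        raise ValueError("RDMs must share the same item set and order")
    nuisance = nuisance or []
    n = neural.n_items
    rng = stream(seed, "item_bootstrap")
    rs = []
    mats = [neural.values, model.values] + [z.values for z in nuisance]
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        iu = np.triu_indices(n, k=1)
        a, b = idx[iu[0]], idx[iu[1]]
        keep = a != b  # drop self-pairs from duplicated items
        a, b = a[keep], b[keep]
        vecs = [m[a, b] for m in mats]
        try:
            r, _ = partial_spearman(vecs[0], vecs[1], vecs[2:],
                                    alternative=alternative)
        except ValueError:
            continue
        if not np.isnan(r):
            rs.append(r)
    return float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0


@dataclass(frozen=True)
class RSAResult:
    connection: str
    model_kind: str
    nuisance_kinds: tuple[str, ...]
    r: float
    p: float
    n_pairs: int
    boot_se: float | None
    fdr_kept: bool


def item_permutation_p(neural: RDM, model: RDM,
                       nuisance: list[RDM] | None = None,
                       n_perm: int = 1000, seed: int = 0,
                       alternative: str = "greater") -> tuple[float, float]:
    """Item-label permutation p for the (partial) Spearman RSA correlation.

    Rows and columns of the neural RDM are jointly relabeled, the pair vector
    rebuilt, and r recomputed per permutation; p uses the add-one estimator.
    Unlike the parametric t approximation, this null respects the dependence
    among pairs sharing an item, so it stays calibrated when RDMs carry
    item-level (additive) structure.
    """
    nuisance = nuisance or []
    model_vec, _ = vectorize_rdm(model)
    nuis_vecs = [vectorize_rdm(z)[0] for z in nuisance]
    vals = neural.values
    n = neural.n_items
    iu = np.triu_indices(n, k=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_obs, _ = partial_spearman(vals[iu], model_vec, nuis_vecs,
                                    alternative=alternative)
    if np.isnan(r_obs):
        return np.nan, np.nan
    rng = stream(seed, "item_perm")
    count = 0
    for _ in range(n_perm):
        pi = rng.permutation(n)
        vec = vals[np.ix_(pi, pi)][iu]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_p, _ = partial_spearman(vec, model_vec, nuis_vecs,
                                      alternative=alternative)
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "less":
            count += r_p <= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    return float(r_obs), (count + 1) / (n_perm + 1)


def rsa_screen(neural_rdms: dict[str, RDM], model: RDM,
               nuisance: list[RDM] | None = None, q: float = 0.05,
               alternative: str = "greater", n_boot: int = 0,
               seed: int = 0, p_mode: str = "parametric",
               n_item_perm: int = 1000) -> list[RSAResult]:
    """Screen regions for model structure: (partial) Spearman per region,
    BH-FDR across regions, sorted by r (descending).

    ``p_mode="parametric"`` uses the t approximation on the pair vector (what
    the original analysis does; it ignores pair non-independence).
    ``p_mode="item_permutation"`` permutes item labels of each neural RDM
    instead — statistically safer when RDMs carry item-level structure.
    The default one-sided alternative tests for significantly *positive*
    correlations; FDR at any q < 0.5 can therefore never keep r <= 0.
    """
    if not neural_rdms:
        raise ValueError("no neural RDMs supplied")
    if p_mode not in ("parametric", "item_permutation"):
        raise ValueError(f"unknown p_mode {p_mode!r}")
    nuisance = nuisance or []
    model_vec, _ = vectorize_rdm(model)
    nuis_vecs = [vectorize_rdm(z)[0] for z in nuisance]
    names, rs, ps, ns, ses = [], [], [], [], []
    for name, rdm in neural_rdms.items():
        vec, _ = vectorize_rdm(rdm)
        ok = _complete_cases(vec, model_vec, *nuis_vecs)
        if p_mode == "item_permutation":
            r, p = item_permutation_p(rdm, model, nuisance, n_item_perm,
                                      seed=seed, alternative=alternative)
        else:
            r, p = partial_spearman(vec, model_vec, nuis_vecs,
                                    alternative=alternative)
        names.append(name)
        rs.append(r)
        ps.append(p)
        ns.append(int(ok.sum()))
        if n_boot > 0:
            ses.append(bootstrap_se(rdm, model, nuisance, n_boot=n_boot,
                                    seed=seed))
        else:
            ses.append(None)
    pvals = np.array([1.0 if np.isnan(p) else p for p in ps])
    kept = fdr_select(pvals, q=q) if q > 0 else np.zeros(len(pvals), dtype=bool)
    results = [
        RSAResult(connection=nm, model_kind=model.kind,
                  nuisance_kinds=tuple(z.kind for z in nuisance),
                  r=rs[i], p=ps[i], n_pairs=ns[i], boot_se=ses[i],
                  fdr_kept=bool(kept[i]))
        for i, nm in enumerate(names)
    ]
    return sorted(results, key=lambda x: (-(x.r if not np.isnan(x.r) else -np.inf)))


def results_table(results: list[RSAResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"connection": r.connection, "model": r.model_kind,
         "nuisance_set": ",".join(r.nuisance_kinds), "r": r.r, "p": r.p,
         "n_pairs": r.n_pairs, "boot_se": r.boot_se, "fdr_kept": r.fdr_kept}
        for r in results
    ])
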
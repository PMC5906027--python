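"""Synthetic cohort generator with planted representational ground truth.

Everything downstream of raw data collection is testable against this module:
it fabricates (i) a voxel template of disjoint contiguous "connections",
(ii) a cohort of contiguous lesion blobs, (iii) a low-dimensional semantic
item space with category structure and attribute spaces coupled to it at
controllable levels, (iv) per-connection item-by-voxel loading matrices that
make lesions degrade naming of semantically similar items together only in
"informative" connections, (v) binary naming responses from a logistic
item-failure model, and (vi) multi-arrangement trials measuring the item
spaces with rater noise.

All generators are pure functions of their arguments including the seed
(stream keys: stage name, entity id), so any stage can be reproduced in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit
from scipy.stats import spearmanr

from ._rng import stream
from .core import GridSpec, LesionCohort, NamingMatrix, Region, VoxelTemplate

__all__ = [
    "GroundTruth",
    "make_template",
    "make_item_space",
    "make_loadings",
    "simulate_lesions",
    "simulate_naming",
    "lesion_damage",
    "simulate_arrangements",
    "simulate_silhouettes",
    "simulate_transcriptions",
    "classical_mds",
]

#: attribute-target validation ceiling: attribute spaces in the emulated world
#: are meaningfully distinct from the semantic space (observed couplings are
#: r = 0.23-0.47), so near-unity targets are rejected as unattainable.
MAX_ATTR_TARGET = 0.9

DEFAULT_ATTRIBUTES = ("shape", "manipulation", "color", "motion")
#: default coupling levels of the four attribute spaces to the semantic space
DEFAULT_ATTR_TARGETS = {"shape": 0.35, "manipulation": 0.47,
                        "color": 0.23, "motion": 0.27}


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic cohort (for generation and test assertions)."""

    item_ids: list[str]
    categories: list[str]                       # per item
    item_embeddings: np.ndarray                 # (I, d) semantic space
    attribute_embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    attribute_weights: dict[str, float] = field(default_factory=dict)
    connection_loadings: dict[str, np.ndarray] = field(default_factory=dict)  # (I, V)
    informative_flags: dict[str, bool] = field(default_factory=dict)
    logistic_params: tuple[float, float] = (-2.0, 1.5)  # (beta0, beta1)
    seed: int = 0

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def semantic_rdm_values(self) -> np.ndarray:
        return squareform(pdist(self.item_embeddings))

    def attribute_rdm_values(self, attribute: str) -> np.ndarray:
        return squareform(pdist(self.attribute_embeddings[attribute]))

    def sidecar(self) -> dict:
        """JSON-serializable summary (seeds, parameters, flags) for manifests."""
        return {
            "seed": int(self.seed),
            "n_items": self.n_items,
            "categories": sorted(set(self.categories)),
            "dim": int(self.item_embeddings.shape[1]),
            "attribute_weights": {k: float(v) for k, v in self.attribute_weights.items()},
            "informative_flags": {k: bool(v) for k, v in self.informative_flags.items()},
            "logistic_params": [float(x) for x in self.logistic_params],
        }


# ---------------------------------------------------------------------------
# contiguous voxel-set growth (shared by template and lesion generators)
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_blob(grid: GridSpec, size: int, rng: np.random.Generator,
               free: np.ndarray | None = None) -> np.ndarray | None:
    """Grow one 6-connected blob of exactly ``size`` voxels; None if it stalls.

    ``free`` (bool over flat indices) restricts growth to unoccupied voxels.
    """
    if size == 0:
        return np.empty(0, dtype=np.int64)
    candidates = np.flatnonzero(free) if free is not None else np.arange(grid.n_voxels)
    if candidates.size == 0:
        return None
    start = int(rng.choice(candidates))
    in_blob = np.zeros(grid.n_voxels, dtype=bool)
    in_blob[start] = True
    frontier = [start]
    chosen = [start]
    shape = np.array(grid.shape)
    while len(chosen) < size:
        if not frontier:
            return None
        # random frontier voxel -> random admissible neighbor
        fi = int(rng.integers(len(frontier)))
        vox = frontier[fi]
        ijk = grid.unravel(np.array([vox]))[0]
        nbrs = ijk + _NEIGHBOR_OFFSETS
        ok = ((nbrs >= 0) & (nbrs < shape)).all(axis=1)
        nbrs = nbrs[ok]
        flat = grid.ravel(nbrs)
        admissible = flat[~in_blob[flat] & (free[flat] if free is not None else True)]
        if admissible.size == 0:
            frontier[fi] = frontier[-1]
            frontier.pop()
            continue
        new = int(rng.choice(admissible))
        in_blob[new] = True
        frontier.append(new)
        chosen.append(new)
    return np.array(sorted(chosen), dtype=np.int64)


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

def make_template(grid: GridSpec, n_connections: int, voxels_per_connection: int,
                  seed: int, kind: str = "connection",
                  max_restarts: int = 200) -> VoxelTemplate:
    """Place ``n_connections`` pairwise-disjoint contiguous voxel sets on the grid."""
    need = n_connections * voxels_per_connection
    if need > grid.n_voxels:
        raise ValueError(
            f"insufficient voxels: need {need} for {n_connections} regions of "
            f"{voxels_per_connection}, grid has {grid.n_voxels}"
        )
    rng = stream(seed, "template")
    free = np.ones(grid.n_voxels, dtype=bool)
    regions: dict[str, Region] = {}
    for c in range(n_connections):
        blob = None
        for _ in range(max_restarts):
            blob = _grow_blob(grid, voxels_per_connection, rng, free=free)
            if blob is not None:
                break
        if blob is None:
            raise ValueError(
                "insufficient voxels: free space too fragmented to place "
                f"contiguous region {c} of {voxels_per_connection} voxels"
            )
        free[blob] = False
        regions[f"conn_{c:03d}"] = Region(kind=kind, voxels=blob)
    return VoxelTemplate(grid=grid, regions=regions)


# ---------------------------------------------------------------------------
# item space
# ---------------------------------------------------------------------------

def _rdm_corr(a_emb: np.ndarray, b_emb: np.ndarray) -> float:
    return float(spearmanr(pdist(a_emb), pdist(b_emb)).statistic)


def _mix(E: np.ndarray, G: np.ndarray, w: float) -> np.ndarray:
    return w * E + (1.0 - w) * G


def _category_directions(n_categories: int, dim: int) -> np.ndarray:
    """Well-separated unit directions in the non-negative orthant.

    dim == 2: evenly spaced angles on the quarter circle; otherwise one-hot
    axes first, then normalized mixtures of consecutive axes once the axes
    run out.
    """
    if dim == 2:
        angles = np.linspace(0.1, np.pi / 2 - 0.1, n_categories)
        return np.column_stack([np.cos(angles), np.sin(angles)])
    dirs = []
    for c in range(n_categories):
        v = np.zeros(dim)
        if c < dim:
            v[c] = 1.0
        else:
            a = (c - dim) % dim
            v[a] = v[(a + 1) % dim] = 1.0 / np.sqrt(2)
        dirs.append(v)
    return np.array(dirs)


def make_item_space(n_items: int, n_categories: int, dim: int,
                    attr_corr_targets: dict[str, float] | None = None,
                    seed: int = 0, *,
                    within_category_sd: float = 0.4,
                    center_scale: float = 1.5, center_jitter: float = 0.25,
                    corr_tol: float = 0.15, max_retries: int = 5,
                    coupling_override: dict[str, float] | None = None) -> GroundTruth:
    """Semantic item space with category clusters, plus coupled attribute spaces.

    The semantic embedding uses non-negative feature-intensity coding: each
    category loads mainly on one axis (plus jitter), items scatter around
    their category center, and rows are normalized to a common norm. The
    non-negativity keeps the magnitude coding of :func:`make_loadings`
    monotone in the embedding (so lesion damage orders items the way the
    space does), and equal row norms decouple overall item difficulty from
    semantic position.

    Attribute embeddings follow ``w * semantic + (1 - w) * noise`` with ``w``
    found by bisection so that the Spearman correlation between the attribute
    RDM and the semantic RDM hits its target (checked on the generated
    instance, tolerance ``corr_tol``). ``coupling_override`` pins ``w``
    directly for named attributes (e.g. ``{"shape": 1.0}`` makes the shape
    space identical to the semantic space), bypassing the search.
    """
    if n_items % n_categories:
        raise ValueError("n_items must be divisible by n_categories")
    if attr_corr_targets is None:
        attr_corr_targets = dict(DEFAULT_ATTR_TARGETS)
    coupling_override = coupling_override or {}
    for name, t in attr_corr_targets.items():
        if name in coupling_override:
            continue
        if not 0.0 < t <= MAX_ATTR_TARGET:
            raise ValueError(
                f"unattainable target correlation {t} for attribute {name!r} "
                f"(must lie in (0, {MAX_ATTR_TARGET}])"
            )

    rng = stream(seed, "item_space")
    per_cat = n_items // n_categories
    categories = [f"cat{c}" for c in range(n_categories) for _ in range(per_cat)]
    item_ids = [f"item_{i:03d}" for i in range(n_items)]
    centers = center_scale * _category_directions(n_categories, dim)
    centers += center_jitter * np.abs(rng.normal(size=(n_categories, dim)))
    E = np.repeat(centers, per_cat, axis=0) + within_category_sd * rng.normal(
        size=(n_items, dim))
    E = np.clip(E, 0.0, None)
    E = E / (np.linalg.norm(E, axis=1, keepdims=True) + 1e-12) * np.sqrt(dim)

    truth = GroundTruth(item_ids=item_ids, categories=categories,
                        item_embeddings=E, seed=seed)

    names = list(dict.fromkeys(list(attr_corr_targets) + list(coupling_override)))
    for name in names:
        arng = stream(seed, "attribute", name)
        if name in coupling_override:
            w = float(coupling_override[name])
            G = arng.normal(size=E.shape) * E.std()
            truth.attribute_embeddings[name] = _mix(E, G, w)
            truth.attribute_weights[name] = w
            continue
        target = attr_corr_targets[name]
        found = None
        for _retry in range(max_retries):
            G = arng.normal(size=E.shape) * E.std()
            lo, hi = 0.0, 1.0
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if _rdm_corr(_mix(E, G, mid), E) < target:
                    lo = mid
                else:
                    hi = mid
            w = 0.5 * (lo + hi)
            r = _rdm_corr(_mix(E, G, w), E)
            if abs(r - target) <= corr_tol:
                found = (w, G)
                break
        if found is None:
            raise ValueError(
                f"unattainable target correlation {target} for attribute {name!r} "
                f"after {max_retries} retries"
            )
        w, G = found
        truth.attribute_embeddings[name] = _mix(E, G, w)
        truth.attribute_weights[name] = w
    return truth


# ---------------------------------------------------------------------------
# connection loadings
# ---------------------------------------------------------------------------

def _segment_dims(grid: GridSpec, region: Region, dim: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Assign each region voxel one semantic dimension, in compact spatial cells.

    The region is partitioned into ``dim`` spatially compact cells (k-means on
    voxel coordinates), so a focal lesion inside the region damages a biased
    mix of dimensions — different segments of a tract carry different aspects
    of the represented space. Falls back to round-robin for tiny regions.
    """
    from scipy.cluster.vq import kmeans2

    V = region.n_voxels
    if V < dim * 2:
        return rng.permutation(dim)[np.arange(V) % dim]
    coords = grid.unravel(region.voxels).astype(float)
    _, labels = kmeans2(coords, dim, minit="++",
                        seed=int(rng.integers(2**31 - 1)))
    return rng.permutation(dim)[labels]


def make_loadings(template: VoxelTemplate, truth: GroundTruth,
                  informative_ids: list[str], gain: float, seed: int,
                  damage_scale: float = 24.0) -> GroundTruth:
    """Attach an items x voxels loading matrix to every template region.

    Each voxel in an informative region carries ``gain * E[:, dim(v)] + noise``
    — a fixed (sparse) linear projection of the semantic embedding, with the
    projected dimension constant over a compact spatial cell of the region.
    Null regions get pure noise, so at ``gain = 0`` the two are
    indistinguishable. Every loading column is then rescaled so its
    item-averaged magnitude is ``damage_scale / V``: a fully lesioned region
    contributes ``damage_scale`` to the mean item's failure logit, and —
    because the per-voxel mean is exact — overall lesion burden alone carries
    no item information; only *which* cells are hit does.
    """
    unknown = set(informative_ids) - set(template.names)
    if unknown:
        raise ValueError(f"unknown connection name(s): {sorted(unknown)}")
    E = truth.item_embeddings
    n_items, dim = E.shape
    for name, region in template.regions.items():
        rng = stream(seed, "loadings", name)
        V = region.n_voxels
        if V == 0:
            truth.connection_loadings[name] = np.zeros((n_items, 0))
            truth.informative_flags[name] = name in informative_ids
            continue
        dims = _segment_dims(template.grid, region, dim, rng)
        base = E[:, dims]
        # noise keyed by item id so reordering items reorders loading rows
        noise = np.stack([stream(seed, "loadings", name, item).normal(size=V)
                          for item in truth.item_ids])
        informative = name in informative_ids
        L = gain * base + noise if informative else noise
        col_mean = np.abs(L).mean(axis=0)
        L = L / np.where(col_mean > 0, col_mean, 1.0) * (damage_scale / V)
        truth.connection_loadings[name] = L
        truth.informative_flags[name] = bool(informative)
    return truth


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def simulate_lesions(template: VoxelTemplate, n_patients: int,
                     size_range: tuple[int, int] = (30, 300), seed: int = 0,
                     n_foci: tuple[int, int] = (1, 1),
                     confine_to_regions: bool = False,
                     stroke_fraction: float = 67 / 80) -> LesionCohort:
    """Contiguous lesion blobs per patient, focus size uniform in ``size_range``.

    By default each patient receives one contiguous blob grown from a uniform
    random seed voxel (6-connectivity). The multifocal extension draws
    ``n_foci`` foci per patient, each grown in a distinct randomly chosen
    template region (``confine_to_regions=True`` keeps each focus inside its
    region, which makes lesion patterns causally independent across regions —
    the configuration the planted-recovery demonstration uses).

    Etiology labels emulate the 67 stroke / 13 TBI cohort composition;
    hemisphere is assigned from the lesion centroid relative to the grid
    midline (the synthetic grid has no anatomy, the label only supports
    subset reruns).
    """
    lo, hi = size_range
    if lo < 0 or hi < lo or hi > template.grid.n_voxels:
        raise ValueError(f"size_range {size_range} outside grid capacity")
    if n_foci[0] < 1 or n_foci[1] < n_foci[0]:
        raise ValueError(f"invalid n_foci range {n_foci}")
    if n_foci[1] > len(template.regions) and confine_to_regions:
        raise ValueError("more foci than template regions")
    grid = template.grid
    names = template.names
    n_stroke = int(round(n_patients * stroke_fraction))
    etiologies = np.array(["stroke"] * n_stroke + ["tbi"] * (n_patients - n_stroke))
    etiologies = stream(seed, "etiology").permutation(etiologies)

    rows, masks = [], {}
    midline = grid.shape[0] / 2.0
    for p in range(n_patients):
        pid = f"p{p:03d}"
        rng = stream(seed, "lesion", p)
        k = int(rng.integers(n_foci[0], n_foci[1] + 1))
        parts = []
        if k == 1 and not confine_to_regions:
            size = int(rng.integers(lo, hi + 1))
            blob = _grow_blob(grid, size, rng)
            if blob is None:
                raise RuntimeError(f"could not grow lesion of size {size}")
            parts.append(blob)
        else:
            regions = rng.choice(len(names), size=k, replace=False)
            for c in regions:
                size = int(rng.integers(lo, hi + 1))
                free = None
                if confine_to_regions:
                    free = np.zeros(grid.n_voxels, dtype=bool)
                    free[template.regions[names[c]].voxels] = True
                    seed_vox = template.regions[names[c]].voxels
                    size = min(size, len(seed_vox))
                blob = _grow_blob(grid, size, rng, free=free)
                if blob is not None:
                    parts.append(blob)
        vox = (np.unique(np.concatenate(parts)) if parts
               else np.empty(0, dtype=np.int64))
        if vox.size:
            hemi = "L" if grid.unravel(vox)[:, 0].mean() < midline else "R"
        else:
            hemi = "L"
        rows.append({"patient_id": pid, "etiology": str(etiologies[p]),
                     "hemisphere": hemi})
        masks[pid] = vox
    return LesionCohort(grid=grid, patients=pd.DataFrame(rows), masks=masks)


# ---------------------------------------------------------------------------
# naming responses
# ---------------------------------------------------------------------------

def lesion_damage(cohort: LesionCohort, template: VoxelTemplate,
                  truth: GroundTruth) -> np.ndarray:
    """Patients x items summed absolute loading of lesioned voxels."""
    missing = [n for n in template.names if n not in truth.connection_loadings]
    if missing:
        raise ValueError(f"loadings missing for regions: {missing}")
    abs_loadings = {n: np.abs(truth.connection_loadings[n]) for n in template.names}
    damage = np.zeros((cohort.n_patients, truth.n_items))
    for pi, pid in enumerate(cohort.patient_ids):
        mask = cohort.masks[pid]
        if mask.size == 0:
            continue
        for name, region in template.regions.items():
            inter = np.intersect1d(region.voxels, mask, assume_unique=True)
            if inter.size:
                col_idx = np.searchsorted(region.voxels, inter)
                damage[pi] += abs_loadings[name][:, col_idx].sum(axis=1)
    return damage


def simulate_naming(cohort: LesionCohort, template: VoxelTemplate,
                    truth: GroundTruth, seed: int = 0,
                    target_accuracy: float | None = None,
                    item_difficulty_sd: float = 0.0) -> NamingMatrix:
    """Binary naming matrix from the logistic item-failure model.

    ``P(item i wrong for patient p) = expit(b0 + b1 * sum_c sum_v lesion(p, v)
    * |loading_c(i, v)|)`` — damage to voxels that load on an item raises that
    item's failure probability, and shared loadings across semantically
    similar items (informative connections) make their failures co-occur.

    With ``target_accuracy`` set, the intercept ``b0`` is solved (bisection on
    the realized cohort damage, deterministic given the seed chain) so the
    grand mean naming accuracy matches the target; the solved value replaces
    ``b0`` in ``truth.logistic_params``. ``item_difficulty_sd`` adds a
    Gaussian per-item intercept, widening the item accuracy span the way
    heterogeneous word frequency / age-of-acquisition does, without coupling
    difficulty to the semantic space.
    """
    from scipy.optimize import brentq

    b0, b1 = truth.logistic_params
    damage = lesion_damage(cohort, template, truth)
    difficulty = 0.0
    if item_difficulty_sd > 0:
        difficulty = item_difficulty_sd * stream(seed, "difficulty").normal(
            size=truth.n_items)
    if target_accuracy is not None:
        if not 0.0 < target_accuracy < 1.0:
            raise ValueError("target_accuracy must lie in (0, 1)")

        def gap(b):
            return expit(b + difficulty + b1 * damage).mean() - (1.0 - target_accuracy)

        b0 = brentq(gap, -500.0, 500.0)
        truth.logistic_params = (float(b0), b1)
    p_wrong = expit(b0 + difficulty + b1 * damage)
    rng = stream(seed, "naming")
    wrong = rng.random(size=p_wrong.shape) < p_wrong
    return NamingMatrix(cohort.patient_ids, truth.item_ids,
                        (~wrong).astype(np.uint8))


# ---------------------------------------------------------------------------
# multi-arrangement trials
# ---------------------------------------------------------------------------

def classical_mds(dissim: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson scaling: coordinates whose distances best match ``dissim``."""
    n = dissim.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dissim ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def simulate_arrangements(truth: GroundTruth, n_raters: int = 20,
                          noise_sd: float = 0.1, trials_per_rater: int = 8,
                          seed: int = 0, attribute: str | None = None,
                          items: list[str] | None = None) -> pd.DataFrame:
    """Multi-arrangement trials: 2-D screen coordinates expressing item distances.

    The canonical layout is the 2-D classical-MDS projection of the chosen
    embedding (semantic by default, or a named attribute), normalized to unit
    RMS pairwise distance. Each trial applies a random rotation/scale (the
    aggregator must be invariant to those) and adds Gaussian coordinate noise.
    Per rater, the first trial shows all items and later trials random
    subsets. Returns a table with columns rater, trial, item, x, y.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    emb = (truth.item_embeddings if attribute is None
           else truth.attribute_embeddings[attribute])
    ids = list(truth.item_ids)
    if items is not None:
        idx = [ids.index(i) for i in items]
        emb, ids = emb[idx], list(items)
    n = len(ids)
    layout = classical_mds(squareform(pdist(emb)), 2)
    d = pdist(layout)
    rms = np.sqrt((d ** 2).mean())
    if rms > 0:
        layout = layout / rms

    rows = []
    key = attribute or "semantic"
    for r in range(n_raters):
        rng = stream(seed, "arrangement", key, r)
        for t in range(trials_per_rater):
            if t == 0:
                sel = np.arange(n)
            else:
                k = int(rng.integers(max(3, n // 3), n + 1))
                sel = rng.choice(n, size=k, replace=False)
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            scale = rng.uniform(0.8, 1.2)
            coords = scale * layout[sel] @ rot.T
            coords = coords + noise_sd * rng.normal(size=coords.shape)
            for j, ii in enumerate(sel):
                rows.append((r, t, ids[ii], coords[j, 0], coords[j, 1]))
    return pd.DataFrame(rows, columns=["rater", "trial", "item", "x", "y"])


# ---------------------------------------------------------------------------
# stimulus descriptors (silhouettes, transcriptions) for the control RDMs
# ---------------------------------------------------------------------------

def simulate_silhouettes(truth: GroundTruth, image_shape: tuple[int, int] = (32, 32),
                         seed: int = 0) -> dict[str, np.ndarray]:
    """Binary object silhouettes: one filled ellipse per item.

    Ellipse geometry is driven by the item's shape-attribute embedding when
    present (so visually similar shapes yield overlapping silhouettes),
    otherwise by the semantic embedding.
    """
    emb = truth.attribute_embeddings.get("shape", truth.item_embeddings)
    z = (emb - emb.mean(axis=0)) / (emb.std(axis=0) + 1e-12)
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    out = {}
    for i, item in enumerate(truth.item_ids):
        rng = stream(seed, "silhouette", item)
        cx = w / 2 + np.clip(z[i, 0], -2, 2) * w / 8
        cy = h / 2 + np.clip(z[i, 1 % z.shape[1]], -2, 2) * h / 8
        a = w / 5 * (1 + 0.3 * np.tanh(z[i, 2 % z.shape[1]]))
        b = h / 5 * (1 + 0.3 * np.tanh(z[i, 3 % z.shape[1]]))
        a += rng.uniform(-0.5, 0.5)
        b += rng.uniform(-0.5, 0.5)
        out[item] = (((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0).astype(np.uint8)
    return out


_ONSETS = ["b", "p", "m", "f", "d", "t", "n", "l", "g", "k", "h",
           "j", "q", "x", "zh", "ch", "sh", "r", "z", "c", "s", ""]
_RHYMES = ["a", "o", "e", "i", "u", "ai", "ei", "ao", "ou", "an", "en",
           "ang", "eng", "ong", "ia", "ie", "iao", "iu", "ian", "in", "uan"]


def simulate_transcriptions(item_ids: list[str], seed: int = 0,
                            syllables_range: tuple[int, int] = (1, 3)):
    """Random Mandarin-like syllable transcriptions (onset/rhyme units) per item."""
    from .behavior import SyllableTranscription

    out = []
    for item in item_ids:
        rng = stream(seed, "transcription", item)
        n_syl = int(rng.integers(syllables_range[0], syllables_range[1] + 1))
        syls = [(str(rng.choice(_ONSETS)), str(rng.choice(_RHYMES)))
                for _ in range(n_syl)]
        out.append(SyllableTranscription(item_id=item, syllables=syls))
    return out
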
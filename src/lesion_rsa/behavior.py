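"""Behavioral RDM construction.

Semantic and modality-specific attribute RDMs come from multi-arrangement
trials (screen distances); control RDMs come from stimulus descriptors:
silhouette overlap (early visual), shared sub-syllabic units (phonological),
and category membership (categorical).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .rdm import RDM

__all__ = [
    "SyllableTranscription",
    "aggregate_arrangement",
    "visual_rdm",
    "phonological_rdm",
    "categorical_rdm",
    "fill_missing_attribute",
    "read_transcriptions",
]


@dataclass(frozen=True)
class SyllableTranscription:
    """Onset/rhyme ("shengmu"/"yunmu") decomposition of one item's name.

    ``syllables`` is an ordered list of (onset, rhyme) pairs; an empty-string
    onset marks a syllable with no onset consonant.
    """

    item_id: str
    syllables: list[tuple[str, str]]

    def units(self) -> Counter:
        """Multiset of sub-syllabic units, position disregarded."""
        c: Counter = Counter()
        for onset, rhyme in self.syllables:
            if onset:
                c[onset] += 1
            if rhyme:
                c[rhyme] += 1
        return c


def read_transcriptions(path: str | Path) -> list[SyllableTranscription]:
    """TSV with columns item, syllable_index, onset, rhyme."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for item, grp in df.groupby("item", sort=False):
        grp = grp.sort_values("syllable_index")
        out.append(SyllableTranscription(
            item_id=str(item),
            syllables=[(str(o), str(r)) for o, r in zip(grp["onset"], grp["rhyme"])],
        ))
    return out


# ---------------------------------------------------------------------------

def aggregate_arrangement(trials: pd.DataFrame, item_ids: list[str],
                          kind: str = "semantic") -> RDM:
    """Aggregate multi-arrangement trials into one RDM.

    Per trial, Euclidean screen distances are scaled to unit RMS over that
    trial's pairs (removing arbitrary screen scale), then each cell is the
    mean of its scaled distances across all trials containing both items.
    Pairs never co-presented become missing cells (with a warning).
    """
    n = len(item_ids)
    index = {it: i for i, it in enumerate(item_ids)}
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for (_, _), grp in trials.groupby(["rater", "trial"], sort=True):
        items = [index[i] for i in grp["item"]]
        coords = grp[["x", "y"]].to_numpy(dtype=float)
        if len(items) < 2:
            continue
        d = pdist(coords)
        rms = np.sqrt((d ** 2).mean())
        if rms == 0:
            continue
        dm = squareform(d / rms)
        idx = np.array(items)
        sums[np.ix_(idx, idx)] += dm
        counts[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        values = sums / counts
    np.fill_diagonal(values, 0.0)
    off = ~np.eye(n, dtype=bool)
    n_missing = int((counts[off] == 0).sum()) // 2
    if n_missing:
        warnings.warn(f"{n_missing} item pair(s) never co-presented; cells set missing",
                      stacklevel=2)
    return RDM(list(item_ids), values, kind)


def visual_rdm(silhouettes: dict[str, np.ndarray]) -> RDM:
    """Early-visual control: 1 - Jaccard overlap of binary object silhouettes."""
    items = list(silhouettes)
    imgs = [np.asarray(silhouettes[i]) != 0 for i in items]
    shapes = {im.shape for im in imgs}
    if len(shapes) > 1:
        raise ValueError(f"silhouettes must share one pixel grid, got {shapes}")
    flat = np.array([im.ravel() for im in imgs])
    inter = (flat[:, None, :] & flat[None, :, :]).sum(axis=2)
    union = (flat[:, None, :] | flat[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        values = 1.0 - inter / union  # union == 0 -> NaN (both empty, undefined)
    np.fill_diagonal(values, np.where(np.diagonal(union) > 0, 0.0, np.nan))
    off = ~np.eye(len(items), dtype=bool)
    if np.isnan(values[off]).any():
        warnings.warn("empty silhouette pair(s): Jaccard undefined, cells set missing",
                      stacklevel=2)
    return RDM(items, values, "visual")


def phonological_rdm(transcriptions: list[SyllableTranscription]) -> RDM:
    """Phonological control: 1 - Dice proportion of shared sub-syllabic units.

    Units (onsets and rhymes) are pooled per item regardless of position;
    the shared proportion is ``2 * |multiset intersection| / (|A| + |B|)``.
    """
    items = [t.item_id for t in transcriptions]
    units = [t.units() for t in transcriptions]
    for item, u in zip(items, units):
        if sum(u.values()) == 0:
            raise ValueError(f"empty transcription for item {item!r}")
    n = len(items)
    values = np.zeros((n, n))
    sizes = [sum(u.values()) for u in units]
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((units[i] & units[j]).values())
            dice = 2.0 * shared / (sizes[i] + sizes[j])
            values[i, j] = values[j, i] = 1.0 - dice
    return RDM(items, values, "phonological")


def categorical_rdm(categories: dict[str, str]) -> RDM:
    """Within-category pairs 0, between-category pairs 1 (dissimilarity coding)."""
    items = list(categories)
    labels = np.array([categories[i] for i in items])
    values = (labels[:, None] != labels[None, :]).astype(float)
    return RDM(items, values, "categorical")


def fill_missing_attribute(rdm: RDM, mode: str) -> RDM:
    """Resolve missing attribute cells: "one" marks them most dissimilar (1),
    "nan" leaves them missing for complete-case deletion downstream."""
    if mode == "one":
        values = rdm.values.copy()
        missing = np.isnan(values)
        off = ~np.eye(rdm.n_items, dtype=bool)
        values[missing & off] = 1.0
        values[missing & ~off] = 0.0
        return rdm.with_values(values)
    if mode == "nan":
        return rdm
    raise ValueError(f"unknown missing-value mode {mode!r} (expected 'one' or 'nan')")
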
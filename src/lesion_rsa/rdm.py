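"""The representational dissimilarity matrix (RDM) container.

An RDM is a symmetric items x items matrix of pairwise dissimilarities with an
optional set of undefined (missing) cells, stored as NaN. It is the common
currency of the package: behavioral models, control matrices, and the
decoding-derived neural matrices all live in this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RDM"]

#: kinds whose defined values must lie in [0, 1]
_UNIT_RANGE_KINDS = {"visual", "phonological", "categorical", "neural"}

KNOWN_KINDS = (
    "semantic", "shape", "manipulation", "color", "motion",
    "visual", "phonological", "categorical", "neural",
)


@dataclass(frozen=True)
class RDM:
    item_ids: list[str]
    values: np.ndarray  # (I, I) float, NaN where undefined
    kind: str = "semantic"

    def __post_init__(self):
        items = list(self.item_ids)
        vals = np.array(self.values, dtype=float)
        n = len(items)
        if vals.shape != (n, n):
            raise ValueError(f"values shape {vals.shape} does not match {n} items")
        defined = ~np.isnan(vals)
        if not (defined == defined.T).all():
            raise ValueError("missing-cell pattern must be symmetric")
        both = defined & defined.T
        if not np.allclose(vals[both], vals.T[both], rtol=0, atol=1e-9, equal_nan=True):
            raise ValueError("defined cells must be symmetric")
        diag = np.diagonal(vals)
        ok = np.isnan(diag) | (np.abs(diag) < 1e-12)
        if not ok.all():
            raise ValueError("diagonal must be 0 where defined")
        if self.kind in _UNIT_RANGE_KINDS:
            v = vals[defined]
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError(f"{self.kind} RDM values must lie in [0, 1]")
        object.__setattr__(self, "item_ids", items)
        object.__setattr__(self, "values", vals)

    # -- basic accessors -------------------------------------------------
    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing_pairs(self) -> int:
        iu = np.triu_indices(self.n_items, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def with_values(self, values: np.ndarray) -> "RDM":
        return replace(self, values=values)

    def subset(self, items: list[str]) -> "RDM":
        idx = [self.item_ids.index(i) for i in items]
        return RDM(items, self.values[np.ix_(idx, idx)], self.kind)

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        pd.DataFrame(self.values, index=self.item_ids,
                     columns=self.item_ids).to_csv(path)
        if sidecar:
            iu = np.triu_indices(self.n_items, k=1)
            missing = [
                [self.item_ids[a], self.item_ids[b]]
                for a, b in zip(*iu)
                if np.isnan(self.values[a, b])
            ]
            meta = {"kind": self.kind, "item_ids": self.item_ids,
                    "missing_pairs": missing}
            path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, kind: str | None = None) -> "RDM":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        if kind is None:
            side = path.with_suffix(".json")
            kind = json.loads(side.read_text())["kind"] if side.exists() else "semantic"
        return cls(list(df.index.astype(str)), df.to_numpy(), kind)


def percentile_transform(rdm: RDM) -> RDM:
    """Map defined off-diagonal values to their percentile (display only).

    Ranks are preserved, so any Spearman statistic computed downstream is
    unchanged; this transform exists purely for comparable heatmap color
    scales and is never applied before correlation.
    """
    from scipy.stats import rankdata

    vals = rdm.values.copy()
    iu = np.triu_indices(rdm.n_items, k=1)
    v = vals[iu]
    ok = ~np.isnan(v)
    pct = np.full_like(v, np.nan)
    if ok.sum():
        # percentile as a fraction so every RDM kind keeps its [0, 1] contract
        pct[ok] = rankdata(v[ok]) / ok.sum()
    vals[iu] = pct
    vals.T[iu] = pct
    return rdm.with_values(vals)
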
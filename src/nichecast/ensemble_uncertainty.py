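"""Consensus, between-model variance and range-change mapping.

A :class:`MapStack` holds aligned suitability maps from several modelling
exercises (different families, or one family at several prevalence
levels). Consensus is the cellwise mean, median, or the first principal
component of the cells × members matrix — the "axis of agreement" —
rescaled to [0, 1] and oriented so it correlates positively with the
mean. The cellwise sample variance maps where the members disagree, i.e.
where the projection is most uncertain.

Binarized current and future maps combine into a four-class range-change
map: stable (in range now and later), contraction (lost), expansion
(gained), absent (never in range).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["MapStack", "RangeChangeMap", "consensus", "variance_map",
           "binarize", "range_change", "RANGE_CLASSES"]


@dataclass
class MapStack:
    """Aligned per-cell suitability maps from >= 2 modelling exercises."""

    member_ids: list[str]
    maps: np.ndarray          # (n_members, n_rows, n_cols), NaN off-mask
    mask: np.ndarray          # shared validity mask

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3 or self.maps.shape[0] != len(self.member_ids):
            raise ValueError("maps must be (n_members, n_rows, n_cols)")
        if self.maps.shape[1:] != self.mask.shape:
            raise ValueError("member maps and mask disagree on geometry")

    @classmethod
    def from_dict(cls, members: Mapping[str, np.ndarray], mask: np.ndarray
                  ) -> "MapStack":
        ids = list(members)
        return cls(ids, np.stack([members[i] for i in ids]), mask)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    def values(self) -> np.ndarray:
        """(n_valid_cells, n_members) matrix of member values."""
        return self.maps[:, self.mask].T


def consensus(stack: MapStack, method: str = "median") -> np.ndarray:
    """Cellwise consensus map: ``mean``, ``median`` or ``pca1``.

    ``pca1`` projects the cells × members matrix (members centered) onto
    its first principal axis, orients the scores to correlate positively
    with the cellwise mean, and min-max rescales them to [0, 1].
    """
    if stack.n_members < 2:
        raise ValueError("consensus needs at least 2 members")
    out = np.full(stack.mask.shape, np.nan)
    if method == "mean":
        out[stack.mask] = stack.values().mean(axis=1)
    elif method == "median":
        out[stack.mask] = np.median(stack.values(), axis=1)
    elif method == "pca1":
        V = stack.values()
        centered = V - V.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        scores = centered @ vt[0]
        mean_map = V.mean(axis=1)
        if np.corrcoef(scores, mean_map)[0, 1] < 0:
            scores = -scores
        rng_ = scores.max() - scores.min()
        scores = (scores - scores.min()) / rng_ if rng_ > 0 else np.full_like(scores, 0.5)
        out[stack.mask] = scores
    else:
        raise ValueError(f"unknown consensus method {method!r}")
    return out


def pca1_explained(stack: MapStack) -> float:
    """Fraction of between-member variance carried by the first axis."""
    centered = stack.values() - stack.values().mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    total = float((s**2).sum())
    return float(s[0] ** 2 / total) if total > 0 else 1.0


def variance_map(stack: MapStack) -> np.ndarray:
    """Cellwise sample variance (denominator n−1) across members."""
    if stack.n_members < 2:
        raise ValueError("variance needs at least 2 members")
    out = np.full(stack.mask.shape, np.nan)
    out[stack.mask] = stack.values().var(axis=1, ddof=1)
    return out


def binarize(suitability: np.ndarray, threshold: float) -> np.ndarray:
    """Presence/absence map: cell >= threshold → 1, else 0 (NaN preserved)."""
    out = np.where(suitability >= threshold, 1.0, 0.0)
    out[np.isnan(suitability)] = np.nan
    return out


#: Range-change class codes (−1 marks masked cells).
RANGE_CLASSES = {"absent": 0, "stable": 1, "contraction": 2, "expansion": 3}


@dataclass
class RangeChangeMap:
    """Four-class current-vs-future range comparison."""

    classes: np.ndarray  # int codes per RANGE_CLASSES, −1 off-mask
    mask: np.ndarray

    def counts(self) -> dict[str, int]:
        """Per-class cell counts; they partition the valid cells."""
        return {
            name: int((self.classes[self.mask] == code).sum())
            for name, code in RANGE_CLASSES.items()
        }


def range_change(current_bin: np.ndarray, future_bin: np.ndarray) -> RangeChangeMap:
    """Classify each valid cell from its binarized current/future status.

    (1,1) → stable, (1,0) → contraction, (0,1) → expansion, (0,0) → absent.
    """
    if current_bin.shape != future_bin.shape:
        raise ValueError("current and future maps disagree on geometry")
    mask = np.isfinite(current_bin) & np.isfinite(future_bin)
    cur = current_bin.astype(float)
    fut = future_bin.astype(float)
    classes = np.full(cur.shape, -1, dtype=int)
    classes[mask & (cur == 1) & (fut == 1)] = RANGE_CLASSES["stable"]
    classes[mask & (cur == 1) & (fut == 0)] = RANGE_CLASSES["contraction"]
    classes[mask & (cur == 0) & (fut == 1)] = RANGE_CLASSES["expansion"]
    classes[mask & (cur == 0) & (fut == 0)] = RANGE_CLASSES["absent"]
    return RangeChangeMap(classes=classes, mask=mask)
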
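"""Leakage-free splitting and near-duplicate removal.

Patches from one cell pair must never straddle the train/test boundary:
frames of the same synapse (and synapses of the same cells) are nearly
identical images, so a patch-level split would leak.  Splitting therefore
operates on (presynaptic, postsynaptic) cell-ID groups, and a similarity
pass removes exact duplicates and extremely overlapping patches first.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .reconstruct_io import Patch

__all__ = ["SplitSpec", "deduplicate", "bbox_iou", "split_by_cell", "group_key"]


@dataclass(frozen=True)
class SplitSpec:
    """Fractions apply to cell groups, not patches (leakage beats balance)."""

    fractions: tuple[float, ...] = (0.8, 0.1, 0.1)
    seed: int = 0
    dedup_threshold: float = 0.5

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must be >=0 and sum to 1, got {self.fractions}")
        if not (0.0 <= self.dedup_threshold <= 1.0):
            raise ValueError("dedup_threshold must be in [0, 1]")


def group_key(p: Patch) -> tuple[str, str]:
    return (p.pre_cell_id, p.post_cell_id)


def bbox_iou(c1, c2, size: int) -> float:
    """Intersection-over-union of two axis-aligned size x size boxes."""
    dx = max(0.0, size - abs(float(c1[0]) - float(c2[0])))
    dy = max(0.0, size - abs(float(c1[1]) - float(c2[1])))
    inter = dx * dy
    union = 2.0 * size * size - inter
    return inter / union if union > 0 else 0.0


def deduplicate(
    patches: list[Patch],
    threshold: float = 0.5,
    *,
    use_pixels: bool = True,
) -> list[Patch]:
    """Greedy earliest-kept filter of duplicate / overlapping patches.

    Exact duplicates (identical pixel content when ``use_pixels``,
    identical centre+z otherwise) are always removed.  Among the survivors
    on the same section, a patch is dropped when its bounding box overlaps
    an already-kept patch with IoU > ``threshold``.  The operation is
    idempotent and keeps the earliest-indexed patch of any conflicting set.
    """
    kept: list[Patch] = []
    seen_hashes: set[str] = set()
    for p in patches:
        if use_pixels and p.image is not None:
            h = hashlib.sha1(np.ascontiguousarray(p.image).tobytes()).hexdigest()
            if h in seen_hashes:
                continue
        else:
            h = None
        exact = any(
            q.z_index == p.z_index and q.center == p.center for q in kept
        )
        if exact:
            continue
        clash = any(
            q.z_index == p.z_index
            and bbox_iou(p.center, q.center, p.size) > threshold
            for q in kept
        )
        if clash:
            continue
        if h is not None:
            seen_hashes.add(h)
        kept.append(p)
    return kept


def split_by_cell(
    patches: list[Patch],
    spec: SplitSpec,
) -> tuple[list[Patch], ...]:
    """Split patches into len(fractions) lists with disjoint cell groups.

    Groups (pre, post cell-ID pairs) are shuffled deterministically under
    ``spec.seed`` and allocated to splits by largest-remainder rounding of
    ``spec.fractions`` applied to the group count.  Every non-zero fraction
    receives at least one group; fewer groups than non-zero fractions is an
    error.
    """
    groups = sorted({group_key(p) for p in patches})
    n_nonzero = sum(f > 0 for f in spec.fractions)
    if len(groups) < n_nonzero:
        raise ValueError(
            f"{len(groups)} cell groups cannot fill {n_nonzero} splits"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(groups))
    shuffled = [groups[i] for i in order]

    n = len(groups)
    fr = np.asarray(spec.fractions, dtype=float)
    counts = np.floor(fr * n).astype(int)
    counts[fr > 0] = np.maximum(counts[fr > 0], 1)
    # largest remainder for the leftovers
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    rema = fr * n - np.floor(fr * n)
    for i in np.argsort(-rema):
        if counts.sum() >= n:
            break
        if fr[i] > 0:
            counts[i] += 1
    while counts.sum() < n:
        counts[np.argmax(fr)] += 1

    assignment: dict[tuple[str, str], int] = {}
    start = 0
    for split_idx, c in enumerate(counts):
        for g in shuffled[start : start + c]:
            assignment[g] = split_idx
        start += c
    out: tuple[list[Patch], ...] = tuple([] for _ in spec.fractions)
    for p in patches:
        out[assignment[group_key(p)]].append(p)
    return out
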
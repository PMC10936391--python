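"""Class activation maps and their region decomposition.

With a head of global average pooling followed by a *bias-free* linear
layer, the class-c activation map

    cam_c[h, w] = sum_k  W[c, k] * F[k, h, w]

projects the head weights onto the feature map at each spatial location,
"cutting out" the pooling step.  Because pooling is a spatial mean and
the head has no bias, the spatial mean of ``cam_c`` equals the class-c
logit exactly — a conservation identity this module checks and tests
rely on.

For region analysis the coarse map is bilinearly upsampled to the input
resolution, thresholded at its Otsu level, and the suprathreshold mask is
split into disjoint catchment basins by a watershed on the negated map
seeded from the mask's connected components.  Regions smaller than an
area threshold (5,000 px at the 512-px full scale, scaled by
``(input_size/512)**2`` otherwise) are discarded; each surviving region
reports its area, centroid and mean activation in raw (unnormalised)
units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, segmentation
from skimage.filters import threshold_otsu
from skimage.transform import resize

from . import _nn
from .reconstruct_io import Patch

__all__ = [
    "ActivationMap", "ActivationRegion", "compute_cam", "segment_cam",
    "scaled_area_threshold", "FULL_SCALE_INPUT", "FULL_SCALE_AREA_THRESHOLD",
]

FULL_SCALE_INPUT = 512
FULL_SCALE_AREA_THRESHOLD = 5000


@dataclass
class ActivationMap:
    values: np.ndarray             # (H', W') raw activation units
    class_index: int
    logit: float
    patch: Patch | None = None


@dataclass(frozen=True)
class ActivationRegion:
    region_id: int
    area: int                      # pixels, upsampled-map coordinates
    centroid: tuple[float, float]  # (x, y)
    mean_intensity: float          # raw activation units


def scaled_area_threshold(input_size: int,
                          base: int = FULL_SCALE_AREA_THRESHOLD) -> float:
    """Area threshold rescaled from the 512-px reference resolution."""
    return base * (input_size / FULL_SCALE_INPUT) ** 2


def compute_cam(model, patch: Patch, class_index: int,
                input_size: int = 128) -> ActivationMap:
    """Weight-projected activation map for one patch and class.

    Requires a GAP + bias-free-linear head; a head with a bias term is
    rejected because the mean-equals-logit identity would not hold.
    """
    if getattr(model.head, "b", None) is not None:
        raise ValueError("CAM requires a bias-free head (mean != logit otherwise)")
    from .model import patches_to_array

    x = patches_to_array([patch], input_size)
    feats = model.features(x)[0]                       # (K, H', W')
    logits = model.head.forward(_nn.global_avg_pool(feats[None]))[0]
    if not 0 <= class_index < model.head.W.shape[0]:
        raise ValueError(f"class_index {class_index} out of range")
    cam = np.tensordot(model.head.W[class_index], feats, axes=([0], [0]))
    return ActivationMap(values=cam, class_index=class_index,
                         logit=float(logits[class_index]), patch=patch)


def upsample_cam(amap: ActivationMap | np.ndarray, size: int) -> np.ndarray:
    """Bilinear upsampling to the input resolution (values preserved)."""
    values = amap.values if isinstance(amap, ActivationMap) else np.asarray(amap)
    return resize(values.astype(float), (size, size), order=1,
                  anti_aliasing=False, preserve_range=True)


def normalized_view(cam: np.ndarray) -> np.ndarray:
    """[0, 1]-scaled copy for rendering only; statistics use raw values."""
    lo, hi = float(cam.min()), float(cam.max())
    return (cam - lo) / (hi - lo) if hi > lo else np.zeros_like(cam)


def segment_cam(
    cam,
    area_threshold: float = FULL_SCALE_AREA_THRESHOLD,
    *,
    upsample_to: int | None = None,
) -> list[ActivationRegion]:
    """Decompose an activation map into filtered watershed regions.

    ``cam`` is either an :class:`ActivationMap` (upsampled to
    ``upsample_to``, default the full-scale 512 px) or an already-upsampled
    2-D array used as-is.  Seeds are the connected components of the Otsu
    suprathreshold mask; the watershed of the negated map, restricted to
    that mask, yields disjoint regions.  Regions with area <=
    ``area_threshold`` are dropped.
    """
    if isinstance(cam, ActivationMap):
        cam = upsample_cam(cam, upsample_to or FULL_SCALE_INPUT)
    cam = np.asarray(cam, dtype=float)
    if not np.all(np.isfinite(cam)):
        raise ValueError("activation map contains non-finite values")
    if cam.max() - cam.min() < 1e-12:
        mask = np.ones_like(cam, dtype=bool)     # constant map: one region
    else:
        mask = cam > threshold_otsu(cam)
    seeds = measure.label(mask)
    if seeds.max() == 0:
        return []
    labels = segmentation.watershed(-cam, markers=seeds, mask=mask)
    regions = []
    for rp in measure.regionprops(labels, intensity_image=cam):
        if rp.area <= area_threshold:
            continue
        cy, cx = rp.centroid
        regions.append(ActivationRegion(
            region_id=int(rp.label), area=int(rp.area),
            centroid=(float(cx), float(cy)),
            mean_intensity=float(rp.intensity_mean),
        ))
    return regions
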
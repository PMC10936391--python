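"""Section annotations, per-section transforms, and patch extraction.

Serial-section EM traces are stored as points in *section* coordinates
(microns) together with a per-image geometric transform.  To recover the
pixel position of an annotation on the original image, the trace transform
is inverted and the image transform is then applied forward.  Around the
centroid of each seven-point synapse "arrow" a fixed-size grayscale patch
is cropped.

Coordinate convention (used everywhere in this package): 0-based,
``(x == column, y == row)``, pixel centers at integer coordinates.

Annotation manifest schema (JSON)::

    {
      "pixel_size": 3.85,                    # nm per pixel, optional
      "annotations": [
        {"name": "pre1-post7", "z": 12,
         "points": [[x, y], ... 7 pairs ...]},
        ...
      ],
      "transforms": {                        # optional, keyed by z as str
        "12": {"trace":  {"translation": [tx, ty], "rotation": r,
                          "scale": s, "deformation_coeffs": [...]},
               "image": {...}}
      }
    }

A simplified RECONSTRUCT-XML dialect is accepted through the same
:func:`parse_annotations` contract (see :func:`_parse_xml`).
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SectionTransform",
    "SynapseAnnotation",
    "Patch",
    "identity_transform",
    "map_to_image",
    "map_to_section",
    "parse_annotations",
    "annotation_centroid",
    "extract_patch",
]

DEFAULT_PIXEL_SIZE_NM = 3.85
DEFAULT_NAME_PATTERN = r"^(?P<pre>[A-Za-z0-9_]+)-(?P<post>[A-Za-z0-9_]+)$"

#: polynomial deformation basis evaluated at (x, y); coefficients beyond
#: the basis length are rejected.  Low order keeps the map numerically
#: invertible for small coefficients.
_DEFORM_BASIS_SIZE = 4  # x*y, x^2, y^2, x^2*y


def _deform_basis(p: np.ndarray) -> np.ndarray:
    """Basis terms (n, 4) for points p of shape (n, 2)."""
    x, y = p[..., 0], p[..., 1]
    return np.stack([x * y, x * x, y * y, x * x * y], axis=-1)


def _deform_jacobian(p: np.ndarray) -> np.ndarray:
    """d(basis)/d(x,y) of shape (n, 4, 2)."""
    x, y = p[..., 0], p[..., 1]
    one = np.ones_like(x)
    dx = np.stack([y, 2 * x, 0 * one, 2 * x * y], axis=-1)
    dy = np.stack([x, 0 * one, 2 * y, x * x], axis=-1)
    return np.stack([dx, dy], axis=-1)


@dataclass(frozen=True)
class SectionTransform:
    """Invertible per-section mapping between trace and image coordinates.

    The forward map composes the elementary motions translation, rotation,
    isotropic scaling and a small low-order polynomial deformation::

        q = s * R(theta) @ p + t + C @ basis(p)

    where ``C`` is a (2, k) coefficient matrix (k <= 4, zero-padded).  The
    inverse is computed by Newton iteration started from the affine inverse;
    for the affine part it is exact in one step.
    """

    translation: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0
    scale: float = 1.0
    deformation_coeffs: tuple[tuple[float, ...], tuple[float, ...]] = ((), ())

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"transform scale must be positive, got {self.scale}")
        for row in self.deformation_coeffs:
            if len(row) > _DEFORM_BASIS_SIZE:
                raise ValueError(
                    f"at most {_DEFORM_BASIS_SIZE} deformation coefficients "
                    f"per axis are supported, got {len(row)}"
                )

    @property
    def _rot(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    @property
    def _coeffs(self) -> np.ndarray:
        out = np.zeros((2, _DEFORM_BASIS_SIZE))
        for i, row in enumerate(self.deformation_coeffs):
            out[i, : len(row)] = row
        return out

    def forward(self, p) -> np.ndarray:
        """Apply the transform to points of shape (2,) or (n, 2)."""
        p = np.asarray(p, dtype=float)
        affine = self.scale * p @ self._rot.T + np.asarray(self.translation)
        return affine + _deform_basis(p) @ self._coeffs.T

    def inverse(self, q, *, tol: float = 1e-12, max_iter: int = 50) -> np.ndarray:
        """Invert the transform by damped Newton iteration."""
        q = np.asarray(q, dtype=float)
        A = self.scale * self._rot
        Ainv = np.linalg.inv(A)
        p = (q - np.asarray(self.translation)) @ Ainv.T
        if not np.any(self._coeffs):
            return p
        C = self._coeffs
        for _ in range(max_iter):
            resid = self.forward(p) - q
            if np.max(np.abs(resid)) < tol:
                break
            # J = A + C @ d(basis)/dp, shape (..., 2, 2)
            J = A + np.einsum("ck,...kd->...cd", C, _deform_jacobian(p))
            p = p - np.linalg.solve(J, resid[..., None])[..., 0]
        resid = self.forward(p) - q
        if np.max(np.abs(resid)) > 1e-8 * (1.0 + np.max(np.abs(q))):
            raise ValueError(
                "transform is not invertible at the requested points "
                "(deformation too strong for Newton inversion)"
            )
        return p


def identity_transform() -> SectionTransform:
    return SectionTransform()


@dataclass(frozen=True)
class SynapseAnnotation:
    """Seven-point arrow marking one synapse on one section."""

    name: str
    z_index: int
    points: np.ndarray  # (7, 2) section coordinates, microns
    pre_cell_id: str
    post_cell_id: str
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (7, 2):
            raise ValueError(
                f"annotation {self.name!r}: expected 7 points, got shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)

    @property
    def synapse_id(self) -> str:
        return f"{self.name}@z{self.z_index}"


@dataclass
class Patch:
    """Fixed-size grayscale crop with provenance."""

    image: np.ndarray
    center: tuple[float, float]
    z_index: int
    label: str
    synapse_id: str
    pre_cell_id: str
    post_cell_id: str = ""
    frame: int = 0

    @property
    def size(self) -> int:
        return self.image.shape[0]


def _parse_cell_ids(name: str, pattern: str) -> tuple[str, str]:
    m = re.match(pattern, name)
    if m is None or "pre" not in m.groupdict() or "post" not in m.groupdict():
        raise ValueError(
            f"annotation name {name!r} does not encode pre/post cell IDs "
            f"(pattern {pattern!r})"
        )
    return m.group("pre"), m.group("post")


def _transform_from_dict(d: dict) -> SectionTransform:
    coeffs = d.get("deformation_coeffs", ((), ()))
    return SectionTransform(
        translation=tuple(d.get("translation", (0.0, 0.0))),
        rotation=float(d.get("rotation", 0.0)),
        scale=float(d.get("scale", 1.0)),
        deformation_coeffs=tuple(tuple(row) for row in coeffs),
    )


def parse_annotations(
    manifest: str | Path,
    *,
    name_pattern: str = DEFAULT_NAME_PATTERN,
) -> tuple[list[SynapseAnnotation], dict[int, dict[str, SectionTransform]]]:
    """Parse an annotation manifest (JSON, or simplified RECONSTRUCT-XML).

    Returns the annotations and a per-section transform table mapping
    ``z -> {"trace": SectionTransform, "image": SectionTransform}``.
    Sections without an entry get identity transforms downstream.

    A malformed record or a name without parseable cell IDs raises
    ``ValueError`` naming the record; records are never silently skipped.
    """
    path = Path(manifest)
    if not path.exists():
        raise FileNotFoundError(f"annotation manifest not found: {path}")
    if path.suffix.lower() == ".xml":
        return _parse_xml(path, name_pattern=name_pattern)

    with open(path) as fh:
        data = json.load(fh)
    pixel_size = float(data.get("pixel_size", DEFAULT_PIXEL_SIZE_NM))
    annotations = []
    for i, rec in enumerate(data.get("annotations", [])):
        try:
            name = rec["name"]
            z = int(rec["z"])
            points = rec["points"]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed annotation record #{i}: {rec!r}") from exc
        pre, post = _parse_cell_ids(name, name_pattern)
        if len(points) != 7:
            raise ValueError(
                f"annotation record #{i} ({name!r}): expected 7 points, "
                f"got {len(points)}"
            )
        annotations.append(
            SynapseAnnotation(
                name=name, z_index=z, points=np.asarray(points, dtype=float),
                pre_cell_id=pre, post_cell_id=post, pixel_size=pixel_size,
            )
        )
    transforms = {
        int(z): {k: _transform_from_dict(v) for k, v in sect.items()}
        for z, sect in data.get("transforms", {}).items()
    }
    return annotations, transforms


def _parse_xml(path: Path, *, name_pattern: str):
    """Simplified RECONSTRUCT-XML dialect.

    ::

        <Series pixel_size="3.85">
          <Section index="12">
            <Transform role="trace" translation="1 2" rotation="0.1" scale="1"/>
            <Contour name="pre1-post7" points="x y, x y, ..."/>
          </Section>
        </Series>
    """
    root = ET.parse(path).getroot()
    pixel_size = float(root.get("pixel_size", DEFAULT_PIXEL_SIZE_NM))
    annotations: list[SynapseAnnotation] = []
    transforms: dict[int, dict[str, SectionTransform]] = {}
    for section in root.iter("Section"):
        z = int(section.get("index"))
        for tr in section.iter("Transform"):
            d: dict = {}
            if tr.get("translation"):
                d["translation"] = [float(v) for v in tr.get("translation").split()]
            for key in ("rotation", "scale"):
                if tr.get(key):
                    d[key] = float(tr.get(key))
            role = tr.get("role", "trace")
            transforms.setdefault(z, {})[role] = _transform_from_dict(d)
        for contour in section.iter("Contour"):
            name = contour.get("name")
            if name is None:
                raise ValueError(f"Contour without name in section {z}")
            pre, post = _parse_cell_ids(name, name_pattern)
            points = [
                [float(v) for v in pair.split()]
                for pair in contour.get("points", "").split(",")
                if pair.strip()
            ]
            if len(points) != 7:
                raise ValueError(
                    f"Contour {name!r} in section {z}: expected 7 points, "
                    f"got {len(points)}"
                )
            annotations.append(
                SynapseAnnotation(
                    name=name, z_index=z, points=np.asarray(points),
                    pre_cell_id=pre, post_cell_id=post, pixel_size=pixel_size,
                )
            )
    return annotations, transforms


def map_to_image(
    p,
    trace_transform: SectionTransform | None = None,
    image_transform: SectionTransform | None = None,
) -> np.ndarray:
    """Map section coordinates to image pixel coordinates.

    The trace transform is inverted, then the image transform applied
    forward.  With identity transforms the output equals the input.
    """
    trace_transform = trace_transform or identity_transform()
    image_transform = image_transform or identity_transform()
    return image_transform.forward(trace_transform.inverse(p))


def map_to_section(
    q,
    trace_transform: SectionTransform | None = None,
    image_transform: SectionTransform | None = None,
) -> np.ndarray:
    """Inverse of :func:`map_to_image`."""
    trace_transform = trace_transform or identity_transform()
    image_transform = image_transform or identity_transform()
    return trace_transform.forward(image_transform.inverse(q))


def annotation_centroid(
    a: SynapseAnnotation,
    trace_transform: SectionTransform | None = None,
    image_transform: SectionTransform | None = None,
) -> np.ndarray:
    """Arithmetic mean of the seven arrow points in image coordinates."""
    return map_to_image(a.points, trace_transform, image_transform).mean(axis=0)


def extract_patch(
    section_image: np.ndarray,
    center,
    size: int = 500,
    *,
    z_index: int = 0,
    label: str = "",
    synapse_id: str = "",
    pre_cell_id: str = "",
    post_cell_id: str = "",
) -> Patch:
    """Crop a size x size patch centred on ``center`` (x, y).

    The crop window starts at ``round(c) - size // 2`` on each axis, so a
    1000 x 1000 image with centre (500, 500) and size 500 yields rows and
    columns 250..749.  Near borders the image is reflect-padded so every
    patch is exactly full-size.  A centre outside the image, or a size
    exceeding either image dimension, is an error.
    """
    img = np.asarray(section_image)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D grayscale image, got shape {img.shape}")
    h, w = img.shape
    if size > h or size > w:
        raise ValueError(f"patch size {size} exceeds image dimensions {img.shape}")
    cx, cy = float(center[0]), float(center[1])
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"patch center ({cx}, {cy}) outside image bounds {img.shape}")
    half = size // 2
    x0 = int(round(cx)) - half
    y0 = int(round(cy)) - half
    pad = size  # reflect pad generously, then slice
    padded = np.pad(img, pad, mode="reflect")
    crop = padded[y0 + pad : y0 + pad + size, x0 + pad : x0 + pad + size]
    return Patch(
        image=crop, center=(cx, cy), z_index=z_index, label=label,
        synapse_id=synapse_id, pre_cell_id=pre_cell_id, post_cell_id=post_cell_id,
    )
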
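"""ΔR2* maps, hypointense-volume fractions and ROI volumetry.

Iron-oxide nanoparticles shorten T2*, so their accumulation shows up in two
complementary ways: as an increase in the voxel-wise relaxation rate
(ΔR2* = R2*_post − R2*_pre, proportional to local concentration in the
linear regime) and as dark, *hypointense* signal on T2*-weighted magnitude
images.  This module computes both read-outs, plus tumor volume from either
a voxel mask or a stack of manually drawn per-slice contours.

Hypointensity rule: a tumor voxel is hypointense when its intensity is
strictly below ``μ_ref − k·σ_ref`` computed over a user-supplied reference
region (e.g. contralateral normal brain); ``k`` defaults to 2.  For pre/post
comparisons the threshold is derived from the **pre-injection** reference,
so the reported increase is attributable to the agent rather than to
threshold drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

from .relaxometry import RelaxationMap

__all__ = [
    "DeltaMap",
    "ROIMask",
    "SliceContour",
    "ContourSet",
    "QuantificationResult",
    "delta_rate",
    "hypointense_fraction",
    "hypointense_increase",
    "mask_volume",
    "contour_volume",
]


@dataclass
class DeltaMap:
    """Voxel-wise rate difference (s⁻¹), defined where both inputs are valid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    valid: np.ndarray
    kind: str = "dR2*"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask shapes differ")


@dataclass
class ROIMask:
    """Boolean region-of-interest mask on the image grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SliceContour:
    """A closed polygon on one slice; vertices in 0-based voxel units
    (voxel-center convention), shape (n, 2) as (x, y)."""

    slice_index: int
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        # explicit closure is allowed; drop the repeated last vertex
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("a contour needs at least 3 distinct vertices")
        self.vertices = v


@dataclass
class ContourSet:
    """Per-slice closed tumor contours with the grid geometry."""

    contours: list[SliceContour]
    slice_thickness: float                      # mm
    in_plane_spacing: tuple[float, float]       # mm (x, y)

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0 or any(s <= 0 for s in self.in_plane_spacing):
            raise ValueError("spacing and slice thickness must be positive")


@dataclass
class QuantificationResult:
    """Percent hypointense tumor volume at two time points and ROI volume."""

    hypo_pre_pct: float
    hypo_post_pct: float
    hypo_increase_pct: float
    threshold: float
    mu_ref: float
    sigma_ref: float
    k: float
    volume_mm3: float


def delta_rate(pre: RelaxationMap, post: RelaxationMap) -> DeltaMap:
    """ΔR2* map: voxel-wise ``post − pre`` on jointly valid voxels.

    Both maps must be rate-kind, on the same grid with the same spacing and
    kind; volumes are assumed grid-aligned (registration is out of scope).
    """
    for m, name in ((pre, "pre"), (post, "post")):
        if not m.is_rate:
            raise ValueError(f"{name} map must be rate-kind, got {m.kind!r}")
    if pre.values.shape != post.values.shape:
        raise ValueError("pre/post grids differ; volumes must be aligned")
    if not np.allclose(pre.spacing, post.spacing):
        raise ValueError("pre/post voxel spacing differs")
    if pre.kind != post.kind:
        raise ValueError(f"map kinds differ: {pre.kind!r} vs {post.kind!r}")
    valid = pre.valid & post.valid
    values = np.where(valid, post.values - pre.values, np.nan)
    return DeltaMap(values=values, spacing=pre.spacing, valid=valid)


def _ref_stats(image: np.ndarray, reference: ROIMask) -> tuple[float, float]:
    ref_vals = image[reference.mask]
    return float(ref_vals.mean()), float(ref_vals.std())


def hypointense_fraction(image: np.ndarray, tumor: ROIMask, reference: ROIMask,
                         k: float = 2.0,
                         threshold: float | None = None) -> tuple[float, float]:
    """Percent of tumor voxels strictly below the reference-derived threshold.

    ``threshold = μ_ref − k·σ_ref`` over the reference region (population
    SD); pass ``threshold`` to reuse a precomputed one.  Returns
    ``(percent, threshold)``.
    """
    image = np.asarray(image, dtype=float)
    if tumor.n_voxels == 0 or reference.n_voxels == 0:
        raise ValueError("tumor and reference ROIs must be non-empty")
    if np.any(tumor.mask & reference.mask):
        raise ValueError("reference ROI must be disjoint from the tumor")
    if threshold is None:
        mu, sd = _ref_stats(image, reference)
        threshold = mu - k * sd
    n_hypo = int((image[tumor.mask] < threshold).sum())
    return 100.0 * n_hypo / tumor.n_voxels, float(threshold)


def hypointense_increase(pre_image: np.ndarray, post_image: np.ndarray,
                         tumor: ROIMask, reference: ROIMask,
                         k: float = 2.0) -> QuantificationResult:
    """Increase in percent hypointense tumor volume after injection.

    The threshold is computed once, from the pre-injection reference region,
    and applied to both time points; the increase is ``post% − pre%``.
    """
    pre_image = np.asarray(pre_image, dtype=float)
    post_image = np.asarray(post_image, dtype=float)
    if pre_image.shape != post_image.shape:
        raise ValueError("pre/post image grids differ")
    mu, sd = _ref_stats(pre_image, reference)
    thr = mu - k * sd
    pre_pct, _ = hypointense_fraction(pre_image, tumor, reference, k, threshold=thr)
    post_pct, _ = hypointense_fraction(post_image, tumor, reference, k, threshold=thr)
    return QuantificationResult(
        hypo_pre_pct=pre_pct,
        hypo_post_pct=post_pct,
        hypo_increase_pct=post_pct - pre_pct,
        threshold=thr, mu_ref=mu, sigma_ref=sd, k=k,
        volume_mm3=mask_volume(tumor),
    )


def mask_volume(mask: ROIMask) -> float:
    """Volume of a voxel mask in mm³: voxel count × voxel volume."""
    return mask.n_voxels * float(np.prod(mask.spacing))


def contour_volume(contours: ContourSet) -> float:
    """Tumor volume (mm³) by integrating contoured areas across slices.

    Each polygon's planar area is computed in physical units (vertex
    coordinates scaled by the in-plane spacing) and multiplied by the slice
    thickness; slice volumes are summed.  Multiple contours on one slice add.
    """
    if not contours.contours:
        raise ValueError("at least one slice contour is required")
    sx, sy = contours.in_plane_spacing
    total_area = 0.0
    for c in contours.contours:
        scaled = c.vertices * np.array([sx, sy])
        poly = Polygon(scaled)
        if not poly.is_valid:
            raise ValueError(
                f"contour on slice {c.slice_index} is not a simple polygon")
        total_area += poly.area
    return total_area * contours.slice_thickness
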
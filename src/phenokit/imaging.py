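"""Side-view plant image segmentation and feature extraction.

A plant is segmented from its (uniform) background with an excess-green
index, and a fixed catalogue of descriptors is measured on the binary
silhouette: the projected area (foreground pixel count), 25 morphological
descriptors and 7 grey-level co-occurrence (GLCM) texture descriptors.
Per-view feature vectors are aggregated over the views of one plant.

The descriptor catalogue is a frozen contract: see
:data:`MORPH_FEATURE_NAMES` and :data:`TEXTURE_FEATURE_NAMES`.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "Calibration",
    "PlantMask",
    "ViewFeatures",
    "PlantFeatureVector",
    "MORPH_FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
    "ALL_FEATURE_NAMES",
    "SegmentationError",
    "segment_plant",
    "projected_area",
    "morphological_features",
    "texture_features",
    "plant_height",
    "extract_view_features",
    "aggregate_views",
]

#: Frozen catalogue of the 25 morphological descriptors.
MORPH_FEATURE_NAMES: tuple[str, ...] = (
    "plant_height_px",
    "plant_width_px",
    "height_width_ratio",
    "compactness",
    "solidity",
    "extent",
    "circularity",
    "convexity",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "orientation",
    "equivalent_diameter",
    "perimeter",
    "hull_area",
    "hull_perimeter",
    "bbox_area",
    "centroid_height_fraction",
    "top_half_area_fraction",
    "radial_spread",
    "hole_count",
    "skeleton_length",
    "branch_count",
    "caliper_diameter",
    "hull_bbox_fill_ratio",
)

#: Frozen catalogue of the 7 GLCM texture descriptors.
TEXTURE_FEATURE_NAMES: tuple[str, ...] = (
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_homogeneity",
    "glcm_energy",
    "glcm_correlation",
    "glcm_entropy",
    "glcm_variance",
)

ALL_FEATURE_NAMES: tuple[str, ...] = (
    ("projected_area_px",) + MORPH_FEATURE_NAMES + TEXTURE_FEATURE_NAMES
)


class SegmentationError(ValueError):
    """Raised when no plant foreground survives segmentation."""


@dataclasses.dataclass(frozen=True)
class Calibration:
    """Pixel-to-physical length calibration."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")


@dataclasses.dataclass
class PlantMask:
    """Binary foreground raster of one segmented side view."""

    bits: np.ndarray  # H x W bool

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape


@dataclasses.dataclass
class ViewFeatures:
    """All descriptors measured on a single side view."""

    projected_area_px: int
    morph: dict[str, float]
    texture: dict[str, float]
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {"projected_area_px": float(self.projected_area_px)}
        out.update(self.morph)
        out.update(self.texture)
        return out


@dataclasses.dataclass
class PlantFeatureVector:
    """Per-plant aggregate of descriptors over all its views."""

    plant_id: str
    stage: str
    features: dict[str, float]
    n_views: int


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError("image must be at least 8 x 8")
    return image


def segment_plant(
    image: np.ndarray,
    min_object_px: int = 64,
    threshold_mode: Literal["otsu", "fixed"] = "otsu",
    fixed_threshold: float = 20.0,
) -> PlantMask:
    """Segment the green plant from a uniform background.

    The excess-green index ``2G - R - B`` is thresholded (Otsu by default,
    or at ``fixed_threshold``), and connected components smaller than
    ``min_object_px`` are discarded.  Holes inside retained components are
    kept open.

    Raises
    ------
    SegmentationError
        If no foreground pixel survives.
    """
    image = _validate_image(image)
    if min_object_px < 1:
        raise ValueError("min_object_px must be >= 1")
    rgb = image.astype(np.int32)
    exg = 2 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]
    if threshold_mode == "otsu":
        if exg.min() == exg.max():
            raise SegmentationError("no plant found: uniform greenness map")
        thr = threshold_otsu(exg)
    elif threshold_mode == "fixed":
        thr = fixed_threshold
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    fg = exg > thr
    if fg.any():
        labels = measure.label(fg, connectivity=2)
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_object_px)
        keep = keep[keep != 0]
        fg = np.isin(labels, keep)
    if not fg.any():
        raise SegmentationError("no plant found")
    return PlantMask(fg)


def projected_area(mask: PlantMask) -> int:
    """Number of foreground pixels (the trait symbolised ``A``)."""
    return int(mask.bits.sum())


def _hull_perimeter_points(coords: np.ndarray) -> np.ndarray:
    """Convex hull vertices over the pixel corner points of ``coords``."""
    from scipy.spatial import ConvexHull, QhullError

    corners = np.concatenate(
        [coords + d for d in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    try:
        hull = ConvexHull(corners)
    except QhullError:
        return corners
    return corners[hull.vertices]


def _polygon_perimeter(vertices: np.ndarray) -> float:
    diff = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    return float(np.hypot(diff[:, 0], diff[:, 1]).sum())


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area; vertices in traversal order."""
    x = vertices[:, 0]
    y = vertices[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def morphological_features(mask: PlantMask) -> dict[str, float]:
    """Measure the 25-descriptor morphological catalogue on a mask.

    Definitions (all in pixel units, row 0 = top of image):

    - ``plant_height_px`` / ``plant_width_px``: bounding-box extents.
    - ``compactness``: projected area / convex-hull area, where the hull is
      the exact polygon over the pixel *corner* points (shoelace area), so
      a filled rectangle scores exactly 1.
    - ``solidity``: same ratio via ``regionprops`` (pixel-centre hull
      rasterisation); kept separately because the two hull constructions
      differ on thin shapes.
    - ``extent``: area / bounding-box area.
    - ``circularity``: ``4 * pi * A / P**2`` with the marching-squares
      perimeter ``P``.
    - ``convexity``: hull perimeter / silhouette perimeter.
    - ``hole_count``: enclosed background components (from the Euler
      number).
    - ``centroid_height_fraction``: height of the centroid above the
      silhouette base, as a fraction of plant height.
    - ``top_half_area_fraction``: share of foreground in the upper half of
      the bounding box.
    - ``radial_spread``: RMS distance of foreground pixels from the
      centroid.
    - ``caliper_diameter``: maximum Feret diameter.
    - ``hull_bbox_fill_ratio``: hull area / bounding-box area.
    """
    bits = mask.bits
    area = int(bits.sum())
    if area == 0:
        raise ValueError("empty mask")

    rows, cols = np.nonzero(bits)
    rmin, rmax = int(rows.min()), int(rows.max())
    cmin, cmax = int(cols.min()), int(cols.max())
    height = rmax - rmin + 1
    width = cmax - cmin + 1
    bbox_area = height * width

    if area == 1:
        # Degenerate single pixel: ratios by convention.
        out = {name: 0.0 for name in MORPH_FEATURE_NAMES}
        out.update(
            plant_height_px=1.0,
            plant_width_px=1.0,
            height_width_ratio=1.0,
            compactness=1.0,
            solidity=1.0,
            extent=1.0,
            circularity=1.0,
            convexity=1.0,
            equivalent_diameter=2.0 / math.sqrt(math.pi),
            perimeter=4.0,
            hull_area=1.0,
            hull_perimeter=4.0,
            bbox_area=1.0,
            hull_bbox_fill_ratio=1.0,
            top_half_area_fraction=1.0,
            caliper_diameter=1.0,
        )
        return out

    label_img = bits.astype(np.uint8)
    props = measure.regionprops(label_img)[0]

    # Crofton (4-direction) perimeter: near-unbiased on smooth silhouettes
    perimeter = float(props.perimeter_crofton) if props.perimeter_crofton > 0 else 4.0
    hull_pts = _hull_perimeter_points(np.column_stack([rows, cols]).astype(float))
    hull_perimeter = _polygon_perimeter(hull_pts)
    hull_area = _polygon_area(hull_pts)

    n_components = int(measure.label(bits, connectivity=2).max())
    euler = int(props.euler_number)
    hole_count = max(0, n_components - euler)

    skeleton = morphology.skeletonize(bits)
    skeleton_length = float(skeleton.sum())
    neighbour_count = ndi.convolve(
        skeleton.astype(np.uint8), np.ones((3, 3), np.uint8), mode="constant"
    )
    branch_count = float(np.count_nonzero(skeleton & (neighbour_count > 3)))

    cr, cc = props.centroid
    radial_spread = float(
        np.sqrt(np.mean((rows - cr) ** 2 + (cols - cc) ** 2))
    )
    centroid_height_fraction = float((rmax - cr) / height)
    top_rows = rows < (rmin + height / 2.0)
    top_half_area_fraction = float(top_rows.sum() / area)

    return {
        "plant_height_px": float(height),
        "plant_width_px": float(width),
        "height_width_ratio": float(height / width),
        "compactness": float(area / hull_area),
        "solidity": float(props.solidity),
        "extent": float(area / bbox_area),
        "circularity": float(4.0 * math.pi * area / perimeter**2),
        "convexity": float(hull_perimeter / perimeter),
        "eccentricity": float(props.eccentricity),
        "major_axis_length": float(props.axis_major_length),
        "minor_axis_length": float(props.axis_minor_length),
        "orientation": float(props.orientation),
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "perimeter": perimeter,
        "hull_area": hull_area,
        "hull_perimeter": hull_perimeter,
        "bbox_area": float(bbox_area),
        "centroid_height_fraction": centroid_height_fraction,
        "top_half_area_fraction": top_half_area_fraction,
        "radial_spread": radial_spread,
        "hole_count": float(hole_count),
        "skeleton_length": skeleton_length,
        "branch_count": branch_count,
        "caliper_diameter": float(props.feret_diameter_max),
        "hull_bbox_fill_ratio": float(hull_area / bbox_area),
    }


def _masked_glcm(
    grey: np.ndarray,
    bits: np.ndarray,
    levels: int,
    offsets: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Symmetric normalised GLCM restricted to pixel pairs inside the mask."""
    lo = grey[bits].min()
    hi = grey[bits].max()
    if hi > lo:
        quant = ((grey - lo) / (hi - lo) * (levels - 1)).round().astype(np.int64)
        quant = np.clip(quant, 0, levels - 1)
    else:
        quant = np.zeros_like(grey, dtype=np.int64)
    glcm = np.zeros((levels, levels), dtype=np.float64)
    h, w = bits.shape
    for dy, dx in offsets:
        src = (slice(max(0, -dy), min(h, h - dy)), slice(max(0, -dx), min(w, w - dx)))
        dst = (slice(max(0, dy), min(h, h + dy)), slice(max(0, dx), min(w, w + dx)))
        valid = bits[src] & bits[dst]
        i = quant[src][valid]
        j = quant[dst][valid]
        np.add.at(glcm, (i, j), 1.0)
        np.add.at(glcm, (j, i), 1.0)  # symmetric
    total = glcm.sum()
    if total == 0:
        raise ValueError("no co-occurring pixel pairs inside the mask")
    return glcm / total


DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))


def texture_features(
    image: np.ndarray,
    mask: PlantMask,
    levels: int = 32,
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
) -> dict[str, float]:
    """Seven GLCM texture descriptors over the masked region.

    Intensity (channel mean for RGB) is min-max quantised to ``levels``
    grey levels inside the mask; the co-occurrence matrix pools the given
    offsets (default: 4 directions at distance 1), is symmetrised and
    normalised to sum 1.

    Descriptors: contrast ``sum p (i-j)^2``, dissimilarity ``sum p |i-j|``,
    homogeneity ``sum p / (1 + (i-j)^2)``, energy ``sum p^2`` (angular
    second moment), correlation, entropy ``-sum p ln p`` (nats) and
    grey-level variance.  For a zero-variance matrix the correlation is 1
    by convention.
    """
    image = np.asarray(image)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    bits = mask.bits
    if bits.shape != image.shape[:2]:
        raise ValueError("mask dimensions do not match image")
    if bits.sum() < 2:
        raise ValueError("masked region smaller than 2 px")
    grey = image.astype(np.float64)
    if grey.ndim == 3:
        grey = grey.mean(axis=2)

    p = _masked_glcm(grey, bits, levels, offsets)
    idx = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    diff = ii - jj

    contrast = float((p * diff**2).sum())
    dissimilarity = float((p * np.abs(diff)).sum())
    homogeneity = float((p / (1.0 + diff**2)).sum())
    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    var_i = float((p * (ii - mu_i) ** 2).sum())
    var_j = float((p * (jj - mu_j) ** 2).sum())
    if var_i > 0 and var_j > 0:
        correlation = float(
            (p * (ii - mu_i) * (jj - mu_j)).sum() / math.sqrt(var_i * var_j)
        )
    else:
        correlation = 1.0

    return {
        "glcm_contrast": contrast,
        "glcm_dissimilarity": dissimilarity,
        "glcm_homogeneity": homogeneity,
        "glcm_energy": energy,
        "glcm_correlation": correlation,
        "glcm_entropy": entropy,
        "glcm_variance": var_i,
    }


def plant_height(mask: PlantMask, cal: Calibration) -> float:
    """Vertical foreground extent in millimetres."""
    rows = np.nonzero(mask.bits.any(axis=1))[0]
    if rows.size == 0:
        raise ValueError("empty mask")
    return float((rows[-1] - rows[0] + 1) * cal.mm_per_px)


def extract_view_features(
    image: np.ndarray,
    min_object_px: int = 64,
    threshold_mode: Literal["otsu", "fixed"] = "otsu",
    levels: int = 32,
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
) -> ViewFeatures:
    """Segment one view and measure the full descriptor catalogue."""
    mask = segment_plant(image, min_object_px=min_object_px, threshold_mode=threshold_mode)
    morph = morphological_features(mask)
    texture = texture_features(image, mask, levels=levels, offsets=offsets)
    return ViewFeatures(
        projected_area_px=projected_area(mask),
        morph=morph,
        texture=texture,
        degenerate=projected_area(mask) == 1,
    )


def aggregate_views(
    per_view: Sequence[ViewFeatures],
    plant_id: str = "",
    stage: str = "",
    how: Literal["mean", "max"] = "mean",
) -> PlantFeatureVector:
    """Aggregate per-view descriptors into one plant-level vector."""
    if len(per_view) == 0:
        raise ValueError("need at least one view")
    dicts = [v.as_dict() for v in per_view]
    names = set(dicts[0])
    for d in dicts[1:]:
        if set(d) != names:
            raise ValueError("inconsistent descriptor sets across views")
    agg = np.mean if how == "mean" else np.max
    if how not in ("mean", "max"):
        raise ValueError(f"unknown aggregation {how!r}")
    features = {
        name: float(agg([d[name] for d in dicts])) for name in dicts[0]
    }
    return PlantFeatureVector(
        plant_id=plant_id, stage=stage, features=features, n_views=len(per_view)
    )
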
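"""Bright-field organoid segmentation chain and per-object measurement.

The chain detects organoid rims rather than bodies: the rim is the only
high-contrast feature in a transmitted-light image.  Edges found by a
Canny filter are "smeared" (blurred and re-binarized) into closed bands,
consolidated by a morphological close, denoised by a morphological open,
and the enclosed interiors are completed by hole filling.  Connected
components of the filled mask are the segmented organoids; pixel area and
mean intensity (on the unblurred greyscale) are measured per object, and
objects in the sparse large-area tail — merged clumps, bubbles — are
excluded by an area cutoff (40,000 px by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature as _skfeature
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph

__all__ = [
    "SegmentationParams",
    "OrganoidObject",
    "to_greyscale",
    "gaussian_blur",
    "canny_edges",
    "smear_edges",
    "morph_close",
    "morph_open",
    "fill_holes",
    "connected_components",
    "measure_objects",
    "apply_area_filter",
    "area_histogram",
    "suggest_tail_cut",
    "segment_organoids",
]

# Rec.601 luma weights for RGB -> grey conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

# 4- and 8-neighbour structuring elements for scipy.ndimage.
_STRUCT = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class SegmentationParams:
    """Every tunable of the detection chain.

    ``canny_low``/``canny_high`` are interpreted as fractions of the
    maximum Sobel gradient magnitude of the blurred image when
    ``canny_relative`` is true (the default — scale-free behaviour across
    contrasts), otherwise as absolute gradient thresholds.
    """

    pre_blur_sigma: float = 1.5
    canny_low: float = 0.1
    canny_high: float = 0.3
    canny_relative: bool = True
    smear_sigma: float = 2.0
    smear_binarize_level: float = 0.15
    close_se_radius: int = 3
    close_iterations: int = 1
    open_se_radius: int = 1
    open_iterations: int = 1
    object_connectivity: int = 8
    hole_connectivity: int = 4
    max_area_px: int = 40_000
    min_area_px: int = 0

    def __post_init__(self) -> None:
        if self.canny_low >= self.canny_high:
            raise ValueError("canny_low must be smaller than canny_high")
        if self.pre_blur_sigma < 0 or self.smear_sigma < 0:
            raise ValueError("blur sigmas must be non-negative")
        if not 0.0 < self.smear_binarize_level < 1.0:
            raise ValueError("smear_binarize_level must lie strictly in (0, 1)")
        if self.close_se_radius < 1 or self.open_se_radius < 1:
            raise ValueError("structuring-element radii must be >= 1")
        if self.close_iterations < 1 or self.open_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.object_connectivity not in (4, 8) or self.hole_connectivity not in (4, 8):
            raise ValueError("connectivities must be 4 or 8")
        if not self.max_area_px > self.min_area_px >= 0:
            raise ValueError("require max_area_px > min_area_px >= 0")


@dataclass(frozen=True)
class OrganoidObject:
    """Per-object features measured on the original greyscale image.

    ``bbox`` is half-open ``(row_min, col_min, row_max, col_max)``;
    coordinates are 0-based (row, col).
    """

    label: int
    area_px: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    mean_intensity: float


def _as_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    return m.astype(bool)


def to_greyscale(image: np.ndarray) -> np.ndarray:
    """Collapse an image to a single grey channel (Rec.601 luma for RGB).

    2-D input passes through unchanged (as float64).  Integer RGB inputs
    are rounded to the nearest grey level, e.g. pure red (255, 0, 0)
    maps to 76.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] == 3:
        grey = arr.astype(np.float64) @ _LUMA
        if np.issubdtype(arr.dtype, np.integer):
            grey = np.rint(grey)
        return grey
    raise ValueError(
        f"unsupported image format: expected 2-D or (H, W, 3), got shape {arr.shape}"
    )


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with reflective borders; ``sigma == 0`` is identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if sigma == 0:
        return img.copy()
    return ndi.gaussian_filter(img, sigma, mode="reflect")


def canny_edges(image: np.ndarray, low: float, high: float) -> np.ndarray:
    """Canny edge detection with absolute gradient thresholds.

    Sobel gradients, non-maximum suppression, then double-threshold
    hysteresis.  The image is used as given — smoothing is the caller's
    job (see :func:`gaussian_blur`), so the internal sigma is 0.
    """
    if low >= high:
        raise ValueError("canny low threshold must be smaller than high")
    img = np.asarray(image, dtype=np.float64)
    return _skfeature.canny(img, sigma=0.0, low_threshold=low, high_threshold=high)


def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude; used to scale relative Canny thresholds."""
    img = np.asarray(image, dtype=np.float64)
    return np.hypot(ndi.sobel(img, axis=1), ndi.sobel(img, axis=0))


def smear_edges(edges: np.ndarray, smear_sigma: float, level: float) -> np.ndarray:
    """Blur a binary edge map and re-binarize, bridging nearby fragments.

    The edge map is treated as a real image, Gaussian blurred with
    ``smear_sigma`` and thresholded at ``level``; broken rim fragments
    fuse into continuous bands whose width shrinks as ``level`` rises.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("smear binarize level must lie strictly in (0, 1)")
    m = _as_binary(edges)
    blurred = ndi.gaussian_filter(m.astype(np.float64), smear_sigma, mode="reflect")
    return blurred > level


def _disc(radius: int) -> np.ndarray:
    return _skmorph.disk(radius).astype(bool)


def morph_close(mask: np.ndarray, se_radius: int, iterations: int = 1) -> np.ndarray:
    """Morphological closing (dilate, then erode) with a disc element.

    The image is padded with background by the element radius before the
    dilation, so the result equals the infinite-plane closing restricted
    to the frame (no spurious growth against the image border).
    """
    if se_radius < 1 or iterations < 1:
        raise ValueError("se_radius and iterations must be >= 1")
    out = _as_binary(mask)
    se = _disc(se_radius)
    for _ in range(iterations):
        padded = np.pad(out, se_radius, constant_values=False)
        padded = ndi.binary_dilation(padded, structure=se)
        padded = ndi.binary_erosion(padded, structure=se, border_value=0)
        out = padded[se_radius:-se_radius, se_radius:-se_radius]
    return out


def morph_open(mask: np.ndarray, se_radius: int, iterations: int = 1) -> np.ndarray:
    """Morphological opening (erode, then dilate) with a disc element.

    Outside the frame counts as background, so the operation equals the
    infinite-plane opening restricted to the frame.
    """
    if se_radius < 1 or iterations < 1:
        raise ValueError("se_radius and iterations must be >= 1")
    out = _as_binary(mask)
    se = _disc(se_radius)
    for _ in range(iterations):
        out = ndi.binary_erosion(out, structure=se, border_value=0)
        out = ndi.binary_dilation(out, structure=se)
    return out


def fill_holes(mask: np.ndarray, hole_connectivity: int = 4) -> np.ndarray:
    """Fill background pockets not reachable from the image border.

    Background reachability is walked under ``hole_connectivity``;
    foreground pixels are never removed.  Complements 8-connected objects
    with 4-connected background (the standard pairing) by default.
    """
    if hole_connectivity not in (4, 8):
        raise ValueError("hole_connectivity must be 4 or 8")
    m = _as_binary(mask)
    return ndi.binary_fill_holes(m, structure=_STRUCT[hole_connectivity])


def connected_components(mask: np.ndarray, object_connectivity: int = 8) -> np.ndarray:
    """Label connected foreground regions 1..n in raster discovery order."""
    if object_connectivity not in (4, 8):
        raise ValueError("object_connectivity must be 4 or 8")
    m = _as_binary(mask)
    labels, n = ndi.label(m, structure=_STRUCT[object_connectivity])
    if n == 0:
        return labels.astype(np.int32)
    # enforce raster-scan discovery order of labels
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    return remap[labels]


def measure_objects(labels: np.ndarray, original: np.ndarray) -> list[OrganoidObject]:
    """Measure area, centroid, bbox and mean intensity per labelled object.

    Mean intensity is taken from ``original`` — the unblurred greyscale
    image — over each object's pixel locations.
    """
    lab = np.asarray(labels)
    img = np.asarray(original, dtype=np.float64)
    if lab.shape != img.shape:
        raise ValueError(
            f"label map shape {lab.shape} does not match image shape {img.shape}"
        )
    out: list[OrganoidObject] = []
    for rp in _skmeasure.regionprops(lab, intensity_image=img):
        out.append(
            OrganoidObject(
                label=int(rp.label),
                area_px=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=tuple(int(v) for v in rp.bbox),
                mean_intensity=float(rp.intensity_mean),
            )
        )
    out.sort(key=lambda o: o.label)
    return out


def apply_area_filter(
    objects: list[OrganoidObject], max_area_px: int = 40_000, min_area_px: int = 0
) -> list[OrganoidObject]:
    """Drop objects outside ``[min_area_px, max_area_px]`` (inclusive).

    Objects strictly above the cutoff are the sparse large-area tail
    treated as noise; an object of exactly the cutoff area is retained.
    """
    if not max_area_px > min_area_px >= 0:
        raise ValueError("require max_area_px > min_area_px >= 0")
    return [o for o in objects if min_area_px <= o.area_px <= max_area_px]


def area_histogram(
    areas: "np.ndarray | list[int]", n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of object pixel areas: returns ``(bin_edges, counts)``."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    a = np.asarray(areas, dtype=np.float64)
    if a.size and a.min() < 0:
        raise ValueError("areas must be non-negative")
    counts, edges = np.histogram(a, bins=n_bins)
    return edges, counts


def suggest_tail_cut(areas: "np.ndarray | list[int]") -> float | None:
    """Diagnostic tail cutoff: the largest inter-point gap beyond Q3.

    Scans the sorted areas above the upper quartile for the widest gap
    between consecutive values and returns its midpoint, or ``None`` when
    no gap exists there.  Purely advisory — the operative exclusion
    threshold is ``SegmentationParams.max_area_px``.
    """
    a = np.sort(np.asarray(areas, dtype=np.float64))
    if a.size < 4:
        return None
    q3 = np.quantile(a, 0.75)
    upper = a[a >= q3]
    if upper.size < 2:
        return None
    gaps = np.diff(upper)
    i = int(np.argmax(gaps))
    if gaps[i] <= 0:
        return None
    return float((upper[i] + upper[i + 1]) / 2.0)


def segment_organoids(
    image: np.ndarray, params: SegmentationParams | None = None
) -> tuple[np.ndarray, list[OrganoidObject]]:
    """Run the full detection chain and return (label map, retained objects).

    Stages, in order: greyscale conversion, Gaussian pre-blur, Canny edge
    detection, edge smearing, morphological close, morphological open,
    hole filling, connected components, per-object measurement (mean
    intensity from the unblurred greyscale), area filtering.  The returned
    label map contains only retained objects, relabelled consecutively.
    """
    if params is None:
        params = SegmentationParams()
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    grey = to_greyscale(arr)
    blurred = gaussian_blur(grey, params.pre_blur_sigma)
    if params.canny_relative:
        gmax = float(gradient_magnitude(blurred).max())
        if gmax == 0.0:
            return np.zeros(grey.shape, dtype=np.int32), []
        low, high = params.canny_low * gmax, params.canny_high * gmax
    else:
        low, high = params.canny_low, params.canny_high
    edges = canny_edges(blurred, low, high)
    mask = smear_edges(edges, params.smear_sigma, params.smear_binarize_level)
    mask = morph_close(mask, params.close_se_radius, params.close_iterations)
    mask = morph_open(mask, params.open_se_radius, params.open_iterations)
    mask = fill_holes(mask, params.hole_connectivity)
    labels = connected_components(mask, params.object_connectivity)
    objects = measure_objects(labels, grey)
    retained = apply_area_filter(objects, params.max_area_px, params.min_area_px)

    keep = np.zeros(len(objects) + 1, dtype=np.int32)
    relabelled: list[OrganoidObject] = []
    for new, obj in enumerate(retained, start=1):
        keep[obj.label] = new
        relabelled.append(
            OrganoidObject(
                label=new,
                area_px=obj.area_px,
                centroid=obj.centroid,
                bbox=obj.bbox,
                mean_intensity=obj.mean_intensity,
            )
        )
    return keep[labels], relabelled
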
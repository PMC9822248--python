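"""Automatic 2D segmentation of fluorescence puncta and overlap colocalization.

Objects are connected components above a robust intensity criterion
(median + k x robust SD of the raw image, no background subtraction),
filtered by area.  Density, per-object mean intensity and area are the
reported statistics.  A colocalization filter retains objects of one
channel whose fractional pixel overlap with the objects of another channel
strictly exceeds a threshold (0% = any shared pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import median_abs_deviation
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import InputError

__all__ = [
    "PunctaObject", "SegmentationResult",
    "segment_puncta", "puncta_statistics", "filter_by_overlap",
]


@dataclass(frozen=True)
class PunctaObject:
    """One segmented punctum."""

    id: int
    centroid: tuple[float, float]    # (x, y) pixels
    area_px: int
    area_nm2: float
    mean_intensity: float
    pixels: np.ndarray               # (n, 2) array of (row, col) indices


@dataclass(frozen=True)
class SegmentationResult:
    """Objects of one image plus the parameters that produced them."""

    objects: tuple[PunctaObject, ...]
    label_image: np.ndarray
    image_shape: tuple[int, int]
    pixel_size: float                # nm / pixel
    parameters: dict = field(default_factory=dict)

    @property
    def image_area_um2(self) -> float:
        h, w = self.image_shape
        return h * w * (self.pixel_size / 1000.0) ** 2

    @property
    def density_per_image(self) -> float:
        return float(len(self.objects))

    @property
    def density_per_um2(self) -> float:
        return len(self.objects) / self.image_area_um2


def segment_puncta(image: np.ndarray, pixel_size: float, *, k: float = 4.0,
                   min_area_px: int = 4, max_area_px: int | None = None,
                   connectivity: int = 2) -> SegmentationResult:
    """Threshold-and-label segmentation of a single-channel image.

    The intensity criterion is ``median + k x robust SD`` where the robust
    SD is the scaled median absolute deviation of the raw image, making the
    pixel sets invariant to affine intensity rescaling.  Components use
    8-connectivity by default and are filtered to ``[min_area_px,
    max_area_px]``.  Deterministic; a constant image yields zero objects.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InputError("image must be single-channel 2D")
    if pixel_size <= 0:
        raise InputError("pixel_size must be > 0")
    med = float(np.median(image))
    robust_sd = float(median_abs_deviation(image, axis=None, scale="normal"))
    threshold = med + k * robust_sd
    fg = image > threshold

    labels = cc_label(fg, connectivity=connectivity)
    objects: list[PunctaObject] = []
    next_id = 1
    for rp in regionprops(labels, intensity_image=image):
        if rp.area < min_area_px or (max_area_px is not None and rp.area > max_area_px):
            labels[labels == rp.label] = 0
            continue
        cy, cx = rp.centroid
        objects.append(PunctaObject(
            id=next_id, centroid=(float(cx), float(cy)),
            area_px=int(rp.area), area_nm2=float(rp.area * pixel_size**2),
            mean_intensity=float(rp.intensity_mean),
            pixels=np.array(rp.coords, dtype=int),
        ))
        labels[labels == rp.label] = -next_id
        next_id += 1
    labels = -labels  # relabel compactly, filtered objects removed

    params = {"k": k, "threshold": threshold, "median": med,
              "robust_sd": robust_sd, "min_area_px": min_area_px,
              "max_area_px": max_area_px, "connectivity": connectivity}
    return SegmentationResult(objects=tuple(objects), label_image=labels,
                              image_shape=image.shape, pixel_size=pixel_size,
                              parameters=params)


def puncta_statistics(result: SegmentationResult) -> dict:
    """Density, mean intensity and mean area of a segmentation result.

    With zero objects the per-object means are undefined and reported as
    NaN.
    """
    n = len(result.objects)
    if n == 0:
        return {"n_objects": 0, "density_per_image": 0.0,
                "density_per_um2": 0.0, "mean_intensity": float("nan"),
                "mean_area_nm2": float("nan")}
    return {
        "n_objects": n,
        "density_per_image": result.density_per_image,
        "density_per_um2": result.density_per_um2,
        "mean_intensity": float(np.mean([o.mean_intensity for o in result.objects])),
        "mean_area_nm2": float(np.mean([o.area_nm2 for o in result.objects])),
    }


def filter_by_overlap(objects_a: SegmentationResult | tuple[PunctaObject, ...],
                      objects_b: SegmentationResult | tuple[PunctaObject, ...],
                      threshold: float = 0.0, *,
                      shape: tuple[int, int] | None = None) -> tuple[PunctaObject, ...]:
    """Retain A objects whose fractional overlap with B strictly exceeds threshold.

    ``threshold`` is a fraction in [0, 1]; 0 retains any object sharing at
    least one pixel with the union of B objects.  Both object sets must live
    on the same pixel grid.
    """
    a_objs, a_shape = _objects_and_shape(objects_a, shape)
    b_objs, b_shape = _objects_and_shape(objects_b, shape)
    if a_shape is not None and b_shape is not None and a_shape != b_shape:
        raise InputError(f"pixel grids differ: {a_shape} vs {b_shape}")
    grid = a_shape or b_shape or shape
    if grid is None:
        raise InputError("pixel grid shape is required")
    if not 0.0 <= threshold <= 1.0:
        raise InputError("threshold must be a fraction in [0, 1]")

    b_mask = np.zeros(grid, dtype=bool)
    for o in b_objs:
        b_mask[o.pixels[:, 0], o.pixels[:, 1]] = True

    kept = []
    for o in a_objs:
        frac = b_mask[o.pixels[:, 0], o.pixels[:, 1]].mean() if o.area_px else 0.0
        if threshold < 1.0:
            retain = frac > threshold
        else:
            retain = frac >= 1.0  # full containment at the limiting case
        if retain:
            kept.append(o)
    return tuple(kept)


def _objects_and_shape(objs, shape):
    if isinstance(objs, SegmentationResult):
        return objs.objects, objs.image_shape
    return tuple(objs), shape
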
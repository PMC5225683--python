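"""Lung detection, liver-dome localisation, and liver extent estimation.

The liver sits just below the right lung, and lungs — being air-filled —
are by far the darkest structures inside the body, so the right lung is
easy to track slice by slice.  Travelling superior -> inferior, two
consecutive relative drops of at least 10 % in right-lung area signal the
emergence of the liver dome.  The right-lung mask of the slice just before
the dome then serves as an in-plane template: counting, per slice, the
template pixels whose intensity falls within the calibrated liver band
(mean +/- k*deviation) picks out the biggest liver slice (the middle
slice) and the last liver slice (first count below ~100 pixels, the
typical size of the liver tail on 512x512 CT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .preprocess import BodyMask


class DomeNotFoundError(RuntimeError):
    """No pair of consecutive qualifying lung-area decreases exists."""


class LungNotFoundError(RuntimeError):
    """No right-lung candidate in any slice; the pipeline cannot start."""


class ExtentEstimationError(RuntimeError):
    """Liver extent could not be derived (e.g. dome too close to the end)."""


@dataclass
class LungProfile:
    """Per-slice right-lung masks, areas, and midpoints."""

    masks: list[np.ndarray]  # per-slice binary mask (may be all-False)
    areas: np.ndarray  # per-slice pixel counts
    midpoints: list[tuple[float, float] | None]  # (row, col) centroid or None


@dataclass
class LiverExtent:
    """Slice range of the liver plus its calibrated intensity band."""

    dome_slice: int
    middle_slice: int
    last_slice: int
    intensity_mean: float
    intensity_dev: float

    def __post_init__(self) -> None:
        if not (self.dome_slice <= self.middle_slice <= self.last_slice):
            raise ValueError("expected dome <= middle <= last slice order")
        if self.intensity_dev < 0:
            raise ValueError("intensity deviation must be >= 0")


def detect_lungs(
    volume_hu: np.ndarray,
    body_masks: Sequence[BodyMask],
    lung_hu_threshold: float = -400.0,
    min_area: int = 50,
    patient_right_is_image_left: bool = True,
) -> LungProfile:
    """Find the right lung in every slice.

    Low-attenuation (HU below ``lung_hu_threshold``) connected components
    inside the body whose centroid lies in the patient-right half are lung
    candidates; the largest is taken as the right lobe.  Slices without a
    candidate get area 0.
    """
    masks: list[np.ndarray] = []
    areas = np.zeros(volume_hu.shape[0])
    midpoints: list[tuple[float, float] | None] = []
    for z in range(volume_hu.shape[0]):
        body = body_masks[z].mask
        best_mask = np.zeros(volume_hu.shape[1:], dtype=bool)
        best_area = 0
        midpoint: tuple[float, float] | None = None
        if body.any():
            cand = (volume_hu[z] < lung_hu_threshold) & body
            labels, n = ndimage.label(cand)
            body_c = ndimage.center_of_mass(body)
            half_w = volume_hu.shape[2] / 2.0
            for i in range(1, n + 1):
                comp = labels == i
                area = int(comp.sum())
                if area < min_area:
                    continue
                cy, cx = ndimage.center_of_mass(comp)
                on_right = cx < half_w if patient_right_is_image_left else cx >= half_w
                if on_right and area > best_area:
                    best_mask, best_area, midpoint = comp, area, (cy, cx)
        masks.append(best_mask)
        areas[z] = best_area
        midpoints.append(midpoint)
    if not areas.any():
        raise LungNotFoundError("no right-lung candidate found in any slice")
    return LungProfile(masks=masks, areas=areas, midpoints=midpoints)


def detect_liver_dome(areas: Sequence[float], threshold: float = 0.10) -> int:
    """Locate the liver dome from the right-lung area profile.

    Returns the smallest index ``i + 2`` such that
    ``area[i+1] <= (1-threshold) * area[i]`` and
    ``area[i+2] <= (1-threshold) * area[i+1]`` with ``area[i] > 0``:
    the first slice after two consecutive qualifying decreases.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if np.count_nonzero(areas) < 3:
        raise DomeNotFoundError("need at least 3 slices with nonzero lung area")
    keep = 1.0 - threshold
    for i in range(len(areas) - 2):
        if areas[i] <= 0:
            continue
        if areas[i + 1] <= keep * areas[i] and areas[i + 2] <= keep * areas[i + 1]:
            return i + 2
    raise DomeNotFoundError("no two consecutive qualifying lung-area decreases")


def find_middle_and_last(
    counts: Sequence[float], start_slice: int, last_slice_pixel_threshold: int = 100
) -> tuple[int, int]:
    """Middle/last liver slice from per-slice in-band pixel counts.

    ``counts[k]`` is the count for slice ``start_slice + k``.  The middle
    slice is the argmax (earliest on ties); the last slice is the first
    slice after the middle whose count falls below the threshold, else the
    final slice.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size == 0:
        raise ExtentEstimationError("no slices to scan for liver extent")
    middle = int(np.argmax(counts))  # argmax takes the earliest on ties
    last = counts.size - 1
    for k in range(middle + 1, counts.size):
        if counts[k] < last_slice_pixel_threshold:
            last = k
            break
    return start_slice + middle, start_slice + last


def estimate_liver_extent(
    volume_hu: np.ndarray,
    lungs: LungProfile,
    dome: int,
    segment_slice_fn: Callable[[int], np.ndarray],
    intensity_k: float = 2.0,
    last_slice_pixel_threshold: int = 100,
    template_erosion: int = 0,
) -> tuple[LiverExtent, np.ndarray]:
    """Calibrate liver intensity and find the middle and last liver slices.

    The two slices after the dome are segmented (``segment_slice_fn``
    returns a binary liver mask for a slice index); the liver mean and
    deviation come from their liver pixels.  The right-lung mask of slice
    ``dome - 1`` templates every remaining slice, and per-slice counts of
    template pixels inside mean +/- k*deviation drive the middle/last
    rule.  Returns the extent and the template mask.
    """
    n_slices = volume_hu.shape[0]
    if dome + 2 >= n_slices:
        raise ExtentEstimationError(f"dome slice {dome} too close to volume end ({n_slices} slices)")
    liver_px = []
    for z in (dome + 1, dome + 2):
        mask = segment_slice_fn(z)
        liver_px.append(volume_hu[z][mask.astype(bool)])
    liver_px = np.concatenate(liver_px) if liver_px else np.array([])
    if liver_px.size == 0:
        raise ExtentEstimationError("calibration slices produced no liver pixels")
    mean = float(liver_px.mean())
    dev = float(liver_px.std())

    template_idx = max(dome - 1, 0)
    template = lungs.masks[template_idx].astype(bool)
    if template_erosion > 0 and template.any():
        template = ndimage.binary_erosion(template, iterations=template_erosion)
    if not template.any():
        raise ExtentEstimationError(f"right-lung template at slice {template_idx} is empty")

    lo, hi = mean - intensity_k * dev, mean + intensity_k * dev
    scan = volume_hu[dome:]
    in_band = (scan >= lo) & (scan <= hi) & template[None, :, :]
    counts = in_band.sum(axis=(1, 2))
    middle, last = find_middle_and_last(counts, dome, last_slice_pixel_threshold)
    extent = LiverExtent(
        dome_slice=dome,
        middle_slice=middle,
        last_slice=last,
        intensity_mean=mean,
        intensity_dev=dev,
    )
    return extent, template
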
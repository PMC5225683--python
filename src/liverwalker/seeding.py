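"""Automatic seed placement for the random walker.

Up to 1200 seeded pixels per slice: at most 600 marking the liver and 600
marking everything else.  Seeds are laid on a regular sub-grid (the
coarsest stride that fits the budget), so placement is deterministic and
seeds never overlap.  The first slices after the liver dome are seeded
from the right-lung template; subsequent slices reuse the previous
slice's liver segmentation, eroded for the liver side and dilated to
clear a margin for the other side.  Low/high-attenuation outlier regions
inside the liver (lesions, cysts) get their own label so the walker can
carve them out; they are merged back into the liver envelope at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

LIVER_LABEL = 1
OTHER_LABEL = 2
LESION_LABEL = 3

MAX_SEEDS_PER_SLICE = 1200
MAX_SEEDS_PER_SIDE = 600


@dataclass
class SeedMap:
    """Per-pixel seed labels for one slice (0 = unseeded)."""

    labels: np.ndarray

    def count(self, label: int) -> int:
        return int((self.labels == label).sum())

    @property
    def total(self) -> int:
        return int((self.labels != 0).sum())

    @property
    def liver_side(self) -> int:
        """Seeds on the liver side of the budget (liver + lesion labels)."""
        return int(((self.labels == LIVER_LABEL) | (self.labels >= LESION_LABEL)).sum())

    @property
    def has_liver(self) -> bool:
        return bool((self.labels == LIVER_LABEL).any())


def subsample_grid(mask: np.ndarray, cap: int) -> np.ndarray:
    """Deterministic sub-grid sample of a boolean mask, at most ``cap`` true.

    Picks the smallest stride s such that keeping pixels with
    ``row % s == 0 and col % s == 0`` leaves <= cap, so seeds spread
    evenly instead of clustering.
    """
    mask = np.asarray(mask, dtype=bool)
    count = int(mask.sum())
    if count <= cap:
        return mask.copy()
    rr, cc = np.nonzero(mask)
    s = 2
    while True:
        keep = (rr % s == 0) & (cc % s == 0)
        if keep.sum() <= cap:
            break
        s += 1
    out = np.zeros_like(mask)
    out[rr[keep], cc[keep]] = True
    return out


def place_initial_seeds(
    slice_hu: np.ndarray,
    template_mask: np.ndarray,
    body_mask: np.ndarray,
    intensity_mean: float | None = None,
    intensity_dev: float | None = None,
    intensity_k: float = 2.0,
    erosion_radius: int = 3,
    dilation_radius: int = 5,
    soft_tissue_range: tuple[float, float] = (0.0, 300.0),
) -> SeedMap:
    """Seed a slice from the dome geometry (right-lung template).

    Liver seeds: sub-grid over the eroded template restricted to the
    calibrated intensity band (or, before calibration, to a broad
    soft-tissue HU range).  Other seeds: sub-grid over body pixels outside
    a dilation of the template.  If no liver candidate survives, the map
    has zero liver seeds and the caller treats the slice as background.
    """
    slice_hu = np.asarray(slice_hu)
    template = np.asarray(template_mask, dtype=bool)
    body = np.asarray(body_mask, dtype=bool)
    core = ndimage.binary_erosion(template, iterations=erosion_radius) if erosion_radius else template
    if intensity_mean is not None and intensity_dev is not None:
        lo = intensity_mean - intensity_k * intensity_dev
        hi = intensity_mean + intensity_k * intensity_dev
    else:
        lo, hi = soft_tissue_range
    liver_cand = core & body & (slice_hu >= lo) & (slice_hu <= hi)
    # opening kills isolated noise pixels that slip through the band
    liver_cand = ndimage.binary_opening(liver_cand, structure=np.ones((3, 3)))
    cleared = ndimage.binary_dilation(liver_cand, iterations=dilation_radius) if liver_cand.any() else liver_cand
    other_cand = body & ~cleared
    labels = np.zeros(slice_hu.shape, dtype=np.int32)
    labels[subsample_grid(liver_cand, MAX_SEEDS_PER_SIDE)] = LIVER_LABEL
    labels[subsample_grid(other_cand, MAX_SEEDS_PER_SIDE)] = OTHER_LABEL
    return SeedMap(labels=labels)


def propagate_seeds(
    previous_liver: np.ndarray,
    body_mask: np.ndarray,
    slice_hu: np.ndarray | None = None,
    intensity_mean: float | None = None,
    intensity_dev: float | None = None,
    intensity_k: float = 2.0,
    erosion_radius: int = 3,
    dilation_radius: int = 5,
) -> SeedMap | None:
    """Seed a slice from the previous slice's liver segmentation.

    Liver seeds sample the eroded previous liver; when the calibrated
    intensity band is supplied, candidates outside mean +/- k*dev are
    dropped first, so a liver that retreats faster than the erosion
    margin (its caudal tip, or past a segmentation overshoot) cannot
    anchor liver seeds in soft tissue.  Other seeds sample the body
    outside a dilation of the previous liver.  Returns None when the
    previous liver is empty (caller falls back to initial seeding).
    """
    prev = np.asarray(previous_liver, dtype=bool)
    body = np.asarray(body_mask, dtype=bool)
    if not prev.any():
        return None
    core = ndimage.binary_erosion(prev, iterations=erosion_radius) if erosion_radius else prev
    if not core.any():
        core = prev  # liver thinner than the erosion element
    liver_cand = core & body
    if slice_hu is not None and intensity_mean is not None and intensity_dev is not None:
        lo = intensity_mean - intensity_k * intensity_dev
        hi = intensity_mean + intensity_k * intensity_dev
        banded = liver_cand & (np.asarray(slice_hu) >= lo) & (np.asarray(slice_hu) <= hi)
        banded = ndimage.binary_opening(banded, structure=np.ones((3, 3)))
        if banded.any():
            liver_cand = banded
    if not liver_cand.any():
        return None
    cleared = ndimage.binary_dilation(prev, iterations=dilation_radius)
    labels = np.zeros(prev.shape, dtype=np.int32)
    labels[subsample_grid(liver_cand, MAX_SEEDS_PER_SIDE)] = LIVER_LABEL
    labels[subsample_grid(body & ~cleared, MAX_SEEDS_PER_SIDE)] = OTHER_LABEL
    return SeedMap(labels=labels)


def seed_lesions(
    slice_hu: np.ndarray,
    seeds: SeedMap,
    liver_region: np.ndarray,
    intensity_mean: float,
    intensity_dev: float,
    outlier_k: float = 2.0,
    min_area: int = 30,
    region_erosion: int = 3,
) -> SeedMap:
    """Add lesion seeds for intensity-outlier regions inside the liver.

    Connected components of pixels with ``|HU - mean| > k * dev`` inside
    the (eroded) liver region, at least ``min_area`` pixels, receive the
    lesion label.  The erosion keeps the search interior: a band of
    out-of-band soft tissue hugging the region boundary (segmentation
    overshoot, partial-volume rim) is not a lesion.  Lesion seeds replace
    any liver seeds on those pixels and count toward the liver side of
    the 1200-seed budget.
    """
    slice_hu = np.asarray(slice_hu)
    region = np.asarray(liver_region, dtype=bool)
    if region_erosion > 0:
        region = ndimage.binary_erosion(region, iterations=region_erosion)
    if not region.any():
        return seeds
    outlier = region & (np.abs(slice_hu - intensity_mean) > outlier_k * intensity_dev)
    comp_labels, n = ndimage.label(outlier)
    lesion_mask = np.zeros(region.shape, dtype=bool)
    for i in range(1, n + 1):
        comp = comp_labels == i
        if comp.sum() >= min_area:
            lesion_mask |= comp
    if not lesion_mask.any():
        return seeds
    labels = seeds.labels.copy()
    labels[lesion_mask & (labels == LIVER_LABEL)] = 0  # lesion overrides liver
    budget = MAX_SEEDS_PER_SIDE - int(((labels == LIVER_LABEL) | (labels >= LESION_LABEL)).sum())
    if budget > 0:
        lesion_core = ndimage.binary_erosion(lesion_mask, iterations=1)
        if not lesion_core.any():
            lesion_core = lesion_mask
        labels[subsample_grid(lesion_core & (labels == 0), budget)] = LESION_LABEL
    return SeedMap(labels=labels)


def validate_seed_map(seeds: SeedMap, body_mask: np.ndarray) -> None:
    """Assert the per-slice seed budget and geometry invariants."""
    if seeds.total > MAX_SEEDS_PER_SLICE:
        raise AssertionError(f"{seeds.total} seeds exceed the {MAX_SEEDS_PER_SLICE} budget")
    if seeds.liver_side > MAX_SEEDS_PER_SIDE:
        raise AssertionError("liver-side seeds exceed the per-side budget")
    if seeds.count(OTHER_LABEL) > MAX_SEEDS_PER_SIDE:
        raise AssertionError("other-organ seeds exceed the per-side budget")
    if ((seeds.labels != 0) & ~np.asarray(body_mask, dtype=bool)).any():
        raise AssertionError("seed placed outside the body mask")
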
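"""End-to-end liver segmentation of a CT series.

Per-series workflow: every slice is preprocessed (table removal, top/
bottom-hat enhancement, 3x3 median); the right lung is tracked and the
liver dome located by the two-consecutive-10 %-decrease rule; the two
slices after the dome are segmented with template-derived seeds to
calibrate the liver intensity band, which fixes the middle and last liver
slices; then slices from the dome to the last liver slice are segmented
superior -> inferior — ribcage B-spline masking, automatic seeding
(template-based at the dome, propagated from the previous slice below),
multi-label random walker, argmax labelling — and the final liver mask is
the envelope of the liver and lesion labels.  Slices outside the liver
extent stay background.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from . import anatomy, preprocess, ribcage, seeding
from .random_walker import RandomWalkerParams, SolverFailure, segment_slice
from .volume_io import CTVolume, WindowSettings, apply_window

logger = logging.getLogger("liverwalker")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its documented default."""

    # display window applied before graph weighting
    window_level: float = 40.0
    window_width: float = 400.0
    use_windowed: bool = True  # walker on window-clipped intensities
    # preprocessing
    canny_sigma: float = 1.0
    hat_radius: int = 5
    # anatomy
    lung_hu_threshold: float = -400.0
    dome_decrease_fraction: float = 0.10
    last_slice_pixel_threshold: int = 100
    intensity_k: float = 2.0
    patient_right_is_image_left: bool = True
    # ribcage
    bone_hu_threshold: float = 200.0
    rib_area_min: int = 20
    rib_area_max: int = 2000
    steep_decrease_fraction: float = 0.70
    spline_degree: int = 3
    spline_samples: int = 360
    # random walker
    beta: float = 500.0
    omega: float = 1.0e-6
    lambda_s: float = 2.0
    connectivity: int = 8
    use_spatial: bool = True
    # seeding
    max_seeds_per_slice: int = 1200
    erosion_radius: int = 3
    dilation_radius: int = 5
    lesion_outlier_k: float = 2.0
    lesion_min_area: int = 30
    initial_seed_hu_min: float = 60.0
    initial_seed_hu_max: float = 200.0

    def walker_params(self) -> RandomWalkerParams:
        return RandomWalkerParams(
            beta=self.beta,
            omega=self.omega,
            lambda_s=self.lambda_s,
            connectivity=self.connectivity,
            use_spatial=self.use_spatial,
        )

    def window(self) -> WindowSettings:
        return WindowSettings(level=self.window_level, width=self.window_width)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class PipelineError(RuntimeError):
    """The series could not be segmented; diagnostics carry the stage."""


@dataclass
class SliceDiagnostics:
    slice_index: int
    stage: str  # background | segmented | failed | no-liver-seeds
    lung_area: float = 0.0
    seed_total: int = 0
    seed_liver: int = 0
    seed_other: int = 0
    seed_lesion: int = 0
    ribcage_interior_area: int = 0
    ribcage_fallback: bool = False
    labels_present: tuple[int, ...] = ()


@dataclass
class SeriesDiagnostics:
    dome_slice: int = -1
    middle_slice: int = -1
    last_slice: int = -1
    liver_mean: float = float("nan")
    liver_dev: float = float("nan")
    lung_areas: np.ndarray = field(default_factory=lambda: np.zeros(0))
    slices: list[SliceDiagnostics] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        return [dataclasses.asdict(s) for s in self.slices]


class _RibcageMasker:
    """Per-slice ribcage interior with steep-decrease fallback caching."""

    def __init__(self, proc: np.ndarray, body_masks: list, config: PipelineConfig):
        self.proc = proc
        self.body_masks = body_masks
        self.cfg = config
        self._centroids: dict[int, ribcage.RibCentroidSet | None] = {}
        self._curves: dict[int, ribcage.RibcageCurve | None] = {}

    def centroids(self, z: int) -> ribcage.RibCentroidSet | None:
        if z not in self._centroids:
            if z < 0 or z >= self.proc.shape[0] or not self.body_masks[z].mask.any():
                self._centroids[z] = None
            else:
                try:
                    self._centroids[z] = ribcage.detect_rib_centroids(
                        self.proc[z],
                        self.body_masks[z].mask,
                        bone_hu_threshold=self.cfg.bone_hu_threshold,
                        area_limits=(self.cfg.rib_area_min, self.cfg.rib_area_max),
                        source_slice=z,
                    )
                except ribcage.InsufficientCentroidsError:
                    self._centroids[z] = None
        return self._centroids[z]

    def _fit(self, cents: ribcage.RibCentroidSet, shape) -> ribcage.RibcageCurve | None:
        try:
            return ribcage.fit_ribcage_spline(
                cents, shape=shape, degree=self.cfg.spline_degree, samples=self.cfg.spline_samples
            )
        except (ribcage.DegenerateCurveError, ribcage.InsufficientCentroidsError):
            return None

    def curve(self, z: int, prev_area: int | None = None) -> tuple[ribcage.RibcageCurve | None, bool]:
        """Interior curve for slice z; True if the fallback was used."""
        shape = self.proc.shape[1:]
        cents = self.centroids(z)
        curve = self._fit(cents, shape) if cents is not None else None
        steep = (
            curve is not None
            and prev_area is not None
            and prev_area > 0
            and curve.interior_area < self.cfg.steep_decrease_fraction * prev_area
        )
        if curve is not None and not steep:
            return curve, False
        # rib-poor or steep-decrease slice: overlay neighbours' centroids
        neighbors = [c for c in (self.centroids(z - 1), self.centroids(z + 1)) if c is not None]
        if neighbors:
            try:
                merged = ribcage.fallback_centroids(neighbors, source_slice=z)
            except ribcage.InsufficientCentroidsError:
                merged = None
            if merged is not None:
                fb = self._fit(merged, shape)
                if fb is not None:
                    return fb, True
        if curve is not None:  # steep but no usable neighbours: keep own fit
            return curve, False
        logger.warning("slice %d: ribcage removal skipped (insufficient centroids)", z)
        return None, False


def segment_series(
    volume: CTVolume,
    config: PipelineConfig | None = None,
    keep_probabilities: bool = False,
) -> tuple[np.ndarray, SeriesDiagnostics, dict]:
    """Segment the liver in a CT volume.

    Returns ``(labels, diagnostics, probabilities)``: ``labels`` is a
    uint8 volume with 1 = liver envelope, 2 = lesion-labelled voxels
    (subset of the envelope reported separately); ``probabilities`` maps
    slice index -> {label: probability image} when requested.
    """
    config = config or PipelineConfig()
    hu = np.asarray(volume.voxels, dtype=np.float64)
    nz = hu.shape[0]
    diag = SeriesDiagnostics()
    probs_out: dict[int, dict[int, np.ndarray]] = {}

    # ---- preprocessing -------------------------------------------------
    body_masks: list[preprocess.BodyMask] = []
    proc_stats = np.empty_like(hu)  # removal + median: intensity decisions
    proc_edge = np.empty_like(hu)  # removal + hats + median: walker input
    for z in range(nz):
        body, stats_sl, edge_sl = preprocess.preprocess_slice(
            hu[z], canny_sigma=config.canny_sigma, hat_radius=config.hat_radius
        )
        body_masks.append(body)
        proc_stats[z] = stats_sl
        proc_edge[z] = edge_sl

    # ---- lungs and dome ------------------------------------------------
    try:
        lungs = anatomy.detect_lungs(
            proc_stats,
            body_masks,
            lung_hu_threshold=config.lung_hu_threshold,
            patient_right_is_image_left=config.patient_right_is_image_left,
        )
    except anatomy.LungNotFoundError as exc:
        raise PipelineError(f"cannot initialize: {exc}") from exc
    diag.lung_areas = lungs.areas.copy()
    try:
        dome = anatomy.detect_liver_dome(lungs.areas, threshold=config.dome_decrease_fraction)
    except anatomy.DomeNotFoundError as exc:
        raise PipelineError(f"liver dome not found: {exc}") from exc
    diag.dome_slice = dome

    masker = _RibcageMasker(proc_stats, body_masks, config)
    window = config.window()
    params = config.walker_params()
    template = lungs.masks[max(dome - 1, 0)].astype(bool)

    def masked_slice(z: int, prev_area: int | None):
        curve, used_fb = masker.curve(z, prev_area)
        if curve is None:
            return proc_stats[z], proc_edge[z], body_masks[z].mask, 0, used_fb
        m_stats = ribcage.mask_inside_ribcage(proc_stats[z], curve)
        m_edge = ribcage.mask_inside_ribcage(proc_edge[z], curve)
        effective_body = body_masks[z].mask & curve.interior
        return m_stats, m_edge, effective_body, curve.interior_area, used_fb

    def walker_image(masked_hu: np.ndarray) -> np.ndarray:
        if config.use_windowed:
            return apply_window(masked_hu, window)
        lo, hi = masked_hu.min(), masked_hu.max()
        return (masked_hu - lo) / (hi - lo) if hi > lo else np.zeros_like(masked_hu)

    # ---- liver-extent calibration (dome+1, dome+2) ---------------------
    def calibration_segment(z: int) -> np.ndarray:
        m_stats, m_edge, eff_body, _, _ = masked_slice(z, None)
        seeds = seeding.place_initial_seeds(
            m_stats,
            template,
            eff_body,
            erosion_radius=config.erosion_radius,
            dilation_radius=config.dilation_radius,
            soft_tissue_range=(config.initial_seed_hu_min, config.initial_seed_hu_max),
        )
        if not seeds.has_liver or not (seeds.labels == seeding.OTHER_LABEL).any():
            return np.zeros(m_stats.shape, dtype=bool)
        labels, _ = segment_slice(walker_image(m_edge), seeds.labels, params)
        return labels == seeding.LIVER_LABEL

    try:
        extent, template = anatomy.estimate_liver_extent(
            proc_stats,
            lungs,
            dome,
            calibration_segment,
            intensity_k=config.intensity_k,
            last_slice_pixel_threshold=config.last_slice_pixel_threshold,
        )
    except anatomy.ExtentEstimationError as exc:
        raise PipelineError(f"liver extent estimation failed: {exc}") from exc
    diag.middle_slice = extent.middle_slice
    diag.last_slice = extent.last_slice
    diag.liver_mean = extent.intensity_mean
    diag.liver_dev = extent.intensity_dev

    # ---- per-slice segmentation, dome -> last --------------------------
    out = np.zeros(hu.shape, dtype=np.uint8)
    prev_liver: np.ndarray | None = None
    prev_interior: int | None = None
    for z in range(nz):
        sd = SliceDiagnostics(slice_index=z, stage="background", lung_area=float(lungs.areas[z]))
        if z < dome or z > extent.last_slice:
            diag.slices.append(sd)
            continue
        m_stats, m_edge, eff_body, interior_area, used_fb = masked_slice(z, prev_interior)
        prev_interior = interior_area or prev_interior
        sd.ribcage_interior_area = interior_area
        sd.ribcage_fallback = used_fb

        seeds = None
        if prev_liver is not None:
            seeds = seeding.propagate_seeds(
                prev_liver, eff_body,
                slice_hu=m_stats,
                intensity_mean=extent.intensity_mean,
                intensity_dev=extent.intensity_dev,
                intensity_k=config.intensity_k,
                erosion_radius=config.erosion_radius,
                dilation_radius=config.dilation_radius,
            )
        if seeds is None:
            seeds = seeding.place_initial_seeds(
                m_stats,
                template,
                eff_body,
                intensity_mean=extent.intensity_mean,
                intensity_dev=extent.intensity_dev,
                intensity_k=config.intensity_k,
                erosion_radius=config.erosion_radius,
                dilation_radius=config.dilation_radius,
            )
        if not seeds.has_liver:
            sd.stage = "no-liver-seeds"
            diag.slices.append(sd)
            prev_liver = None
            continue
        if prev_liver is not None:
            # lesion outliers are only searched inside a known liver region;
            # the template alone cannot distinguish a lesion from adjacent
            # soft tissue, so the dome slices run without lesion labels
            seeds = seeding.seed_lesions(
                m_stats,
                seeds,
                prev_liver,
                extent.intensity_mean,
                extent.intensity_dev,
                outlier_k=config.lesion_outlier_k,
                min_area=config.lesion_min_area,
                region_erosion=config.erosion_radius,
            )
        seeding.validate_seed_map(seeds, body_masks[z].mask)
        sd.seed_total = seeds.total
        sd.seed_liver = seeds.count(seeding.LIVER_LABEL)
        sd.seed_other = seeds.count(seeding.OTHER_LABEL)
        sd.seed_lesion = seeds.total - sd.seed_liver - sd.seed_other
        if not (seeds.labels == seeding.OTHER_LABEL).any():
            # degenerate: everything is liver candidate; label whole region
            labels = np.where(eff_body, seeding.LIVER_LABEL, 0).astype(np.int32)
        else:
            try:
                labels, probs = segment_slice(walker_image(m_edge), seeds.labels, params)
            except SolverFailure as exc:
                logger.error("slice %d: solver failure (%s); marked failed", z, exc)
                sd.stage = "failed"
                diag.slices.append(sd)
                continue  # propagation falls back to the last good slice
            if keep_probabilities:
                probs_out[z] = probs.as_images()
        envelope = (labels == seeding.LIVER_LABEL) | (labels >= seeding.LESION_LABEL)
        lesion_vox = labels >= seeding.LESION_LABEL
        out[z][envelope] = 1
        out[z][lesion_vox] = 2  # still liver envelope; lesion voxels flagged
        sd.stage = "segmented"
        sd.labels_present = tuple(int(l) for l in np.unique(labels) if l != 0)
        diag.slices.append(sd)
        prev_liver = envelope
    return out, diag, probs_out


def liver_mask(labels: np.ndarray) -> np.ndarray:
    """Binary liver envelope from the pipeline's label volume."""
    return labels >= 1
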
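"""Synthetic abdominal CT phantom with ground-truth masks.

Generates a deterministic axial CT stack exhibiting exactly the anatomy
the segmentation pipeline keys on: an air background (~-1000 HU), an
elliptical soft-tissue body with a detached table arc, two low-attenuation
lungs whose area tapers caudally and collapses across a configured dome
transition (so the 10 %-decrease rule fires at a known slice), a
near-uniform liver under the right lung that grows to a configured middle
slice and shrinks to a configured last slice, a ring of bright ribs, and
optional lower-attenuation lesions inside the liver.  All geometry is
specified as fractions of the in-plane shape, so the same spec scales
between 512x512 and reduced grids.  Voxels are tissue mean + seeded
Gaussian noise; the same seed reproduces the volume bit-exactly.

Ground-truth masks follow envelope semantics: lesion voxels are part of
the liver mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .volume_io import CTVolume


@dataclass
class LesionSpec:
    """A spherical low/high-attenuation lesion inside the liver."""

    center: tuple[float, float, float]  # (slice index, row frac, col frac)
    radius_frac: float  # of min(in-plane shape)
    hu_offset: float = -60.0


@dataclass
class PhantomSpec:
    """Full parametric description of one phantom volume."""

    shape: tuple[int, int, int] = (40, 512, 512)
    seed: int = 7

    # tissue attenuation means and noise deviations (HU)
    hu_air: float = -1000.0
    hu_lung: float = -700.0
    hu_soft: float = 40.0
    hu_liver: float = 100.0
    hu_bone: float = 700.0
    noise_air: float = 5.0
    noise_lung: float = 10.0
    noise_soft: float = 10.0
    noise_liver: float = 15.0
    noise_bone: float = 20.0

    # key slice indices
    dome_slice: int = 10
    middle_slice: int = 20
    last_slice: int = 32

    # geometry, fractional of (rows, cols)
    body_center: tuple[float, float] = (0.55, 0.50)
    body_semi: tuple[float, float] = (0.38, 0.42)
    right_lung_center: tuple[float, float] = (0.45, 0.32)
    right_lung_semi: tuple[float, float] = (0.17, 0.155)
    left_lung_center: tuple[float, float] = (0.45, 0.68)
    left_lung_semi: tuple[float, float] = (0.17, 0.155)
    lung_taper: float = 0.985  # per-slice area factor above the dome
    dome_drop: float = 0.78  # area factor at the dome-1 transition slice
    liver_center: tuple[float, float] = (0.46, 0.33)
    liver_semi_max: tuple[float, float] = (0.125, 0.115)
    liver_start_area_factor: float = 0.12
    liver_tail_area_px: int = 60  # approximate liver area on the last slice

    rib_count: int = 12
    rib_radius_factor: float = 0.87
    rib_semi: tuple[float, float] = (0.022, 0.017)
    rib_poor_slices: tuple[int, ...] = ()  # slices keeping only 3 ribs

    lesions: tuple[LesionSpec, ...] = ()
    include_table: bool = True
    spacing: tuple[float, float, float] = (2.5, 0.7, 0.7)

    def validate(self) -> None:
        nz, nr, nc = self.shape
        if not (0 <= self.dome_slice <= self.middle_slice <= self.last_slice < nz):
            raise ValueError("need 0 <= dome <= middle <= last < n_slices")
        if self.dome_slice < 3:
            raise ValueError("dome_slice must leave room for the lung profile above")
        if self.noise_liver < 0:
            raise ValueError("liver noise deviation must be >= 0")
        for les in self.lesions:
            if not (self.dome_slice <= les.center[0] <= self.last_slice):
                raise ValueError(f"lesion at slice {les.center[0]} lies outside the liver extent")

    # ---- analytic geometry helpers -------------------------------------

    def _px(self, frac_rc: tuple[float, float]) -> tuple[float, float]:
        return frac_rc[0] * self.shape[1], frac_rc[1] * self.shape[2]

    def lung_area_factors(self) -> np.ndarray:
        """Per-slice area factor of both lungs (0 at and after the dome)."""
        f = np.zeros(self.shape[0])
        d = self.dome_slice
        for z in range(min(d - 1, self.shape[0])):
            f[z] = self.lung_taper**z
        if d - 1 < self.shape[0]:
            f[d - 1] = self.dome_drop * f[d - 2]
        return f

    def right_lung_analytic_areas(self) -> np.ndarray:
        """Expected right-lung pixel area per slice (pi*a*b * factor)."""
        a, b = self._px(self.right_lung_semi)
        return np.pi * a * b * self.lung_area_factors()

    def liver_area_factors(self) -> np.ndarray:
        """Per-slice liver area factor: grows to 1 at middle, shrinks to tail."""
        f = np.zeros(self.shape[0])
        a, b = self._px(self.liver_semi_max)
        full = np.pi * a * b
        tail = min(self.liver_tail_area_px / full, 1.0)
        d, m, l = self.dome_slice, self.middle_slice, self.last_slice
        for z in range(d, l + 1):
            if z <= m:
                t = 1.0 if m == d else (z - d) / (m - d)
                f[z] = self.liver_start_area_factor + (1 - self.liver_start_area_factor) * t
            else:
                t = (z - m) / (l - m)
                f[z] = 1.0 + (tail - 1.0) * t
        return f

    def liver_analytic_areas(self) -> np.ndarray:
        a, b = self._px(self.liver_semi_max)
        return np.pi * a * b * self.liver_area_factors()

    def rib_centers(self) -> np.ndarray:
        """(rib_count, 2) in-plane rib centre coordinates (row, col)."""
        cy, cx = self._px(self.body_center)
        ay, ax = self._px(self.body_semi)
        ang = 2 * np.pi * np.arange(self.rib_count) / self.rib_count
        rows = cy + self.rib_radius_factor * ay * np.sin(ang)
        cols = cx + self.rib_radius_factor * ax * np.cos(ang)
        return np.stack([rows, cols], axis=1)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = max(semi[0], 1e-9), max(semi[1], 1e-9)
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, dict[str, np.ndarray], PhantomSpec]:
    """Render the phantom volume and its ground-truth masks.

    Returns ``(volume, masks, spec)`` where ``masks`` holds boolean
    volumes ``liver`` (envelope, lesions included), ``lungs``,
    ``right_lung``, ``ribs`` and ``lesions``.
    """
    spec.validate()
    nz, nr, nc = spec.shape
    rng = np.random.default_rng(spec.seed)

    tissue = np.zeros(spec.shape, dtype=np.int8)  # 0 air 1 soft 2 lung 3 liver 4 bone 5 lesion
    right_lung = np.zeros(spec.shape, dtype=bool)
    left_lung = np.zeros(spec.shape, dtype=bool)
    liver = np.zeros(spec.shape, dtype=bool)
    ribs = np.zeros(spec.shape, dtype=bool)
    lesions = np.zeros(spec.shape, dtype=bool)

    body_center = spec._px(spec.body_center)
    body_semi = spec._px(spec.body_semi)
    lung_f = spec.lung_area_factors()
    liver_f = spec.liver_area_factors()
    rib_centers = spec.rib_centers()
    rib_semi = (spec.rib_semi[0] * nr, spec.rib_semi[1] * nc)

    plane = (nr, nc)
    body2d = _ellipse_mask(plane, body_center, body_semi)
    table2d = np.zeros(plane, dtype=bool)
    if spec.include_table:
        r0, r1 = int(0.965 * nr), int(0.985 * nr)
        c0, c1 = int(0.20 * nc), int(0.80 * nc)
        table2d[r0:r1, c0:c1] = True
        table2d &= ~body2d

    for z in range(nz):
        tissue[z][body2d] = 1
        if lung_f[z] > 0:
            s = np.sqrt(lung_f[z])
            rsemi = (spec.right_lung_semi[0] * nr * s, spec.right_lung_semi[1] * nc * s)
            lsemi = (spec.left_lung_semi[0] * nr * s, spec.left_lung_semi[1] * nc * s)
            rl = _ellipse_mask(plane, spec._px(spec.right_lung_center), rsemi) & body2d
            ll = _ellipse_mask(plane, spec._px(spec.left_lung_center), lsemi) & body2d
            right_lung[z], left_lung[z] = rl, ll
            tissue[z][rl | ll] = 2
        if liver_f[z] > 0:
            s = np.sqrt(liver_f[z])
            semi = (spec.liver_semi_max[0] * nr * s, spec.liver_semi_max[1] * nc * s)
            lv = _ellipse_mask(plane, spec._px(spec.liver_center), semi) & body2d
            liver[z] = lv
            tissue[z][lv] = 3
        keep = range(spec.rib_count) if z not in spec.rib_poor_slices else range(0, spec.rib_count, spec.rib_count // 3)
        for k in keep:
            rb = _ellipse_mask(plane, tuple(rib_centers[k]), rib_semi) & body2d
            ribs[z] |= rb
            tissue[z][rb] = 4

    for les in spec.lesions:
        zc, rf, cf = les.center
        radius = les.radius_frac * min(nr, nc)
        z_radius = max(radius * spec.spacing[1] / spec.spacing[0], 0.5)
        zz, rr, cc = np.ogrid[:nz, :nr, :nc]
        ball = ((zz - zc) / z_radius) ** 2 + ((rr - rf * nr) / radius) ** 2 + ((cc - cf * nc) / radius) ** 2 <= 1.0
        inside = ball & liver
        lesions |= inside
        tissue[inside] = 5

    means = {0: spec.hu_air, 1: spec.hu_soft, 2: spec.hu_lung, 3: spec.hu_liver, 4: spec.hu_bone}
    devs = {0: spec.noise_air, 1: spec.noise_soft, 2: spec.noise_lung, 3: spec.noise_liver, 4: spec.noise_bone}
    hu = np.empty(spec.shape, dtype=np.float64)
    noise = rng.standard_normal(spec.shape)
    for t, mean in means.items():
        sel = tissue == t
        hu[sel] = mean + devs[t] * noise[sel]
    lesion_sel = tissue == 5
    lesion_mean = np.full(spec.shape, spec.hu_liver)
    for les in spec.lesions:  # per-lesion offset
        zc, rf, cf = les.center
        radius = les.radius_frac * min(nr, nc)
        z_radius = max(radius * spec.spacing[1] / spec.spacing[0], 0.5)
        zz, rr, cc = np.ogrid[:nz, :nr, :nc]
        ball = ((zz - zc) / z_radius) ** 2 + ((rr - rf * nr) / radius) ** 2 + ((cc - cf * nc) / radius) ** 2 <= 1.0
        lesion_mean[ball] = spec.hu_liver + les.hu_offset
    hu[lesion_sel] = lesion_mean[lesion_sel] + spec.noise_liver * noise[lesion_sel]
    if spec.include_table:
        hu[:, table2d] = spec.hu_bone / 2.0 + spec.noise_soft * noise[:, table2d]

    volume = CTVolume(voxels=hu, spacing=spec.spacing)
    masks = {
        "liver": liver | lesions,  # envelope: lesions are liver
        "lungs": right_lung | left_lung,
        "right_lung": right_lung,
        "ribs": ribs,
        "lesions": lesions,
    }
    return volume, masks, spec


_PRESETS = ("healthy", "single-lesion", "multi-lesion", "rib-poor-slice", "low-contrast")


def make_test_suite(preset: str, shape: tuple[int, int, int] = (40, 512, 512), seed: int = 7) -> PhantomSpec:
    """Deterministic preset specs covering the pipeline's failure modes.

    healthy: no lesions.  single-lesion: one interior lesion.
    multi-lesion: three lesions, one touching the liver boundary.
    rib-poor-slice: one mid-liver slice keeps only 3 ribs (spline
    fallback).  low-contrast: liver barely brighter than soft tissue.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose one of {_PRESETS}")
    spec = PhantomSpec(shape=shape, seed=seed)
    if shape[0] != 40:  # rescale the key slices to the volume depth
        nz = shape[0]
        spec.dome_slice = max(3, round(0.25 * nz))
        spec.middle_slice = max(spec.dome_slice + 2, round(0.5 * nz))
        spec.last_slice = min(nz - 1, max(spec.middle_slice + 2, round(0.8 * nz)))
    if preset == "single-lesion":
        spec.lesions = (LesionSpec(center=(spec.middle_slice, 0.46, 0.33), radius_frac=0.035),)
    elif preset == "multi-lesion":
        # third lesion centred near the liver's max in-plane radius: it
        # intersects the liver boundary
        spec.lesions = (
            LesionSpec(center=(spec.middle_slice, 0.44, 0.30), radius_frac=0.030),
            LesionSpec(center=(spec.middle_slice + 4, 0.49, 0.36), radius_frac=0.025),
            LesionSpec(center=(spec.middle_slice, 0.46, 0.33 + spec.liver_semi_max[1] * 0.95), radius_frac=0.028),
        )
    elif preset == "rib-poor-slice":
        spec.rib_poor_slices = (spec.middle_slice,)
    elif preset == "low-contrast":
        spec.hu_liver = spec.hu_soft + 15.0  # |liver - adjacent tissue| <= 20 HU
    return spec
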
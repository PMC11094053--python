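"""Synthetic short-axis cine phantoms with ground-truth masks and analytic volumes.

A phantom emulates a breath-held short-axis cine stack of the left ventricle:
an annular myocardial wall around a bright blood pool, imaged over one cardiac
cycle (default 30 phases) on 11-16 parallel slices. The cavity radius shrinks
smoothly from end-diastole (phase 0) to end-systole and recovers, so analytic
end-diastolic/end-systolic volumes and LV mass are known in closed form.
Basal and apical slices may carry no labelable ventricle (empty masks), an
infarct can thin the wall over an angular sector, and image quality can be
degraded along three graded channels (artefacts, noise, general blur) that
mirror a 1 (best) to 4 (worst) visual rating per channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

MYOCARDIAL_DENSITY_G_PER_ML = 1.05

BACKGROUND, CAVITY, MYOCARDIUM = 0, 1, 2

# rendered intensities (arbitrary units in [0, 1]); blood is bright on cine MRI
_I_BACKGROUND = 0.15
_I_MYOCARDIUM = 0.45
_I_BLOOD = 0.95
_I_PAPILLARY = 0.50


@dataclass(frozen=True)
class InfarctSpec:
    """Regional wall thinning over an angular sector, as after chronic infarction."""

    sector_start_deg: float
    sector_end_deg: float
    thinning_fraction: float
    affected_slices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.thinning_fraction < 1.0):
            raise ValueError("thinning_fraction must lie in [0, 1)")
        if (self.sector_end_deg - self.sector_start_deg) % 360.0 == 0.0 and \
                self.sector_end_deg != self.sector_start_deg + 360.0:
            if self.sector_end_deg == self.sector_start_deg:
                raise ValueError("sector arc must be non-empty")


@dataclass(frozen=True)
class QualityScore:
    """Three-criterion image quality rating, each 1 (best) to 4 (worst)."""

    artefacts: int = 1
    noise: int = 1
    general: int = 1

    def __post_init__(self) -> None:
        for name in ("artefacts", "noise", "general"):
            v = getattr(self, name)
            if v not in (1, 2, 3, 4):
                raise ValueError(f"{name} score must be in {{1,2,3,4}}, got {v!r}")


def total_quality_score(q: QualityScore) -> int:
    """Sum of the three quality criteria; bounded by [3, 12]."""
    return q.artefacts + q.noise + q.general


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and acquisition parameters of one synthetic cine stack.

    ``endo_radius_px`` gives the end-diastolic endocardial radius, either one
    value for all labeled slices or one per labeled slice. ``empty_slice_margin``
    slices at each end of the stack (base and apex) are emitted with empty
    masks, mimicking slices where no ventricle is labelable.
    """

    n_slices: int = 12
    n_phases: int = 30
    image_size: int = 96
    pixel_spacing_mm: float = 0.4
    slice_thickness_mm: float = 6.0
    endo_radius_px: float | Sequence[float] = 16.0
    wall_thickness_px: float = 7.0
    contraction_fraction: float = 0.30
    infarct: InfarctSpec | None = None
    empty_slice_margin: int = 1
    papillary_muscles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if not (0.0 <= self.contraction_fraction < 1.0):
            raise ValueError("contraction_fraction must lie in [0, 1)")
        if self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("spacings must be positive")
        radii = np.atleast_1d(np.asarray(self.endo_radius_px, dtype=float))
        if np.any(radii <= 0) or self.wall_thickness_px <= 0:
            raise ValueError("radii and wall thickness must be positive")
        if np.any(radii + self.wall_thickness_px >= self.image_size / 2):
            raise ValueError("phantom geometry exceeds image bounds")
        if 2 * self.empty_slice_margin >= self.n_slices:
            raise ValueError("empty_slice_margin leaves no labeled slices")

    @property
    def labeled_slices(self) -> tuple[int, ...]:
        m = self.empty_slice_margin
        return tuple(range(m, self.n_slices - m))

    def radii_per_labeled_slice(self) -> np.ndarray:
        radii = np.atleast_1d(np.asarray(self.endo_radius_px, dtype=float))
        n = len(self.labeled_slices)
        if radii.size == 1:
            return np.full(n, radii[0])
        if radii.size != n:
            raise ValueError(
                f"endo_radius_px must be scalar or length {n} (labeled slices), got {radii.size}"
            )
        return radii.copy()


@dataclass
class CineStack:
    """4D intensity volume (slice, phase, row, col) with physical spacing."""

    data: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_phases(self) -> int:
        return self.data.shape[1]


@dataclass
class GroundTruth:
    """Per-frame label masks plus the analytic volumetry of the phantom.

    ``geometry`` retains the continuous description (center, per-slice/phase
    endocardial radii, wall thickness map) so that downstream edits such as
    infarct thinning can re-rasterize exactly.
    """

    masks: np.ndarray  # (slice, phase, row, col) uint8 in {0,1,2}
    analytic_edv_ml: float
    analytic_esv_ml: float
    analytic_lv_mass_g: float
    ed_phase: int
    es_phase: int
    geometry: dict = field(default_factory=dict)

    @property
    def analytic_ef_percent(self) -> float:
        if self.analytic_edv_ml <= 0:
            return float("nan")
        return 100.0 * (self.analytic_edv_ml - self.analytic_esv_ml) / self.analytic_edv_ml


@dataclass(frozen=True)
class DatasetSplit:
    """Animal-wise, group-stratified partition into train/validation/test."""

    train: frozenset[str]
    validation: frozenset[str]
    test: frozenset[str]

    def subset_of(self, animal: str) -> str:
        for name in ("train", "validation", "test"):
            if animal in getattr(self, name):
                return name
        raise KeyError(animal)


def _contraction_profile(n_phases: int) -> tuple[np.ndarray, int]:
    """Cosine volume profile: 0 at ED (phase 0), 1 at ES, back to 0.

    ES is placed at ``floor(0.4 * n_phases)``; the piecewise cosine gives a
    smooth single-minimum cavity-size curve so extremum-based phase selection
    is well posed.
    """
    es = max(1, int(np.floor(0.4 * n_phases)))
    p = np.arange(n_phases, dtype=float)
    s = np.empty(n_phases)
    down = p <= es
    s[down] = 0.5 * (1.0 - np.cos(np.pi * p[down] / es))
    s[~down] = 0.5 * (1.0 - np.cos(np.pi * (n_phases - p[~down]) / (n_phases - es)))
    return s, es


def _sector_mask(shape: tuple[int, int], center: tuple[float, float],
                 start_deg: float, end_deg: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    ang = np.degrees(np.arctan2(yy - center[0], xx - center[1])) % 360.0
    a0, a1 = start_deg % 360.0, end_deg % 360.0
    if (end_deg - start_deg) % 360.0 == 0.0 and end_deg != start_deg:
        return np.ones(shape, dtype=bool)
    if a0 <= a1:
        return (ang >= a0) & (ang < a1)
    return (ang >= a0) | (ang < a1)


def _rasterize_frame(shape: tuple[int, int], center: tuple[float, float],
                     r_endo: float, wall_map: np.ndarray | float) -> np.ndarray:
    """Label an annulus frame; a pixel belongs to a region if its center is inside."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    rr = np.hypot(yy - center[0], xx - center[1])
    r_epi = r_endo + wall_map
    mask = np.zeros(shape, dtype=np.uint8)
    mask[rr <= r_epi] = MYOCARDIUM
    mask[rr <= r_endo] = CAVITY
    return mask


def _wall_map(shape: tuple[int, int], center: tuple[float, float], wall: float,
              spec: InfarctSpec | None, slice_index: int) -> np.ndarray | float:
    if spec is None or slice_index not in spec.affected_slices:
        return wall
    sector = _sector_mask(shape, center, spec.sector_start_deg, spec.sector_end_deg)
    wm = np.full(shape, wall)
    wm[sector] = wall * (1.0 - spec.thinning_fraction)
    return wm


def _analytic_volumes(cfg: PhantomConfig, radii_ed: np.ndarray, profile: np.ndarray,
                      es: int) -> tuple[float, float, float]:
    dx = cfg.pixel_spacing_mm
    dz = cfg.slice_thickness_mm
    r_mm_ed = radii_ed * dx
    r_mm_es = radii_ed * (1.0 - cfg.contraction_fraction * profile[es]) * dx
    edv = float(np.sum(np.pi * r_mm_ed**2 * dz) / 1000.0)
    esv = float(np.sum(np.pi * r_mm_es**2 * dz) / 1000.0)
    # wall volume at ED; infarct thinning handled by the caller
    w_mm = cfg.wall_thickness_px * dx
    wall_vol = float(np.sum(np.pi * ((r_mm_ed + w_mm) ** 2 - r_mm_ed**2) * dz) / 1000.0)
    return edv, esv, wall_vol * MYOCARDIAL_DENSITY_G_PER_ML


def _analytic_infarct_mass_loss(cfg: PhantomConfig, radii_ed: np.ndarray,
                                spec: InfarctSpec) -> float:
    """Mass removed by sector thinning at ED, from the continuous annulus geometry."""
    dx, dz = cfg.pixel_spacing_mm, cfg.slice_thickness_mm
    arc = (spec.sector_end_deg - spec.sector_start_deg) % 360.0
    if arc == 0.0 and spec.sector_end_deg != spec.sector_start_deg:
        arc = 360.0
    frac = arc / 360.0
    w = cfg.wall_thickness_px * dx
    w_thin = w * (1.0 - spec.thinning_fraction)
    loss = 0.0
    labeled = cfg.labeled_slices
    for k, s in enumerate(labeled):
        if s not in spec.affected_slices:
            continue
        r = radii_ed[k] * dx
        full = np.pi * ((r + w) ** 2 - r**2)
        thin = np.pi * ((r + w_thin) ** 2 - r**2)
        loss += frac * (full - thin) * dz / 1000.0
    return loss * MYOCARDIAL_DENSITY_G_PER_ML


def generate_phantom_stack(cfg: PhantomConfig) -> tuple[CineStack, GroundTruth]:
    """Render one cine stack and its ground truth.

    Returns the intensity stack of shape (n_slices, n_phases, N, N) and a
    :class:`GroundTruth` whose analytic volumes come from the continuous
    geometry (sum over labeled slices of pi * r^2 * slice thickness).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.image_size
    shape = (n, n)
    # small seeded off-center jitter; the ventricle is rarely dead-center
    cy = n / 2.0 + rng.uniform(-2.0, 2.0)
    cx = n / 2.0 + rng.uniform(-2.0, 2.0)
    center = (cy, cx)

    profile, es = _contraction_profile(cfg.n_phases)
    radii_ed = cfg.radii_per_labeled_slice()

    stack = np.full((cfg.n_slices, cfg.n_phases, n, n), _I_BACKGROUND, dtype=np.float64)
    masks = np.zeros((cfg.n_slices, cfg.n_phases, n, n), dtype=np.uint8)

    # per-slice/phase endocardial radii, retained for exact re-rasterization
    radius_table = np.zeros((cfg.n_slices, cfg.n_phases))
    pap_offsets = rng.uniform(-0.5, 0.5, size=2) if cfg.papillary_muscles else None

    for k, s in enumerate(cfg.labeled_slices):
        for p in range(cfg.n_phases):
            r = radii_ed[k] * (1.0 - cfg.contraction_fraction * profile[p])
            radius_table[s, p] = r
            wall = _wall_map(shape, center, cfg.wall_thickness_px, cfg.infarct, s)
            m = _rasterize_frame(shape, center, r, wall)
            masks[s, p] = m
            img = np.full(shape, _I_BACKGROUND)
            img[m == MYOCARDIUM] = _I_MYOCARDIUM
            img[m == CAVITY] = _I_BLOOD
            if cfg.papillary_muscles and r > 6:
                # intensity-only features inside the blood pool; never labeled
                yy, xx = np.mgrid[0:n, 0:n]
                for sign, off in zip((1, -1), pap_offsets):
                    pcy = cy + sign * 0.45 * r + off
                    pcx = cx + 0.25 * r * sign
                    pap = np.hypot(yy - pcy, xx - pcx) <= 0.18 * r
                    img[pap & (m == CAVITY)] = _I_PAPILLARY
            stack[s, p] = ndimage.gaussian_filter(img, 0.7)

    edv, esv, mass = _analytic_volumes(cfg, radii_ed, profile, es)
    if cfg.infarct is not None:
        mass -= _analytic_infarct_mass_loss(cfg, radii_ed, cfg.infarct)

    gt = GroundTruth(
        masks=masks,
        analytic_edv_ml=edv,
        analytic_esv_ml=esv,
        analytic_lv_mass_g=mass,
        ed_phase=0,
        es_phase=es,
        geometry={
            "center": center,
            "radius_table": radius_table,
            "wall_thickness_px": cfg.wall_thickness_px,
            "labeled_slices": cfg.labeled_slices,
            "config": cfg,
        },
    )
    return CineStack(stack, cfg.pixel_spacing_mm, cfg.slice_thickness_mm), gt


def apply_infarct(gt: GroundTruth, spec: InfarctSpec) -> GroundTruth:
    """Thin the myocardial wall over an angular sector of the affected slices.

    The cavity is untouched; myocardium pixels in the sector beyond the
    thinned wall revert to background. Requires the phantom geometry captured
    at generation time.
    """
    if not (0.0 <= spec.thinning_fraction < 1.0):
        raise ValueError("thinning_fraction must lie in [0, 1)")
    geo = gt.geometry
    if not geo:
        raise ValueError("ground truth lacks phantom geometry; cannot re-rasterize")
    missing = [s for s in spec.affected_slices if s not in geo["labeled_slices"]]
    if missing:
        raise ValueError(f"affected slices {missing} carry no labeled ventricle")
    if spec.thinning_fraction == 0.0:
        return gt

    cfg: PhantomConfig = geo["config"]
    center = geo["center"]
    masks = gt.masks.copy()
    shape = masks.shape[-2:]
    for s in spec.affected_slices:
        wall = _wall_map(shape, center, geo["wall_thickness_px"], spec, s)
        for p in range(masks.shape[1]):
            masks[s, p] = _rasterize_frame(shape, center, geo["radius_table"][s, p], wall)

    radii_ed = cfg.radii_per_labeled_slice()
    mass = gt.analytic_lv_mass_g - _analytic_infarct_mass_loss(cfg, radii_ed, spec)
    new_geo = dict(geo)
    new_geo["config"] = replace(cfg, infarct=spec)
    return GroundTruth(masks, gt.analytic_edv_ml, gt.analytic_esv_ml, mass,
                       gt.ed_phase, gt.es_phase, new_geo)


def inject_degradation(stack: CineStack, q: QualityScore, seed: int) -> CineStack:
    """Degrade image quality along the three rated channels; masks are untouched.

    Score 1 in a channel leaves it off; higher scores monotonically increase
    the channel's strength. Noise is additive Gaussian, artefacts are
    multiplicative low-frequency shading bands (emulating B0/B1 field
    inhomogeneity at ultra-high field), and general quality is Gaussian blur.
    """
    if q == QualityScore(1, 1, 1):
        return CineStack(stack.data.copy(), stack.pixel_spacing_mm, stack.slice_thickness_mm)
    rng = np.random.default_rng(seed)
    n = stack.data.shape[-1]
    out = stack.data.copy()

    if q.general > 1:
        # per-step blur kept small relative to the phantom wall thickness so a
        # score of 3 degrades delineation without rendering frames nondiagnostic
        sigma = 0.35 * (q.general - 1)
        out = ndimage.gaussian_filter(out, sigma=(0, 0, sigma, sigma))

    if q.artefacts > 1:
        amp = 0.10 * (q.artefacts - 1)
        yy, xx = np.mgrid[0:n, 0:n] / n
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(1.0, 2.5)
        phase = rng.uniform(0, 2 * np.pi)
        band = 1.0 + amp * np.sin(2 * np.pi * freq * (yy * np.sin(theta) + xx * np.cos(theta)) + phase)
        out = out * band

    if q.noise > 1:
        sd = 0.03 * (q.noise - 1)
        out = out + rng.normal(0.0, sd, size=out.shape)

    return CineStack(out, stack.pixel_spacing_mm, stack.slice_thickness_mm)


def split_animals(animals: Sequence[tuple[str, str]],
                  counts: tuple[int, int, int],
                  seed: int,
                  quotas: dict[str, dict[str, int]] | None = None) -> DatasetSplit:
    """Animal-wise, group-stratified random split into train/validation/test.

    ``animals`` is a list of (id, group) pairs with group in {"infarct",
    "sham"}; ``counts`` are the subset sizes. Per-group quotas default to a
    largest-remainder proportional allocation of each subset's count; explicit
    quotas (subset -> group -> count) override it. Assignment within a group
    is random under ``seed``.
    """
    subset_names = ("train", "validation", "test")
    if len(counts) != 3:
        raise ValueError("counts must be (train, validation, test)")
    if sum(counts) != len(animals):
        raise ValueError(f"counts sum to {sum(counts)} but there are {len(animals)} animals")
    ids = [a for a, _ in animals]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal ids")
    groups = sorted({g for _, g in animals})
    by_group = {g: [a for a, gg in animals if gg == g] for g in groups}
    total = len(animals)

    if quotas is None:
        quotas = {name: {} for name in subset_names}
        remaining = {g: len(by_group[g]) for g in groups}
        for i, name in enumerate(subset_names):
            c = counts[i]
            if i == len(subset_names) - 1:
                alloc = dict(remaining)
            else:
                ideal = {g: c * len(by_group[g]) / total for g in groups}
                alloc = {g: min(int(np.floor(ideal[g])), remaining[g]) for g in groups}
                leftover = c - sum(alloc.values())
                order = sorted(groups, key=lambda g: ideal[g] - np.floor(ideal[g]), reverse=True)
                j = 0
                while leftover > 0:
                    g = order[j % len(order)]
                    if alloc[g] < remaining[g]:
                        alloc[g] += 1
                        leftover -= 1
                    j += 1
                    if j > 10 * len(order):
                        raise ValueError("infeasible stratification quotas")
            quotas[name] = alloc
            for g in groups:
                remaining[g] -= alloc.get(g, 0)

    for i, name in enumerate(subset_names):
        if sum(quotas[name].values()) != counts[i]:
            raise ValueError(f"quotas for {name} do not sum to {counts[i]}")
    for g in groups:
        if sum(quotas[name].get(g, 0) for name in subset_names) != len(by_group[g]):
            raise ValueError(f"quotas for group {g!r} do not cover its animals")

    rng = np.random.default_rng(seed)
    assignment: dict[str, list[str]] = {name: [] for name in subset_names}
    for g in groups:
        pool = list(by_group[g])
        rng.shuffle(pool)
        for name in subset_names:
            k = quotas[name].get(g, 0)
            assignment[name].extend(pool[:k])
            pool = pool[k:]
    return DatasetSplit(frozenset(assignment["train"]),
                        frozenset(assignment["validation"]),
                        frozenset(assignment["test"]))


def perturb_masks(masks: np.ndarray, magnitude: float, seed: int) -> np.ndarray:
    """Emulate an independent observer by jittering region boundaries.

    Each labeled frame's cavity and epicardial boundaries are displaced by a
    smooth random field with standard deviation ``magnitude`` pixels: the
    signed distance to the boundary is perturbed by low-frequency noise and
    re-thresholded. Local over- and under-segmentation partially cancel, as
    they do between human readings; disagreement grows with ``magnitude``
    (0 returns a copy).
    """
    out = masks.copy()
    if magnitude <= 0:
        return out
    rng = np.random.default_rng(seed)
    n_s, n_p = masks.shape[:2]
    for s in range(n_s):
        for p in range(n_p):
            m = masks[s, p]
            if not m.any():
                continue
            cav2 = _jitter_region(m == CAVITY, magnitude, rng)
            epi2 = _jitter_region(m > 0, magnitude, rng)
            epi2 |= cav2  # endocardium stays inside the epicardium
            new = np.zeros_like(m)
            new[epi2] = MYOCARDIUM
            new[cav2] = CAVITY
            out[s, p] = new
    return out


def _jitter_region(region: np.ndarray, magnitude: float,
                   rng: np.random.Generator) -> np.ndarray:
    if not region.any():
        return region.copy()
    signed = ndimage.distance_transform_edt(region) \
        - ndimage.distance_transform_edt(~region)
    field = ndimage.gaussian_filter(rng.normal(0.0, 1.0, region.shape), 4.0)
    sd = field.std()
    if sd > 0:
        field *= magnitude / sd
    jittered = (signed + field) > 0
    jittered = ndimage.binary_fill_holes(jittered)
    if not jittered.any():
        return region.copy()
    lab, n = ndimage.label(jittered)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        jittered = lab == (int(np.argmax(sizes)) + 1)
    return jittered


def save_phantom(stack: CineStack, gt: GroundTruth, out_dir: str | Path, scan_id: str) -> None:
    """Write the stack and masks as NIfTI plus a JSON ground-truth sidecar."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([stack.pixel_spacing_mm, stack.pixel_spacing_mm,
                      stack.slice_thickness_mm, 1.0])
    for name, arr in (("image", stack.data.astype(np.float32)),
                      ("mask", gt.masks.astype(np.uint8))):
        # stored as (row, col, slice, phase); axis order noted in the header
        vol = np.transpose(arr, (2, 3, 0, 1))
        img = nib.Nifti1Image(vol, affine)
        img.header["descrip"] = b"axes: row,col,slice,phase"
        nib.save(img, out / f"{scan_id}_{name}.nii")
    sidecar = {
        "scan": scan_id,
        "analytic_edv_ml": gt.analytic_edv_ml,
        "analytic_esv_ml": gt.analytic_esv_ml,
        "analytic_lv_mass_g": gt.analytic_lv_mass_g,
        "ed_phase": gt.ed_phase,
        "es_phase": gt.es_phase,
        "pixel_spacing_mm": stack.pixel_spacing_mm,
        "slice_thickness_mm": stack.slice_thickness_mm,
    }
    (out / f"{scan_id}_truth.json").write_text(json.dumps(sidecar, indent=2))
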
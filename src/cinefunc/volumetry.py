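"""ED/ES phase selection and cardiac-function volumetry from label masks.

Volumes are computed by voxel counting: the blood-pool volume of a phase is
the number of cavity voxels across all slices times the voxel volume. The
end-diastolic phase (ED) maximises the blood-pool volume, end-systole (ES)
minimises it. Stroke volume SV = EDV - ESV, ejection fraction
EF = 100 * SV / EDV, and LV mass is the myocardial volume at ED (epicardial
minus endocardial volume) times the myocardial density of 1.05 g/ml.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import CAVITY, MYOCARDIAL_DENSITY_G_PER_ML


@dataclass(frozen=True)
class VolumetryConfig:
    pixel_spacing_mm: tuple[float, float] = (0.4, 0.4)
    slice_thickness_mm: float = 6.0
    myocardial_density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML

    def __post_init__(self) -> None:
        dx, dy = self.pixel_spacing_mm
        if dx <= 0 or dy <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("spacings must be positive")
        if self.myocardial_density_g_per_ml <= 0:
            raise ValueError("density must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy = self.pixel_spacing_mm
        return dx * dy * self.slice_thickness_mm


@dataclass
class CardiacFunction:
    """Clinical endpoint record for one scan."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_percent: float
    lv_mass_g: float
    ed_phase: int
    es_phase: int
    missing_label_slices: int = 0
    ef_defined: bool = True


def blood_pool_volume(phase_masks: np.ndarray, cfg: VolumetryConfig) -> float:
    """Blood-pool volume in ml of one phase: cavity voxel count x voxel volume.

    ``phase_masks`` holds the label masks of all slices at one phase,
    shape (n_slices, rows, cols). Empty masks contribute zero.
    """
    n_vox = int(np.count_nonzero(np.asarray(phase_masks) == CAVITY))
    return n_vox * cfg.voxel_volume_mm3 / 1000.0


def _labeled_volume(phase_masks: np.ndarray, cfg: VolumetryConfig) -> float:
    """Epicardial volume in ml: voxels labeled cavity or myocardium."""
    n_vox = int(np.count_nonzero(np.asarray(phase_masks) > 0))
    return n_vox * cfg.voxel_volume_mm3 / 1000.0


def select_ed_es(per_phase_volumes: np.ndarray) -> tuple[int, int]:
    """ED = phase of largest blood-pool volume, ES = smallest; earliest wins ties."""
    v = np.asarray(per_phase_volumes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 phases to select ED/ES")
    ed = int(np.argmax(v))
    es = int(np.argmin(v))
    if v[ed] == v[es]:
        warnings.warn("constant volume curve: ED and ES coincide", stacklevel=2)
    return ed, es


def compute_function(masks: np.ndarray, cfg: VolumetryConfig,
                     ed_phase: int | None = None,
                     es_phase: int | None = None) -> CardiacFunction:
    """Cardiac function from a (slice, phase, row, col) label-mask stack.

    ED/ES default to the volume extrema but can be pinned externally, as when
    several observers must read the same phases. Slices with absent labels at
    ED or ES contribute zero volume; their count is reported because missing
    labels artificially reduce volumes. EDV = 0 leaves EF undefined (flagged
    via ``ef_defined``), never silently zero.
    """
    masks = np.asarray(masks)
    if masks.ndim != 4:
        raise ValueError("expected (slice, phase, row, col) masks")
    n_phases = masks.shape[1]
    volumes = np.array([blood_pool_volume(masks[:, p], cfg) for p in range(n_phases)])
    auto_ed, auto_es = select_ed_es(volumes)
    ed = auto_ed if ed_phase is None else int(ed_phase)
    es = auto_es if es_phase is None else int(es_phase)

    edv = volumes[ed]
    esv = volumes[es]
    sv = edv - esv
    epi_vol = _labeled_volume(masks[:, ed], cfg)
    lv_mass = (epi_vol - edv) * cfg.myocardial_density_g_per_ml

    missing = int(sum((~masks[:, p].any(axis=(1, 2))).sum() for p in (ed, es)))

    if edv > 0:
        ef = 100.0 * sv / edv
        ef_defined = True
    else:
        ef = float("nan")
        ef_defined = False
        warnings.warn("EDV is zero: EF undefined", stacklevel=2)
    return CardiacFunction(edv_ml=float(edv), esv_ml=float(esv), sv_ml=float(sv),
                           ef_percent=float(ef), lv_mass_g=float(lv_mass),
                           ed_phase=ed, es_phase=es,
                           missing_label_slices=missing, ef_defined=ef_defined)
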
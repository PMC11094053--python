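"""Dice and Hausdorff agreement between segmentations, with absent-label conventions.

Dice measures volumetric overlap of filled regions (2|A∩B| / (|A|+|B|));
the Hausdorff distance (HD) is the symmetric maximum of directed minimum
Euclidean distances between boundary point sets. When exactly one of the two
labels is absent the pair scores Dice 0 and HD +infinity; when both are
absent the metrics are undefined and the pair is excluded from aggregation.
Dice is aggregated by the mean, HD by the median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.distance import directed_hausdorff


class PairStatus(str, Enum):
    BOTH_PRESENT = "both_present"
    REFERENCE_ONLY = "reference_only"
    PREDICTION_ONLY = "prediction_only"
    BOTH_ABSENT = "both_absent"


class PredictionClass(str, Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    MISSING = "missing"
    EXCLUDED = "excluded"


@dataclass
class PairwiseAgreement:
    """Agreement of one predicted frame with its reference frame."""

    status: PairStatus
    dice_lv: float | None = None
    dice_my: float | None = None
    hd_lv: float | None = None
    hd_my: float | None = None


@dataclass
class AggregateAgreement:
    mean_dice_lv: float
    mean_dice_my: float
    median_hd_lv: float
    median_hd_my: float
    n_pairs: int


def dice(region_a: np.ndarray, region_b: np.ndarray) -> float:
    """Dice overlap of two boolean regions on the same grid.

    Returns 0 when exactly one region is empty; raises when both are empty
    (the pair is undefined and must be excluded upstream).
    """
    a = np.asarray(region_a, dtype=bool)
    b = np.asarray(region_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined: both regions empty")
    if na == 0 or nb == 0:
        return 0.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def hausdorff(contour_a: np.ndarray | None, contour_b: np.ndarray | None) -> float:
    """Symmetric Hausdorff distance between two point sets (pixel coordinates).

    +infinity when exactly one contour is absent; undefined (raises) when
    both are.
    """
    a_absent = contour_a is None or len(contour_a) == 0
    b_absent = contour_b is None or len(contour_b) == 0
    if a_absent and b_absent:
        raise ValueError("Hausdorff undefined: both contours absent")
    if a_absent or b_absent:
        return math.inf
    a = np.asarray(contour_a, dtype=float)
    b = np.asarray(contour_b, dtype=float)
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def classify_prediction(pred: np.ndarray, ref: np.ndarray, tau: float = 0.5) -> PredictionClass:
    """Classify one predicted frame as correct / incorrect / missing / excluded.

    Frames without a manual reference label are excluded (they were never
    evaluated); an empty prediction against a nonempty reference is missing;
    otherwise the myocardium Dice against ``tau`` decides correct vs incorrect.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError("grid mismatch")
    if not ref.any():
        return PredictionClass.EXCLUDED
    if not pred.any():
        return PredictionClass.MISSING
    if (pred == 2).any() or (ref == 2).any():
        d = dice(pred == 2, ref == 2)
    else:  # cavity-only frames: judge on the blood pool instead
        d = dice(pred == 1, ref == 1)
    return PredictionClass.CORRECT if d >= tau else PredictionClass.INCORRECT


def status_tally(classes: list[PredictionClass]) -> dict[str, float]:
    """Percentages of correct/incorrect/missing among evaluated (non-excluded) frames."""
    kept = [c for c in classes if c is not PredictionClass.EXCLUDED]
    if not kept:
        raise ValueError("no evaluated frames")
    n = len(kept)
    return {
        "n": n,
        "correct_percent": 100.0 * sum(c is PredictionClass.CORRECT for c in kept) / n,
        "incorrect_percent": 100.0 * sum(c is PredictionClass.INCORRECT for c in kept) / n,
        "missing_percent": 100.0 * sum(c is PredictionClass.MISSING for c in kept) / n,
    }


def pairwise_agreement(pred: np.ndarray, ref: np.ndarray) -> PairwiseAgreement:
    """Per-frame Dice (LV cavity and myocardium) and boundary HD for a mask pair."""
    from .contours import mask_to_contours

    pred = np.asarray(pred)
    ref = np.asarray(ref)
    p_has, r_has = bool(pred.any()), bool(ref.any())
    if not p_has and not r_has:
        return PairwiseAgreement(PairStatus.BOTH_ABSENT)
    if not p_has:
        return PairwiseAgreement(PairStatus.REFERENCE_ONLY, 0.0, 0.0, math.inf, math.inf)
    if not r_has:
        return PairwiseAgreement(PairStatus.PREDICTION_ONLY, 0.0, 0.0, math.inf, math.inf)

    d_lv = _dice_or_zero(pred == 1, ref == 1)
    d_my = _dice_or_zero(pred == 2, ref == 2)
    cp_p = mask_to_contours(pred)
    cp_r = mask_to_contours(ref)
    hd_lv = _hd_or_inf(cp_p.endo, cp_r.endo)
    hd_my = _hd_or_inf(cp_p.epi, cp_r.epi)
    return PairwiseAgreement(PairStatus.BOTH_PRESENT, d_lv, d_my, hd_lv, hd_my)


def _dice_or_zero(a: np.ndarray, b: np.ndarray) -> float | None:
    if not a.any() and not b.any():
        return None
    return dice(a, b)


def _hd_or_inf(a: np.ndarray | None, b: np.ndarray | None) -> float | None:
    a_absent = a is None or len(a) == 0
    b_absent = b is None or len(b) == 0
    if a_absent and b_absent:
        return None
    return hausdorff(a, b)


def aggregate(pairs: list[PairwiseAgreement]) -> AggregateAgreement:
    """Mean Dice and median HD over pairs with defined metrics.

    Infinite HDs participate in the median as +infinity. (A display cap of
    100 exists for plotting only and never enters this computation.)
    """
    defined = [p for p in pairs if p.status is not PairStatus.BOTH_ABSENT]
    if not defined:
        raise ValueError("no pairs with defined metrics")

    def _vals(attr: str) -> list[float]:
        return [getattr(p, attr) for p in defined if getattr(p, attr) is not None]

    return AggregateAgreement(
        mean_dice_lv=float(np.mean(_vals("dice_lv"))),
        mean_dice_my=float(np.mean(_vals("dice_my"))),
        median_hd_lv=_median_with_inf(_vals("hd_lv")),
        median_hd_my=_median_with_inf(_vals("hd_my")),
        n_pairs=len(defined),
    )


def _median_with_inf(values: list[float]) -> float:
    """Median as an order statistic so +inf is handled exactly."""
    v = sorted(values)
    n = len(v)
    if n == 0:
        return math.nan
    mid = n // 2
    if n % 2 == 1:
        return float(v[mid])
    lo, hi = v[mid - 1], v[mid]
    if math.isinf(lo) and math.isinf(hi):
        return math.inf
    return (lo + hi) / 2.0


def cap_for_display(values: np.ndarray, cap: float = 100.0) -> np.ndarray:
    """Map values above ``cap`` (including +inf) to ``cap`` for plotting only."""
    return np.minimum(np.asarray(values, dtype=float), cap)
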
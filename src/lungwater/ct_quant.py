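"""Densitometric lung-water quantification from HU volumes and lung masks.

A voxel of Hounsfield unit ``h`` carries a tissue weight fraction of
``1 + h/1000`` (air = -1000 HU -> 0, water = 0 HU -> 1 g/ml).  Summed over the
voxels inside the edema HU window this yields the calculated lung weight;
subtracting the height-predicted expected lung weight and dividing by ideal
body weight gives the CT-derived extravascular lung water index (ml/kg),
taking 1 g of excess tissue as 1 ml of lung water.

Note the per-voxel form ``(1 + HU/1000) * v`` is the unique one consistent
with the closed form ``(1 - meanHU/(-1000)) * V``; the sometimes-quoted
``(1 - (HU - 1000)/1000)`` variant would assign water a density of 2 g/ml
and is not used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import (
    AlignmentError,
    EmptySelectionError,
    NumericError,
    ValidationError,
)

__all__ = [
    "CTVolume",
    "LungMask",
    "HUWindow",
    "PatientAnthro",
    "LungQuantResult",
    "DEFAULT_WINDOW",
    "IBW_RULES",
    "select_edema_voxels",
    "lung_weight",
    "expected_lung_weight",
    "ideal_body_weight",
    "evlwi_ct",
    "quantify_scan",
    "dice_coefficient",
]


@dataclass(frozen=True)
class CTVolume:
    """A 3-D Hounsfield-unit array with per-axis voxel spacing in mm."""

    hu: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        if hu.ndim != 3:
            raise ValidationError(f"CT volume must be rank 3, got rank {hu.ndim}")
        if not np.all(np.isfinite(hu)):
            raise ValidationError("CT volume contains non-finite HU values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in ml (product of spacings in mm^3, / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class LungMask:
    """A binary 3-D segmentation mask aligned to a :class:`CTVolume`."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 3:
            raise ValidationError(f"mask must be rank 3, got rank {arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError("mask values must be binary (0/1)")
            arr = arr.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "mask", arr)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class HUWindow:
    """Inclusive HU interval retained for quantification."""

    lower: float = -700.0
    upper: float = 200.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValidationError(f"HU window requires lower < upper, got [{self.lower}, {self.upper}]")


#: Edema window: -700 to 200 HU inclusive; HU > 200 is treated as contrast.
DEFAULT_WINDOW = HUWindow(-700.0, 200.0)


@dataclass(frozen=True)
class PatientAnthro:
    """Height (m), sex, and optionally actual weight (kg) of one patient."""

    height: float
    sex: Literal["male", "female"]
    actual_weight: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not np.isfinite(self.height) or self.height <= 0:
            raise ValidationError(f"height must be a positive number of metres, got {self.height}")
        if not 1.2 <= self.height <= 2.2:
            warnings.warn(
                f"height {self.height} m outside the plausible range [1.2, 2.2] m",
                stacklevel=3,
            )


@dataclass(frozen=True)
class LungQuantResult:
    """Quantification output for a single scan.

    Units: lung_volume ml, mean_hu HU, lung_weight and expected_lung_weight g,
    ibw kg, evlwi_ct ml/kg.
    """

    included_voxel_count: int
    lung_volume: float
    mean_hu: float
    lung_weight: float
    expected_lung_weight: float
    ibw: float
    evlwi_ct: float
    window: HUWindow = field(default=DEFAULT_WINDOW)
    ibw_rule: str = "devine"
    window_only: bool = True


def _check_aligned(volume: CTVolume, mask: LungMask) -> None:
    if volume.hu.shape != mask.mask.shape:
        raise AlignmentError(
            f"volume shape {volume.hu.shape} != mask shape {mask.mask.shape}"
        )
    if not np.allclose(volume.spacing, mask.spacing):
        raise AlignmentError(
            f"volume spacing {volume.spacing} != mask spacing {mask.spacing}"
        )


def select_edema_voxels(
    volume: CTVolume, mask: LungMask, window: HUWindow = DEFAULT_WINDOW
) -> np.ndarray:
    """Return the HU values of masked voxels inside the window (inclusive).

    Voxels above the upper bound (contrast agent, > 200 HU by default) and
    below the lower bound (hyperaerated) are dropped.  Raises
    :class:`EmptySelectionError` if the mask itself is empty.
    """
    _check_aligned(volume, mask)
    if mask.voxel_count == 0:
        raise EmptySelectionError("lung mask is empty; nothing to quantify")
    vals = volume.hu[mask.mask]
    return vals[(vals >= window.lower) & (vals <= window.upper)]


def lung_weight(hu_values: np.ndarray, voxel_volume_ml: float) -> float:
    """Calculated lung weight in g: sum over voxels of (1 + HU/1000) * v.

    Numerically identical to the mean-HU closed form
    ``(1 - meanHU/(-1000)) * total_volume``.
    """
    if voxel_volume_ml <= 0:
        raise ValidationError(f"voxel volume must be > 0 ml, got {voxel_volume_ml}")
    vals = np.asarray(hu_values, dtype=float)
    if vals.size == 0:
        raise EmptySelectionError("no voxels selected; mean HU (hence lung weight) undefined")
    return float(np.sum(1.0 + vals / 1000.0) * voxel_volume_ml)


# Expected (height-predicted) lung weight, linear in height (m).
_ELW_INTERCEPT = -1806.1
_ELW_SLOPE = 1633.7


def expected_lung_weight(anthro: PatientAnthro) -> float:
    """Height-predicted normal lung weight in g: -1806.1 + 1633.7 * height(m)."""
    w = _ELW_INTERCEPT + _ELW_SLOPE * anthro.height
    if w <= 0:
        raise ValidationError(
            f"expected lung weight {w:.1f} g non-positive at height {anthro.height} m; "
            "formula not valid below ~1.106 m"
        )
    return float(w)


def _ibw_devine(anthro: PatientAnthro) -> float:
    height_cm = anthro.height * 100.0
    base = 50.0 if anthro.sex == "male" else 45.5
    ibw = base + 0.91 * (height_cm - 152.4)
    if height_cm < 152.4:
        warnings.warn(
            f"height {height_cm:.1f} cm below 152.4 cm; IBW falls below the base constant",
            stacklevel=4,
        )
    return float(ibw)


#: Configurable IBW rules; "devine" (sex-specific predicted body weight) is the default.
IBW_RULES = {"devine": _ibw_devine}


def ideal_body_weight(anthro: PatientAnthro, rule: str = "devine") -> float:
    """Ideal (predicted) body weight in kg under the named rule.

    Default rule: male 50 + 0.91*(height_cm - 152.4); female 45.5 + same slope.
    """
    try:
        fn = IBW_RULES[rule]
    except KeyError:
        raise ValidationError(f"unknown IBW rule {rule!r}; known: {sorted(IBW_RULES)}") from None
    ibw = fn(anthro)
    if ibw <= 0:
        raise ValidationError(f"IBW {ibw:.2f} kg non-positive at height {anthro.height} m")
    return ibw


def evlwi_ct(lung_weight_g: float, expected_lung_weight_g: float, ibw_kg: float) -> float:
    """CT-derived EVLWI in ml/kg: (calculated - expected lung weight) / IBW.

    1 g of excess tissue is taken as 1 ml of extravascular lung water.
    Negative values (drier-than-expected lung) are returned, not clipped.
    """
    if ibw_kg <= 0:
        raise ValidationError(f"IBW must be > 0 kg, got {ibw_kg}")
    return float((lung_weight_g - expected_lung_weight_g) / ibw_kg)


def quantify_scan(
    volume: CTVolume,
    mask: LungMask,
    anthro: PatientAnthro,
    window: HUWindow = DEFAULT_WINDOW,
    ibw_rule: str = "devine",
    window_only: bool = True,
) -> LungQuantResult:
    """Full per-scan quantification: voxel selection, weights, EVLWI_CT.

    With ``window_only`` (default) both lung volume and weight are integrated
    over windowed voxels only; set it False to integrate weight over windowed
    voxels but volume over the full mask (sensitivity analysis).
    """
    selected = select_edema_voxels(volume, mask, window)
    if selected.size == 0:
        raise EmptySelectionError(
            f"no masked voxels inside the HU window [{window.lower}, {window.upper}]"
        )
    vv = volume.voxel_volume_ml
    weight = lung_weight(selected, vv)
    if window_only:
        volume_ml = selected.size * vv
    else:
        volume_ml = mask.voxel_count * vv
    elw = expected_lung_weight(anthro)
    ibw = ideal_body_weight(anthro, rule=ibw_rule)
    return LungQuantResult(
        included_voxel_count=int(selected.size),
        lung_volume=float(volume_ml),
        mean_hu=float(selected.mean()),
        lung_weight=weight,
        expected_lung_weight=elw,
        ibw=ibw,
        evlwi_ct=evlwi_ct(weight, elw, ibw),
        window=window,
        ibw_rule=ibw_rule,
        window_only=window_only,
    )


def dice_coefficient(mask_a: LungMask, mask_b: LungMask) -> float:
    """DICE overlap 2|A∩B| / (|A| + |B|) between two binary masks."""
    a, b = mask_a.mask, mask_b.mask
    if a.shape != b.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size_a = int(a.sum())
    size_b = int(b.sum())
    if size_a + size_b == 0:
        raise NumericError("DICE undefined: both masks are empty")
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (size_a + size_b)
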
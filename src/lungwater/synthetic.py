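"""Ground-truth-known synthetic data: CT phantoms and patient cohorts.

Phantoms are two ellipsoidal "lungs" inside an ellipsoidal soft-tissue body
on an air background, with optional contrast-like (> 200 HU) voxels inside
the lungs and effusion-like (~+10 HU) voxels hugging the lung boundary.  The
returned truth record is computed from the realized (post-noise) voxel values
so recovery tests can be exact.

Cohorts are drawn from a three-parameter linear model
evlwi_tptd = intercept + slope_ct * evlwi_ct + ecbf_coef * ecbf + N(0, sd),
with right-skewed gamma EVLWI_CT, truncated-normal ECBF and normal heights.
All generators are deterministic in their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .ct_quant import CTVolume, DEFAULT_WINDOW, HUWindow, LungMask, PatientAnthro, evlwi_ct as _evlwi_ct, expected_lung_weight, ideal_body_weight
from .errors import ValidationError

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortGenParams",
    "generate_phantom",
    "generate_cohort",
    "degrade_mask",
]

# gamma parameters fitted numerically to the target quartiles
# (q1 5.8, median 10.2, q3 14.8 ml/kg) by least squares
EVLWI_CT_GAMMA_SHAPE = 2.522475411641151
EVLWI_CT_GAMMA_SCALE = 4.472148607694263


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and composition of a synthetic chest phantom.

    ``lung_geometry`` is a tuple of two (center, semi_axes) pairs in voxel
    coordinates; ``body_geometry`` one (center, semi_axes) pair enclosing the
    lungs.  HU in the usual scale (air -1000, water 0).
    """

    shape: tuple[int, int, int] = (40, 56, 56)
    spacing: tuple[float, float, float] = (2.5, 1.5, 1.5)
    lung_geometry: tuple = (
        ((20.0, 28.0, 16.0), (14.0, 16.0, 9.0)),
        ((20.0, 28.0, 40.0), (14.0, 16.0, 9.0)),
    )
    body_geometry: tuple = ((20.0, 28.0, 28.0), (19.0, 26.0, 27.0))
    lung_mean_hu: float = -500.0
    hu_noise_sd: float = 0.0
    contrast_fraction: float = 0.0
    effusion_fraction: float = 0.0
    body_hu: float = 40.0
    background_hu: float = -1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1000.0 < self.lung_mean_hu <= 200.0):
            raise ValidationError(f"lung_mean_hu must be in (-1000, 200], got {self.lung_mean_hu}")
        for name in ("contrast_fraction", "effusion_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if self.hu_noise_sd < 0:
            raise ValidationError("hu_noise_sd must be >= 0")


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth for one generated phantom (post-noise voxels)."""

    true_lung_volume: float  # ml, voxels inside the HU window
    true_lung_weight: float  # g
    true_mean_hu: float
    true_evlwi_ct: float | None
    ground_truth_mask: LungMask = field(repr=False)
    included_voxel_count: int = 0
    contrast_voxel_count: int = 0


def _ellipsoid(shape: tuple[int, int, int], center, semi_axes) -> np.ndarray:
    center = np.asarray(center, dtype=float)
    semi = np.asarray(semi_axes, dtype=float)
    if np.any(semi <= 0):
        raise ValidationError("ellipsoid semi-axes must be > 0")
    if np.any(center - semi < -0.5) or np.any(center + semi > np.asarray(shape) - 0.5):
        raise ValidationError(
            f"ellipsoid (center {tuple(center)}, semi-axes {tuple(semi)}) "
            f"does not fit inside the volume {shape}"
        )
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def generate_phantom(
    spec: PhantomSpec,
    anthro: PatientAnthro | None = None,
    window: HUWindow = DEFAULT_WINDOW,
) -> tuple[CTVolume, LungMask, PhantomTruth]:
    """Build a phantom volume, its lung mask, and the matching ground truth.

    Lung voxel HU are N(lung_mean_hu, hu_noise_sd) clipped to (-1000, 200];
    ``floor(contrast_fraction * n_lung)`` voxels are replaced by contrast-like
    HU in (200, 500].  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    lung = np.zeros(spec.shape, dtype=bool)
    for center, semi in spec.lung_geometry:
        lung |= _ellipsoid(spec.shape, center, semi)
    body = _ellipsoid(spec.shape, *spec.body_geometry)
    if not np.all(body[lung]):
        raise ValidationError("lung ellipsoids must lie inside the body ellipsoid")

    hu = np.full(spec.shape, float(spec.background_hu))
    hu[body] = spec.body_hu
    n_lung = int(lung.sum())
    vals = rng.normal(spec.lung_mean_hu, spec.hu_noise_sd, size=n_lung)
    vals = np.clip(vals, np.nextafter(-1000.0, 0.0), 200.0)

    n_contrast = int(np.floor(spec.contrast_fraction * n_lung))
    if n_contrast:
        idx = rng.choice(n_lung, size=n_contrast, replace=False)
        vals[idx] = 500.0 - rng.uniform(0.0, 300.0, size=n_contrast)  # (200, 500]
    hu[lung] = vals

    if spec.effusion_fraction:
        shell = ndimage.binary_dilation(lung) & body & ~lung
        cand = np.flatnonzero(shell)
        k = int(np.floor(spec.effusion_fraction * cand.size))
        if k:
            pick = rng.choice(cand, size=k, replace=False)
            hu.flat[pick] = 10.0

    mask = LungMask(lung, spec.spacing)
    volume = CTVolume(hu, spec.spacing)

    vv = volume.voxel_volume_ml
    inside = (vals >= window.lower) & (vals <= window.upper)
    sel = vals[inside]
    true_volume = float(sel.size * vv)
    true_weight = float(np.sum(1.0 + sel / 1000.0) * vv) if sel.size else 0.0
    true_mean = float(sel.mean()) if sel.size else float("nan")
    true_evlwi = None
    if anthro is not None:
        true_evlwi = _evlwi_ct(true_weight, expected_lung_weight(anthro), ideal_body_weight(anthro))
    truth = PhantomTruth(
        true_lung_volume=true_volume,
        true_lung_weight=true_weight,
        true_mean_hu=true_mean,
        true_evlwi_ct=true_evlwi,
        ground_truth_mask=mask,
        included_voxel_count=int(sel.size),
        contrast_voxel_count=n_contrast,
    )
    return volume, mask, truth


@dataclass(frozen=True)
class CohortGenParams:
    """Generative parameters for a synthetic paired cohort.

    Defaults: regression coefficients of the fitted clinical model
    (intercept 5.054, CT slope 0.4711, ECBF coefficient 3.439), gamma
    EVLWI_CT calibrated to median ~10 / IQR ~5.8-14.8 ml/kg, ECBF
    N(3.9, 1.1) truncated to [1.0, 6.5] l/min, height N(1.77, 0.09) m,
    23% female.  residual_sd 8 ml/kg is an assumption, not a fitted value.
    """

    n: int = 64
    intercept: float = 5.054
    slope_ct: float = 0.4711
    ecbf_coef: float = 3.439
    residual_sd: float = 8.0
    evlwi_ct_shape: float = EVLWI_CT_GAMMA_SHAPE
    evlwi_ct_scale: float = EVLWI_CT_GAMMA_SCALE
    ecbf_mean: float = 3.9
    ecbf_sd: float = 1.1
    ecbf_bounds: tuple[float, float] = (1.0, 6.5)
    height_mean: float = 1.77
    height_sd: float = 0.09
    female_fraction: float = 0.23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be >= 0")
        if self.evlwi_ct_shape <= 0 or self.evlwi_ct_scale <= 0:
            raise ValidationError("gamma parameters must be > 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValidationError("female_fraction must be in [0, 1]")
        lo, hi = self.ecbf_bounds
        if not lo < hi or lo < 0:
            raise ValidationError(f"bad ecbf bounds {self.ecbf_bounds}")


def generate_cohort(params: CohortGenParams) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table plus the generative record for recovery testing.

    Columns: patient_id, evlwi_ct, evlwi_tptd, ecbf, height_m, sex,
    time_offset_h.  EVLWI_CT and ECBF are drawn independently (joint
    distribution unknown; independence is assumed).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    evlwi = rng.gamma(params.evlwi_ct_shape, params.evlwi_ct_scale, size=n)
    lo, hi = params.ecbf_bounds
    a = (lo - params.ecbf_mean) / params.ecbf_sd
    b = (hi - params.ecbf_mean) / params.ecbf_sd
    ecbf = stats.truncnorm.rvs(
        a, b, loc=params.ecbf_mean, scale=params.ecbf_sd, size=n, random_state=rng
    )
    height = rng.normal(params.height_mean, params.height_sd, size=n)
    sex = np.where(rng.random(n) < params.female_fraction, "female", "male")
    noise = rng.normal(0.0, params.residual_sd, size=n) if params.residual_sd > 0 else np.zeros(n)
    tptd = params.intercept + params.slope_ct * evlwi + params.ecbf_coef * ecbf + noise
    table = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "evlwi_ct": evlwi,
            "evlwi_tptd": tptd,
            "ecbf": ecbf,
            "height_m": height,
            "sex": sex,
            "time_offset_h": rng.uniform(0.0, 6.0, size=n),
        }
    )
    record = asdict(params)
    record["ecbf_bounds"] = list(params.ecbf_bounds)
    return table, record


def degrade_mask(
    mask: LungMask,
    erosion_steps: int,
    seed: int | None = None,
    flip_fraction: float = 0.0,
) -> LungMask:
    """Degrade a mask by morphological erosion plus optional boundary flips.

    Erosion uses 6-connectivity.  With ``flip_fraction`` 0 the output is a
    subset of the input.  Flips toggle a random fraction of the boundary-shell
    voxels of the eroded mask.  Raises if the mask empties completely.
    """
    if erosion_steps < 0:
        raise ValidationError("erosion_steps must be >= 0")
    if not 0.0 <= flip_fraction < 1.0:
        raise ValidationError("flip_fraction must be in [0, 1)")
    out = mask.mask.copy()
    if erosion_steps:
        out = ndimage.binary_erosion(out, iterations=erosion_steps)
    if flip_fraction:
        rng = np.random.default_rng(seed)
        inner = ndimage.binary_erosion(out)
        outer = ndimage.binary_dilation(out)
        shell = outer & ~inner
        cand = np.flatnonzero(shell)
        k = int(np.floor(flip_fraction * cand.size))
        if k:
            pick = rng.choice(cand, size=k, replace=False)
            flat = out.ravel()
            flat[pick] = ~flat[pick]
            out = flat.reshape(out.shape)
    if not out.any():
        raise ValidationError("degradation emptied the mask completely")
    return LungMask(out, mask.spacing)
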
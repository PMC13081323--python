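"""Readers and writers: NIfTI volumes/masks, cohort CSV, quantification CSV.

NIfTI is the volume contract (.nii / .nii.gz); spacing comes from the header
zooms.  Masks stored as floats are binarized at 0.5.  Cohort files are UTF-8
CSV with decimal points and a documented header; lines starting with '#' are
comments.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .correction import CorrectionModel  # noqa: F401  (re-export convenience)
from .ct_quant import CTVolume, LungMask, LungQuantResult
from .errors import FormatError, ValidationError

__all__ = [
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
    "quant_result_to_csv",
]

COHORT_COLUMNS = ("patient_id", "evlwi_ct", "evlwi_tptd", "ecbf", "height_m", "sex")
_OPTIONAL_COLUMNS = ("time_offset_h", "evlwi_tptd_corr")


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()
    except FormatError:
        raise
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got rank {data.ndim}")
    spacing = tuple(float(z) for z in zooms[:3])
    return data, spacing


def read_volume(path: str | Path) -> CTVolume:
    """Read a 3-D HU volume from NIfTI; spacing from header zooms."""
    data, spacing = _load_nifti(path)
    return CTVolume(data, spacing)


def read_mask(path: str | Path) -> LungMask:
    """Read a binary mask from NIfTI; float masks are binarized at 0.5."""
    data, spacing = _load_nifti(path)
    return LungMask(data > 0.5, spacing)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([*spacing, 1.0])


def write_volume(volume: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.hu.astype(np.float64), _affine(volume.spacing))
    nib.save(img, str(path))


def write_mask(mask: LungMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.spacing))
    nib.save(img, str(path))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Required columns: patient_id, evlwi_ct, evlwi_tptd, ecbf, height_m, sex.
    Duplicate patient_id and non-numeric measurements are rejected with the
    offending id / line number.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True, dtype=str)
    except Exception as exc:
        raise FormatError(f"{path}: unparseable CSV ({exc})") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    dupes = df["patient_id"][df["patient_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(
            f"{path}: duplicated patient_id {dupes}; one row per patient is required"
        )
    numeric = ["evlwi_ct", "evlwi_tptd", "ecbf", "height_m"] + [
        c for c in _OPTIONAL_COLUMNS if c in df.columns
    ]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based counting
            raise ValidationError(
                f"{path}: non-numeric {col} value {df.loc[bad[0], col]!r} on data line {bad[0] + 2}"
            )
        df[col] = coerced
    if (df["ecbf"].dropna() < 0).any():
        raise ValidationError(f"{path}: ecbf must be >= 0 l/min")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValidationError(
            f"{path}: sex must be 'male' or 'female', got {df.loc[bad_sex, 'sex'].iloc[0]!r}"
        )
    return df


_COHORT_HEADER = (
    "# cohort table: evlwi_ct / evlwi_tptd in ml/kg, ecbf in l/min, height_m in m\n"
)


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_COHORT_HEADER)
        table.to_csv(fh, index=False, lineterminator="\n")


def quant_result_to_csv(result: LungQuantResult, scan_id: str = "scan") -> str:
    """One-row CSV for a quantification result, units in a comment header."""
    buf = _io.StringIO()
    buf.write(
        "# lung_volume ml, mean_hu HU, lung_weight g, expected_lung_weight g, "
        "ibw kg, evlwi_ct ml/kg; "
        f"window [{result.window.lower}, {result.window.upper}] HU; "
        f"ibw_rule {result.ibw_rule}; window_only {result.window_only}\n"
    )
    row = pd.DataFrame(
        [
            {
                "scan_id": scan_id,
                "included_voxel_count": result.included_voxel_count,
                "lung_volume": result.lung_volume,
                "mean_hu": result.mean_hu,
                "lung_weight": result.lung_weight,
                "expected_lung_weight": result.expected_lung_weight,
                "ibw": result.ibw,
                "evlwi_ct": result.evlwi_ct,
            }
        ]
    )
    row.to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue()
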
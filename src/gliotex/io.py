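"""Standard-format I/O: NIfTI and 16-bit PNG images, CSV tables, JSON configs.

Conventions: 0-based pixel indexing, row-major, origin top-left. ADC maps
are stored in mm^2/s and are never silently rescaled — NIfTI carries the
units in the header description, PNG (an integer format) stores
``round(ADC * 1e6)`` in 1e-6 mm^2/s, recorded in a sidecar-free fixed
convention. Masks are 0/255 PNG or 0/1 NIfTI.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CohortConfig

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_adc_png",
    "read_adc_png",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "load_cohort_config",
]

ADC_PNG_SCALE = 1e6  # PNG stores ADC in 1e-6 mm^2/s (micro-units)


def write_image(path: str | Path, array: np.ndarray, units: str = "") -> None:
    """Write a 2D float array as NIfTI (.nii/.nii.gz) or 16-bit PNG."""
    path = Path(path)
    if path.suffix == ".png":
        arr = np.asarray(array)
        if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
            raise ValueError("PNG output requires values in [0, 65535]; use NIfTI")
        iio.imwrite(path, np.round(arr).astype(np.uint16))
    else:
        img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine=np.eye(4))
        if units:
            img.header["descrip"] = f"units={units}".encode()
        nib.save(img, str(path))


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".png":
        return np.asarray(iio.imread(path), dtype=float)
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def write_adc_png(path: str | Path, adc_values: np.ndarray) -> None:
    """ADC map to 16-bit PNG at the fixed 1e-6 mm^2/s integer scale."""
    write_image(path, np.asarray(adc_values) * ADC_PNG_SCALE)


def read_adc_png(path: str | Path) -> np.ndarray:
    return read_image(path) / ADC_PNG_SCALE


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    m = np.asarray(mask, dtype=bool)
    if path.suffix == ".png":
        iio.imwrite(path, (m * np.uint16(65535)).astype(np.uint16))
    else:
        nib.save(nib.Nifti1Image(m.astype(np.uint8), affine=np.eye(4)), str(path))


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    # %.17g keeps float64 round-trips exact
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # surface the file name in the error
        raise ValueError(f"malformed CSV table {path}: {exc}") from exc


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON file {path}: {exc}") from exc


def load_cohort_config(path: str | Path) -> CohortConfig:
    return CohortConfig.from_dict(read_json(path))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
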
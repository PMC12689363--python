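"""On-disk contracts: 4D DW volumes, b-value tables, ROI masks, parameter
maps and long-format biomarker CSVs.

Canonical image format is NIfTI-1; Analyze 7.5 (.hdr/.img) is accepted
read-only as a dialect.  b-value tables follow the FSL convention:
whitespace-separated numbers on one line, one entry per 4th-dimension
volume, units s/mm².  Biomarker tables are UTF-8 CSVs with the header
``subject_id,group,session,roi_name,biomarker_name,value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionScheme",
    "DwiVolume",
    "RoiMask",
    "BiomarkerTable",
    "PAPER_BVALUES",
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "write_maps",
    "read_map",
    "read_bvals",
    "write_bvals",
    "read_biomarker_table",
    "write_biomarker_table",
    "BIOMARKER_COLUMNS",
]

#: the 10-b acquisition scheme used throughout the tests and phantoms, s/mm²
PAPER_BVALUES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 300.0, 500.0, 800.0)

BIOMARKER_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "roi_name",
    "biomarker_name",
    "value",
]


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered diffusion weightings (b-values, s/mm²) of an acquisition.

    ``n_averages`` records the scanner-side number of signal averages and is
    metadata only — the stored signal is assumed already averaged.
    """

    bvalues: tuple
    n_averages: int = 1

    def __post_init__(self):
        b = tuple(float(x) for x in self.bvalues)
        object.__setattr__(self, "bvalues", b)
        if any(x < 0 for x in b):
            raise ValueError("b-values must be non-negative")
        if len(set(b)) < 4:
            raise ValueError(
                f"at least 4 distinct b-values required, got {len(set(b))}"
            )
        if list(b) != sorted(b):
            raise ValueError("b-values must be sorted ascending")
        if len(set(b)) != len(b):
            raise ValueError("duplicate b-values are not permitted in a scheme")
        if self.n_averages < 1:
            raise ValueError("n_averages must be a positive integer")

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.bvalues, dtype=float)

    def __len__(self) -> int:
        return len(self.bvalues)


@dataclass
class DwiVolume:
    """A 4D diffusion-weighted stack: one 3D volume per b-value.

    ``signal`` is indexed (x, y, z, b-index) with the b-axis ordered to
    match ``scheme.bvalues`` (ascending).
    """

    signal: np.ndarray
    scheme: AcquisitionScheme
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, b)")
        if self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"4th dimension ({self.signal.shape[3]}) does not match "
                f"scheme length ({len(self.scheme)})"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple:
        return self.signal.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class RoiMask:
    """Integer label volume on the DWI grid; 0 is background."""

    labels: np.ndarray
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integer-valued")
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3D")

    def indices(self, label: int) -> np.ndarray:
        return self.labels == label

    def present_labels(self):
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)


class BiomarkerTable:
    """Long-format per-ROI biomarker records.

    One row per (subject_id, group, session, roi_name, biomarker_name,
    value); the key (subject, session, roi, biomarker) must be unique.
    Backed by a pandas DataFrame, exposed as ``.df``.
    """

    KEY = ["subject_id", "session", "roi_name", "biomarker_name"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in BIOMARKER_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"biomarker table missing columns: {missing}")
        df = df[BIOMARKER_COLUMNS].copy()
        df["value"] = df["value"].astype(float)
        dup = df.duplicated(subset=self.KEY)
        if dup.any():
            rows = df.loc[dup, self.KEY].to_dict("records")
            raise ValueError(f"duplicate biomarker records: {rows[:5]}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "BiomarkerTable":
        return cls(pd.DataFrame(list(records), columns=BIOMARKER_COLUMNS))


# ---------------------------------------------------------------------------
# b-value tables


def read_bvals(path) -> np.ndarray:
    """Parse an FSL-style b-value file (whitespace-separated, s/mm²)."""
    text = Path(path).read_text()
    vals = np.array([float(tok) for tok in text.split()], dtype=float)
    if np.any(vals < 0):
        raise ValueError(f"negative b-value in {path}")
    return vals


def write_bvals(bvalues, path) -> None:
    Path(path).write_text(" ".join(f"{float(b):g}" for b in bvalues) + "\n")


# ---------------------------------------------------------------------------
# DWI volumes


def read_dwi(volume_path, bval_path) -> DwiVolume:
    """Load a 4D NIfTI-1/Analyze volume plus its b-value table.

    The b-axis is permuted to ascending b; volumes sharing b = 0 are
    arithmetically averaged into a single sample.  Spatial axes are never
    reordered.
    """
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got {data.ndim}D")
    bvals = read_bvals(bval_path)
    if len(bvals) != data.shape[3]:
        raise ValueError(
            f"b-value count ({len(bvals)}) does not match 4th dimension "
            f"({data.shape[3]})"
        )
    order = np.argsort(bvals, kind="stable")
    bvals = bvals[order]
    data = data[..., order]
    # average replicate b=0 volumes into one sample
    zero = bvals == 0
    if zero.sum() > 1:
        avg = data[..., zero].mean(axis=3, keepdims=True)
        data = np.concatenate([avg, data[..., ~zero]], axis=3)
        bvals = np.concatenate([[0.0], bvals[~zero]])
    scheme = AcquisitionScheme(tuple(bvals))
    zooms = img.header.get_zooms()[:3]
    return DwiVolume(
        signal=data,
        scheme=scheme,
        voxel_size=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=float),
    )


def write_dwi(vol: DwiVolume, volume_path, bval_path=None) -> None:
    """Write a DwiVolume as NIfTI-1 (float64) plus an FSL bval file."""
    img = nib.Nifti1Image(vol.signal, vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (1.0,))
    nib.save(img, str(volume_path))
    if bval_path is not None:
        write_bvals(vol.scheme.bvalues, bval_path)


# ---------------------------------------------------------------------------
# masks


def read_mask(path, reference: DwiVolume) -> RoiMask:
    """Load an integer label mask and validate it against the DWI grid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"mask {path} contains non-integer values")
    data = np.round(data).astype(np.int32)
    if data.shape != reference.grid_shape:
        raise ValueError(
            f"mask grid {data.shape} does not match DWI grid "
            f"{reference.grid_shape}"
        )
    return RoiMask(labels=data)


def write_mask(mask: RoiMask, reference: DwiVolume, path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), reference.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# parameter maps


def write_maps(maps: Mapping[str, np.ndarray], reference: DwiVolume, out_dir) -> dict:
    """Write named 3D parameter maps as NIfTI files carrying the reference
    affine.

    Maps named ``preference`` (or ``validity``) are written as int16 codes;
    everything else as float32.  Returns a manifest mapping name ->
    {path, dtype, has_nan}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, arr in maps.items():
        arr = np.asarray(arr)
        if arr.shape != reference.grid_shape:
            raise ValueError(
                f"map '{name}' shape {arr.shape} does not match reference "
                f"grid {reference.grid_shape}"
            )
        if name in ("preference", "validity"):
            data = arr.astype(np.int16)
        else:
            data = arr.astype(np.float32)
        path = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(data, reference.affine), str(path))
        manifest[name] = {
            "path": str(path),
            "dtype": str(data.dtype),
            "has_nan": bool(np.isnan(arr).any()) if arr.dtype.kind == "f" else False,
        }
    return manifest


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


# ---------------------------------------------------------------------------
# biomarker tables


def read_biomarker_table(path) -> BiomarkerTable:
    df = pd.read_csv(path, dtype={"subject_id": str, "session": str})
    if len(df) == 0:
        df = pd.DataFrame(columns=BIOMARKER_COLUMNS)
    return BiomarkerTable(df)


def write_biomarker_table(table: BiomarkerTable, path) -> None:
    table.df.to_csv(path, index=False)
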
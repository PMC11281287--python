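"""On-disk formats: HDF5 cube/sample containers and the CSV sample manifest.

HDF5 layout (one file per plant image or tile)::

    /cube            float32, (C, H, W)
    /wavelengths_nm  float64, (C,)
    /mask            uint8,   (H, W)   -- optional
    attrs: sensor_boundary, imaging, identifier, treatment, variety

The manifest is a UTF-8 CSV with the exact header
``sample_id,imaging,identifier,treatment,variety,path``.
"""

from __future__ import annotations

import os
import re

import h5py
import numpy as np
import pandas as pd

from .containers import MANIFEST_COLUMNS, TREATMENTS, HyperCube

REQUIRED_ATTRS = ("sensor_boundary", "imaging", "identifier", "treatment", "variety")


class ManifestError(ValueError):
    """Raised when manifest rows fail validation; carries the offending rows."""

    def __init__(self, message: str, bad_rows: pd.DataFrame | None = None):
        super().__init__(message)
        self.bad_rows = bad_rows


def write_cube(cube: HyperCube, meta: dict, path: str | os.PathLike,
               mask: np.ndarray | None = None) -> None:
    """Write a cube plus metadata to HDF5; the write is refused if ``meta`` is
    missing any of the required attributes."""
    missing = [k for k in REQUIRED_ATTRS if k != "sensor_boundary" and k not in meta]
    if missing:
        raise KeyError(f"missing required metadata attribute(s): {', '.join(missing)}")
    if meta["treatment"] not in TREATMENTS:
        raise ValueError(f"treatment must be one of {TREATMENTS}, got {meta['treatment']!r}")
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.values.astype(np.float32))
        f.create_dataset("wavelengths_nm", data=cube.wavelengths_nm.astype(np.float64))
        if mask is not None:
            mask = np.asarray(mask)
            if mask.shape != cube.spatial_shape:
                raise ValueError(
                    f"mask shape {mask.shape} does not match cube {cube.spatial_shape}")
            f.create_dataset("mask", data=mask.astype(np.uint8))
        f.attrs["sensor_boundary"] = int(cube.sensor_boundary)
        f.attrs["imaging"] = int(meta["imaging"])
        f.attrs["identifier"] = str(meta["identifier"])
        f.attrs["treatment"] = str(meta["treatment"])
        f.attrs["variety"] = str(meta["variety"])


def read_cube(path: str | os.PathLike) -> tuple[HyperCube, dict]:
    """Read a cube written by :func:`write_cube`; round-trip is bit-exact.

    Returns ``(cube, meta)`` where ``meta`` contains imaging/identifier/
    treatment/variety and, if stored, the boolean ``mask``.
    """
    with h5py.File(path, "r") as f:
        missing = [k for k in REQUIRED_ATTRS if k not in f.attrs]
        if missing:
            raise KeyError(f"file lacks required attribute(s): {', '.join(missing)}")
        cube = HyperCube(
            values=f["cube"][()],
            wavelengths_nm=f["wavelengths_nm"][()],
            sensor_boundary=int(f.attrs["sensor_boundary"]),
        )
        meta = {
            "imaging": int(f.attrs["imaging"]),
            "identifier": str(f.attrs["identifier"]),
            "treatment": str(f.attrs["treatment"]),
            "variety": str(f.attrs["variety"]),
        }
        if "mask" in f:
            meta["mask"] = f["mask"][()].astype(bool)
    return cube, meta


def empty_manifest() -> pd.DataFrame:
    return pd.DataFrame(columns=MANIFEST_COLUMNS)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate column set, sample_id uniqueness and treatment tokens."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
    manifest = manifest[MANIFEST_COLUMNS]
    bad = manifest[~manifest["treatment"].isin(TREATMENTS)]
    if len(bad):
        raise ManifestError(
            f"{len(bad)} row(s) with unknown treatment token "
            f"{sorted(bad['treatment'].unique())}", bad_rows=bad)
    if manifest["sample_id"].duplicated().any():
        dup = manifest[manifest["sample_id"].duplicated(keep=False)]
        raise ManifestError(f"duplicate sample_id(s): {sorted(dup['sample_id'].unique())}",
                            bad_rows=dup)
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_manifest(manifest).to_csv(path, index=False, encoding="utf-8")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "identifier": str,
                                  "treatment": str, "variety": str, "path": str},
                     keep_default_na=False)
    if len(df):
        df["imaging"] = df["imaging"].astype(int)
    return validate_manifest(df)


_ENVI_WL_RE = re.compile(r"wavelength\s*=\s*\{(.*?)\}", re.IGNORECASE | re.DOTALL)
_ENVI_BANDS_RE = re.compile(r"^\s*bands\s*=\s*(\d+)", re.IGNORECASE | re.MULTILINE)


def read_envi_header(path: str | os.PathLike) -> dict:
    """Convenience parser for an ENVI ``.hdr``: band count and wavelengths.

    Only the fields needed to build a wavelength axis are extracted; this is a
    plumbing helper for importing real acquisitions, not a full ENVI reader.
    """
    with open(path, "r", encoding="utf-8", errors="replace") as f:
        text = f.read()
    out: dict = {}
    m = _ENVI_BANDS_RE.search(text)
    if m:
        out["bands"] = int(m.group(1))
    m = _ENVI_WL_RE.search(text)
    if m:
        out["wavelengths_nm"] = np.array(
            [float(tok) for tok in m.group(1).replace("\n", " ").split(",") if tok.strip()]
        )
    if "bands" in out and "wavelengths_nm" in out and \
            out["bands"] != len(out["wavelengths_nm"]):
        raise ValueError(
            f"ENVI header inconsistent: bands={out['bands']} but "
            f"{len(out['wavelengths_nm'])} wavelengths")
    return out
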
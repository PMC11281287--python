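"""Core in-memory containers for dual-sensor hyperspectral data.

A :class:`HyperCube` holds a co-registered reflectance (or radiance) image as a
rank-3 array in ``(channel, row, col)`` order together with its wavelength axis.
The spectral axis is the concatenation of a VNIR block and a SWIR block; because
the two sensors overlap around 950–990 nm, wavelengths are required to be
strictly increasing only *within* each block, never across the sensor boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed column order of the sample manifest CSV.
MANIFEST_COLUMNS = ["sample_id", "imaging", "identifier", "treatment", "variety", "path"]

#: Admissible irrigation-regime codes: C = well-watered control, D = water-deficient.
TREATMENTS = ("C", "D")


@dataclass
class HyperCube:
    """A C×H×W hyperspectral image with its wavelength axis.

    Parameters
    ----------
    values
        Rank-3 array ``(C, H, W)``; reflectance (unitless) or radiance.
    wavelengths_nm
        Length-C vector of band-center wavelengths in nanometres.
    sensor_boundary
        Index of the first SWIR channel; channels ``[0, sensor_boundary)`` form
        the VNIR block and ``[sensor_boundary, C)`` the SWIR block.
    """

    values: np.ndarray
    wavelengths_nm: np.ndarray
    sensor_boundary: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be rank-3 (C,H,W), got shape {self.values.shape}")
        c = self.values.shape[0]
        if self.wavelengths_nm.shape != (c,):
            raise ValueError(
                f"wavelengths length {self.wavelengths_nm.shape} does not match "
                f"channel count {c}"
            )
        if not 0 <= self.sensor_boundary <= c:
            raise ValueError(f"sensor_boundary {self.sensor_boundary} outside [0, {c}]")
        for lo, hi, name in (
            (0, self.sensor_boundary, "VNIR"),
            (self.sensor_boundary, c, "SWIR"),
        ):
            block = self.wavelengths_nm[lo:hi]
            if block.size > 1 and not np.all(np.diff(block) > 0):
                raise ValueError(f"wavelengths not strictly increasing within {name} block")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")
        if not np.all(np.isfinite(self.wavelengths_nm)):
            raise ValueError("wavelengths must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


@dataclass
class PlantImage:
    """A whole-plant cube plus its segmentation mask and acquisition metadata."""

    cube: HyperCube
    mask: np.ndarray  # (H, W) bool, True on plant pixels
    imaging: int
    identifier: str
    treatment: str
    variety: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.cube.spatial_shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match cube spatial shape "
                f"{self.cube.spatial_shape}"
            )
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if not self.mask.any():
            raise ValueError("plant mask has no true pixels")


@dataclass
class Sample:
    """A model-ready tile cut from a plant image.

    ``data`` is ``(C, h, w)`` with background pixels already zeroed; ``label``
    is the binary training target (1 = water-deficient).
    """

    data: np.ndarray
    sample_id: str
    imaging: int
    identifier: str
    treatment: str
    variety: str
    wavelengths_nm: np.ndarray | None = None
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")

    @property
    def label(self) -> int:
        return 1 if self.treatment == "D" else 0
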
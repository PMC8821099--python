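"""In-memory containers for diffusion volumes and tensor fields.

Axis convention (fixed throughout the package, recorded in every volume):
``x`` = left-right (the perivascular / medullary-vein direction),
``y`` = anterior-posterior (association-fiber direction),
``z`` = inferior-superior (projection-fiber direction).
All diffusivities are stored in mm^2/s; user-facing profiles and reports
use units of 1e-3 mm^2/s, the usual DTI convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .protocol import AcquisitionProtocol

AXIS_CONVENTION = "x=left-right(perivascular) y=anterior-posterior z=inferior-superior"

#: order of the six unique tensor elements in TensorField.elements
#: (lower-triangular, row-major)
TENSOR_ELEMENT_ORDER = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")


@dataclass
class DWIVolume:
    """A 4-D diffusion-weighted signal array plus its acquisition protocol.

    ``signal`` has shape (nx, ny, nz, m) where m == len(protocol).
    """

    signal: np.ndarray
    protocol: AcquisitionProtocol
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.25)
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise InputError(f"DWI signal must be 4-D, got shape {self.signal.shape}")
        if self.signal.shape[3] != len(self.protocol):
            raise InputError(
                f"signal has {self.signal.shape[3]} measurements but protocol "
                f"lists {len(self.protocol)}"
            )
        if np.any(self.signal < 0):
            raise InputError("DWI signals must be nonnegative")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors with a validity mask.

    ``tensors`` has shape (nx, ny, nz, 3, 3) in mm^2/s, ``ln_s0`` the
    estimated (or ground-truth) log baseline signal, ``valid`` a boolean
    mask; a voxel is invalid when its fit failed, an eigenvalue is
    nonpositive, or its signals were degenerate.
    """

    tensors: np.ndarray
    ln_s0: np.ndarray
    valid: np.ndarray
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise InputError(
                f"tensor array must have shape (nx,ny,nz,3,3), got {self.tensors.shape}"
            )
        self.ln_s0 = np.asarray(self.ln_s0, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        shape = self.tensors.shape[:3]
        if self.ln_s0.shape != shape or self.valid.shape != shape:
            raise InputError("ln_s0 and valid must match the tensor grid shape")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def elements(self) -> np.ndarray:
        """Unique tensor elements as (nx, ny, nz, 6) in lower-triangular
        order Dxx, Dxy, Dyy, Dxz, Dyz, Dzz (see TENSOR_ELEMENT_ORDER)."""
        t = self.tensors
        return np.stack(
            [t[..., 0, 0], t[..., 0, 1], t[..., 1, 1],
             t[..., 0, 2], t[..., 1, 2], t[..., 2, 2]],
            axis=-1,
        )
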
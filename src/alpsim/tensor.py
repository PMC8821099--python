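"""Diffusion-tensor estimation by log-linear least squares.

The single-tensor model relates the measured signal to the baseline via
``S_i = S0 * exp(-b_i g_i^T D g_i)``; taking logs makes the model linear
in (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), so ordinary least squares on
log-signals inverts a noise-free acquisition exactly. Weighted least
squares (weights S_i^2, the first-order noise propagation of the log
transform) is available behind a flag for noisy data.
"""

from __future__ import annotations

import numpy as np

from .containers import DWIVolume, TensorField
from .errors import InputError, ParameterError
from .protocol import AcquisitionProtocol

#: fraction of S0 below which a signal is clamped before the log transform
CLAMP_FRACTION = 1e-6
#: voxels with more than this fraction of clamped measurements are flagged
MAX_CLAMPED_FRACTION = 0.20


def design_matrix(protocol: AcquisitionProtocol) -> np.ndarray:
    """Design matrix mapping (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to
    log-signals: row i is
    (1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz).

    Raises
    ------
    ParameterError
        If the rows have rank < 7 (the tensor fit would be
        under-determined, e.g. fewer than six non-collinear directions).
    """
    b = protocol.bvals
    g = protocol.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    x = np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )
    if np.linalg.matrix_rank(x) < 7:
        raise ParameterError(
            "protocol is under-determined for a tensor fit: need at least "
            "6 non-collinear weighted directions plus a b=0 measurement"
        )
    return x


def fit_tensor(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    weighted: bool = False,
) -> TensorField:
    """Estimate a diffusion tensor in every (masked) voxel.

    Signals at or below ``CLAMP_FRACTION * S0_ref`` are clamped before the
    log; a voxel is flagged invalid (never raised) if more than 20% of its
    measurements were clamped, any signal is non-finite, the voxel is all
    zero, or a fitted eigenvalue is nonpositive. Negative eigenvalues are
    not clipped -- the voxel is simply excluded from downstream selection.

    Parameters
    ----------
    dwi : the volume to fit.
    mask : optional boolean (nx, ny, nz) array; unmasked voxels get a zero
        tensor and ``valid=False``.
    weighted : if True, one WLS refinement pass with weights equal to the
        squared model signal predicted by the OLS pass.
    """
    x = design_matrix(dwi.protocol)
    nx, ny, nz, m = dwi.signal.shape
    flat = dwi.signal.reshape(-1, m)
    nvox = flat.shape[0]

    if mask is None:
        mask_flat = np.ones(nvox, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (nx, ny, nz):
            raise InputError("mask shape must match the DWI grid")
        mask_flat = mask.reshape(-1)

    # reference amplitude for the clamp: mean b=0 signal per voxel,
    # falling back to the protocol S0 for pathological voxels
    b0 = dwi.protocol.bvals == 0
    s0_ref = flat[:, b0].mean(axis=1)
    s0_ref = np.where(s0_ref > 0, s0_ref, dwi.protocol.s0)
    eps = CLAMP_FRACTION * s0_ref

    finite = np.isfinite(flat).all(axis=1)
    nonzero = flat.max(axis=1, initial=0.0) > 0
    clamped = flat <= eps[:, None]
    usable = mask_flat & finite & nonzero

    sig = np.maximum(flat, eps[:, None])
    logs = np.where(usable[:, None], np.log(sig, where=sig > 0, out=np.zeros_like(sig)), 0.0)

    pinv = np.linalg.pinv(x)
    beta = logs @ pinv.T  # (nvox, 7)

    if weighted:
        for i in np.flatnonzero(usable):
            w = np.exp(x @ beta[i]) ** 2
            xw = x * w[:, None]
            beta[i] = np.linalg.lstsq(x.T @ xw, xw.T @ logs[i], rcond=None)[0]

    ln_s0 = beta[:, 0]
    d = np.zeros((nvox, 3, 3))
    d[:, 0, 0] = beta[:, 1]
    d[:, 1, 1] = beta[:, 2]
    d[:, 2, 2] = beta[:, 3]
    d[:, 0, 1] = d[:, 1, 0] = beta[:, 4]
    d[:, 0, 2] = d[:, 2, 0] = beta[:, 5]
    d[:, 1, 2] = d[:, 2, 1] = beta[:, 6]

    evals = np.linalg.eigvalsh(d)
    spd = evals.min(axis=1) > 0
    too_clamped = clamped.mean(axis=1) > MAX_CLAMPED_FRACTION
    valid = usable & spd & ~too_clamped & np.isfinite(beta).all(axis=1)

    d[~usable] = 0.0
    ln_s0[~usable] = 0.0
    return TensorField(
        tensors=d.reshape(nx, ny, nz, 3, 3),
        ln_s0=ln_s0.reshape(nx, ny, nz),
        valid=valid.reshape(nx, ny, nz),
        axis_convention=dwi.axis_convention,
    )


def eig_sorted(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and matching orthonormal eigenvectors.

    Returns ``(evals, evecs)`` with ``evecs[:, i]`` the eigenvector of
    ``evals[i]``; the principal eigenvector ``evecs[:, 0]`` is the fiber
    orientation of the single-tensor model.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3) or not np.isfinite(tensor).all():
        raise InputError("tensor must be a finite 3x3 matrix")
    evals, evecs = np.linalg.eigh(tensor)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def axis_diffusivities(tensor: np.ndarray) -> tuple[float, float, float]:
    """Scanner-frame diagonal (Dxx, Dyy, Dzz) of a tensor.

    These are the axis diffusivities the ALPS construction reads out --
    diagonal elements in the fixed scanner frame, not eigenvalues.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3) or not np.isfinite(tensor).all():
        raise InputError("tensor must be a finite 3x3 matrix")
    return float(tensor[0, 0]), float(tensor[1, 1]), float(tensor[2, 2])
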
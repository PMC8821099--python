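"""Diffusion acquisition protocols: b-values and gradient directions.

The default protocol mirrors a single-shell clinical DTI acquisition:
32 unique diffusion directions at b = 1000 s/mm^2 plus one unweighted
(b = 0) baseline measurement. The direction set is an
electrostatic-repulsion point set shipped with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ParameterError

DEFAULT_BVALUE = 1000.0  # s/mm^2


def _load_default_directions() -> np.ndarray:
    ref = resources.files("alpsim.data").joinpath("gradients32.txt")
    with resources.as_file(ref) as path:
        dirs = np.loadtxt(path)
    return dirs


@dataclass(frozen=True)
class AcquisitionProtocol:
    """A list of (b-value, unit gradient direction) measurements.

    Parameters
    ----------
    bvals : (m,) array of b-values in s/mm^2, at least one of them zero.
    bvecs : (m, 3) array of gradient directions; unit norm where b > 0
        (the direction of a b = 0 measurement is irrelevant and stored
        as the zero vector).
    s0 : baseline (unweighted) signal amplitude, arbitrary units.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    s0: float = 1000.0

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ParameterError(
                f"bvals/bvecs shape mismatch: {bvals.shape} vs {bvecs.shape}"
            )
        if np.any(bvals < 0):
            raise ParameterError("b-values must be nonnegative")
        if not np.any(bvals == 0):
            raise ParameterError("protocol needs at least one b=0 measurement")
        weighted = bvals > 0
        norms = np.linalg.norm(bvecs[weighted], axis=1)
        if weighted.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ParameterError("gradient directions must be unit norm where b > 0")
        if self.s0 <= 0:
            raise ParameterError("baseline signal s0 must be positive")

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n_weighted(self) -> int:
        return int(np.sum(self.bvals > 0))


def default_protocol(bvalue: float = DEFAULT_BVALUE, s0: float = 1000.0) -> AcquisitionProtocol:
    """32 directions at the given b-value plus a leading b=0 measurement."""
    dirs = _load_default_directions()
    bvals = np.concatenate([[0.0], np.full(len(dirs), bvalue)])
    bvecs = np.vstack([np.zeros(3), dirs])
    return AcquisitionProtocol(bvals=bvals, bvecs=bvecs, s0=s0)
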
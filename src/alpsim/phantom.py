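"""Three-fiber periventricular phantoms and synthetic DWI.

The phantom emulates the tissue configuration the ALPS index exploits at
the level of the lateral-ventricle body: projection fibers running
inferior-superior (z), association fibers anterior-posterior (y) and
subcortical fibers left-right (x), embedded in isotropic background.
The perivascular (medullary-vein) direction is x, so the ground-truth
ALPS index of a phantom is

    mean(lambda_pv^proj, lambda_pv^assoc) / mean(lambda_rd^proj, lambda_rd^assoc)

exactly. Default diffusivity profiles are calibrated so this analytic
index equals 1.460 for the ESRD profile and 1.632 for the healthy-control
profile, the group means the downstream pipeline is expected to recover.

Synthetic signals follow the Stejskal-Tanner single-tensor forward model
S = S0 exp(-b g^T D g) with optional Rician noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import AXIS_CONVENTION, DWIVolume, TensorField
from .errors import GeometryError, ParameterError
from .protocol import AcquisitionProtocol

FIBERS = ("projection", "association", "subcortical")

#: expected principal axis of each fiber population (0=x, 1=y, 2=z)
FIBER_AXES = {"projection": 2, "association": 1, "subcortical": 0}


@dataclass(frozen=True)
class FiberDiffusivities:
    """Principal diffusivities of one fiber population, 1e-3 mm^2/s.

    ``axial`` along the fiber, ``perivascular`` across the fiber along the
    perivascular (x) direction, ``radial`` across the fiber along the
    remaining direction. For the subcortical fibers the fiber axis itself
    is x, so ``perivascular`` there is just the larger of the two radial
    diffusivities (captured for QC only).
    """

    axial: float
    perivascular: float
    radial: float

    def __post_init__(self) -> None:
        if min(self.axial, self.perivascular, self.radial) <= 0:
            raise ParameterError("diffusivities must be positive")
        if not (self.axial >= self.perivascular >= self.radial):
            raise ParameterError(
                "expected axial >= perivascular >= radial diffusivity, got "
                f"({self.axial}, {self.perivascular}, {self.radial})"
            )


@dataclass(frozen=True)
class DiffusivityProfile:
    """Ground-truth diffusivities of the three fiber populations plus
    isotropic background, in 1e-3 mm^2/s.

    ``sigma_subject`` is the between-subject SD applied to the
    perivascular diffusivity when cohorts are simulated; it is a free
    parameter of the generator (group-level ALPS dispersion is not a
    published quantity), defaulted so a two-arm comparison at realistic
    sample sizes is well powered.
    """

    projection: FiberDiffusivities
    association: FiberDiffusivities
    subcortical: FiberDiffusivities
    background: float = 0.8
    sigma_subject: float = 0.04

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ParameterError("background diffusivity must be positive")
        if self.sigma_subject < 0:
            raise ParameterError("sigma_subject must be nonnegative")

    def fiber(self, name: str) -> FiberDiffusivities:
        return getattr(self, name)

    def analytic_alps(self) -> float:
        """Noise-free ALPS index implied by the profile (calibration
        identity: perivascular over radial diffusivity, averaged over the
        projection and association fibers)."""
        num = 0.5 * (self.projection.perivascular + self.association.perivascular)
        den = 0.5 * (self.projection.radial + self.association.radial)
        return num / den

    def with_perivascular(self, value: float) -> "DiffusivityProfile":
        """Copy of the profile with the perivascular diffusivity of every
        fiber replaced (used for per-subject jitter); the value is clipped
        into the open (radial, axial) interval of each fiber so the
        anisotropy ordering is preserved."""
        fibers = {}
        for name in FIBERS:
            f = self.fiber(name)
            v = float(np.clip(value, f.radial + 1e-6, f.axial - 1e-6))
            fibers[name] = replace(f, perivascular=v)
        return DiffusivityProfile(
            projection=fibers["projection"],
            association=fibers["association"],
            subcortical=fibers["subcortical"],
            background=self.background,
            sigma_subject=self.sigma_subject,
        )


def esrd_profile() -> DiffusivityProfile:
    """Default end-stage-renal-disease profile: analytic ALPS = 1.460."""
    return DiffusivityProfile(
        projection=FiberDiffusivities(axial=1.40, perivascular=0.730, radial=0.50),
        association=FiberDiffusivities(axial=1.40, perivascular=0.730, radial=0.50),
        subcortical=FiberDiffusivities(axial=1.40, perivascular=0.730, radial=0.50),
    )


def control_profile() -> DiffusivityProfile:
    """Default healthy-control profile: analytic ALPS = 1.632."""
    return DiffusivityProfile(
        projection=FiberDiffusivities(axial=1.40, perivascular=0.816, radial=0.50),
        association=FiberDiffusivities(axial=1.40, perivascular=0.816, radial=0.50),
        subcortical=FiberDiffusivities(axial=1.40, perivascular=0.816, radial=0.50),
    )


def isotropic_profile(diffusivity: float = 0.8) -> DiffusivityProfile:
    """All fibers and background share one isotropic diffusivity
    (analytic ALPS = 1 by construction)."""
    f = FiberDiffusivities(axial=diffusivity, perivascular=diffusivity, radial=diffusivity)
    return DiffusivityProfile(
        projection=f, association=f, subcortical=f, background=diffusivity
    )


Bounds = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class PhantomGeometry:
    """Grid shape and rectangular (half-open) voxel-index bounds of the
    three fiber regions; everything else is background.

    The three regions must be disjoint and share at least one x index,
    since the ALPS procedure selects one voxel per fiber on a common
    x-axis.
    """

    shape: tuple[int, int, int] = (12, 12, 6)
    regions: dict[str, Bounds] = field(
        default_factory=lambda: {
            "projection": ((2, 10), (1, 4), (0, 6)),
            "association": ((2, 10), (4, 7), (0, 6)),
            "subcortical": ((2, 10), (7, 10), (0, 6)),
        }
    )

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise GeometryError(f"invalid grid shape {self.shape}")
        if set(self.regions) != set(FIBERS):
            raise GeometryError(f"regions must be exactly {FIBERS}")
        for name, bounds in self.regions.items():
            for axis, (lo, hi) in enumerate(bounds):
                if not (0 <= lo < hi <= self.shape[axis]):
                    raise GeometryError(
                        f"{name} region bounds {bounds} exceed grid {self.shape}"
                    )
        masks = {name: self.region_mask(name) for name in FIBERS}
        for i, a in enumerate(FIBERS):
            for b in FIBERS[i + 1 :]:
                if np.any(masks[a] & masks[b]):
                    raise GeometryError(f"fiber regions {a} and {b} overlap")
        if not self.common_x_indices().size:
            raise GeometryError("fiber regions share no x index")

    def region_mask(self, name: str) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.regions[name]
        mask[x0:x1, y0:y1, z0:z1] = True
        return mask

    def common_x_indices(self) -> np.ndarray:
        xs = [set(range(b[0][0], b[0][1])) for b in self.regions.values()]
        return np.array(sorted(set.intersection(*xs)), dtype=int)


def _fiber_tensor(f: FiberDiffusivities, axis: int) -> np.ndarray:
    """Diagonal tensor (mm^2/s) for a fiber whose principal axis is the
    given scanner axis; the perivascular diffusivity always sits on x
    unless the fiber axis itself is x."""
    if axis == 2:  # projection: x=perivascular, y=radial, z=axial
        diag = (f.perivascular, f.radial, f.axial)
    elif axis == 1:  # association: x=perivascular, y=axial, z=radial
        diag = (f.perivascular, f.axial, f.radial)
    else:  # subcortical: x=axial, y=perivascular, z=radial
        diag = (f.axial, f.perivascular, f.radial)
    return np.diag(diag) * 1e-3


def build_phantom(
    geometry: PhantomGeometry,
    profile: DiffusivityProfile,
    axes: dict[str, int] | None = None,
) -> TensorField:
    """Ground-truth tensor field of the three-fiber phantom.

    Every voxel is symmetric positive definite by construction; the
    validity mask is all True and ln S0 is zero (the baseline amplitude
    is supplied by the acquisition protocol at simulation time).

    ``axes`` overrides the fiber-axis assignment (default
    projection->z, association->y, subcortical->x), used for
    axis-permutation sanity checks.
    """
    axes = dict(FIBER_AXES if axes is None else axes)
    tensors = np.empty(geometry.shape + (3, 3))
    tensors[...] = np.eye(3) * profile.background * 1e-3
    for name in FIBERS:
        tensors[geometry.region_mask(name)] = _fiber_tensor(
            profile.fiber(name), axes[name]
        )
    return TensorField(
        tensors=tensors,
        ln_s0=np.zeros(geometry.shape),
        valid=np.ones(geometry.shape, dtype=bool),
        axis_convention=AXIS_CONVENTION,
    )


def simulate_dwi(
    field: TensorField,
    protocol: AcquisitionProtocol,
    snr: float = np.inf,
    seed: int = 0,
) -> DWIVolume:
    """Forward-simulate a DWI volume from a tensor field.

    The noiseless signal is S0 exp(-b g^T D g). With finite ``snr``,
    Rician noise is applied per measurement:
    S_noisy = sqrt((S + e1)^2 + e2^2) with e1, e2 ~ Normal(0, S0/snr) --
    the magnitude-image noise model of MRI, referenced to the b=0
    amplitude. Identical (field, protocol, snr, seed) give bit-identical
    volumes.
    """
    if not np.isfinite(field.tensors).all():
        raise ParameterError("tensor field contains non-finite values")
    if not snr > 0:
        raise ParameterError(f"snr must be positive (got {snr})")
    b = protocol.bvals
    g = protocol.bvecs
    exponent = -b * np.einsum("mi,...ij,mj->...m", g, field.tensors, g)
    signal = protocol.s0 * np.exp(exponent)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = protocol.s0 / snr
        e1 = rng.normal(0.0, sigma, size=signal.shape)
        e2 = rng.normal(0.0, sigma, size=signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2**2)
    return DWIVolume(
        signal=signal, protocol=protocol, axis_convention=field.axis_convention
    )
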
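"""ALPS voxel selection and index computation.

The ALPS ("analysis along the perivascular space") construction reads the
scanner-frame diagonal diffusivities of one voxel per fiber population --
projection, association and subcortical -- selected on a shared x index
inside rectangular ROIs, and forms the dimensionless ratio

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

i.e. diffusivity along the perivascular (x) axis over diffusivity
perpendicular to both the fiber and the perivascular axis. The
subcortical voxel enters no formula term and is carried for QC only.

"Maximum orientation" is operationalized as the largest absolute dot
product between the voxel's principal eigenvector and the fiber's
expected axis; voxels whose tensor is too close to isotropic for the
principal direction to be meaningful (Westin linearity below
``MIN_LINEARITY``) score zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import TensorField
from .errors import ComputationError, GeometryError, SelectionError
from .phantom import FIBER_AXES, FIBERS, Bounds, PhantomGeometry
from .tensor import fit_tensor

#: (lambda1 - lambda2)/lambda1 below which the principal direction is
#: treated as undefined and the alignment score is zero
MIN_LINEARITY = 0.05

AXIS_NAMES = ("x", "y", "z")


@dataclass(frozen=True)
class FiberROI:
    """Rectangular search regions (half-open voxel-index bounds) for the
    three fiber populations, with each fiber's expected axis and the
    alignment floor below which a measurement is flagged."""

    regions: dict[str, Bounds]
    expected_axes: dict[str, int] = field(default_factory=lambda: dict(FIBER_AXES))
    alignment_floor: float = 0.5

    def __post_init__(self) -> None:
        if set(self.regions) != set(FIBERS):
            raise GeometryError(f"ROI must define regions for {FIBERS}")
        if sorted(self.expected_axes.values()) != [0, 1, 2]:
            raise GeometryError("expected axes must be the three distinct axes")

    @classmethod
    def from_geometry(cls, geometry: PhantomGeometry, **kwargs) -> "FiberROI":
        """ROI coinciding with the phantom's ground-truth fiber regions."""
        return cls(regions=dict(geometry.regions), **kwargs)


@dataclass(frozen=True)
class FiberSample:
    """One selected voxel: its index, scanner-frame diagonal diffusivities
    (Dxx, Dyy, Dzz) in mm^2/s, and its alignment score."""

    voxel: tuple[int, int, int]
    diffusivities: tuple[float, float, float]
    alignment: float

    def along(self, axis: int) -> float:
        return self.diffusivities[axis]


@dataclass(frozen=True)
class ALPSMeasurement:
    """The per-fiber samples entering (and QC-ing) the ALPS formula.

    ``expected_axes`` records the fiber-axis convention the voxels were
    selected under; under the default (projection->z, association->y) the
    denominator terms are exactly Dyy_proj and Dzz_assoc.
    """

    samples: dict[str, FiberSample]
    flagged: bool = False  # True when some alignment fell below the ROI floor
    expected_axes: dict[str, int] = field(default_factory=lambda: dict(FIBER_AXES))

    @property
    def dxx_projection(self) -> float:
        return self.samples["projection"].along(0)

    @property
    def dyy_projection(self) -> float:
        return self.samples["projection"].along(1)

    @property
    def dxx_association(self) -> float:
        return self.samples["association"].along(0)

    @property
    def dzz_association(self) -> float:
        return self.samples["association"].along(2)

    def diffusivity(self, fiber: str, axis: int) -> float:
        """Scanner-frame diffusivity of the selected voxel of ``fiber``
        along coordinate ``axis`` (mm^2/s); covers all nine per-axis
        readouts used in group comparisons."""
        return self.samples[fiber].along(axis)


@dataclass(frozen=True)
class ALPSResult:
    measurement: ALPSMeasurement
    index: float

    @property
    def flagged(self) -> bool:
        return self.measurement.flagged


def _alignment_scores(field_: TensorField, mask: np.ndarray, axis: int) -> np.ndarray:
    """|principal eigenvector . axis| per voxel of ``mask``; zero where the
    voxel is invalid or the tensor has no meaningful principal direction."""
    scores = np.full(field_.grid_shape, -np.inf)
    idx = np.argwhere(mask & field_.valid)
    if idx.size == 0:
        return scores
    tensors = field_.tensors[tuple(idx.T)]
    evals, evecs = np.linalg.eigh(tensors)  # ascending
    lam1, lam2 = evals[:, 2], evals[:, 1]
    linearity = (lam1 - lam2) / np.maximum(lam1, 1e-30)
    align = np.abs(evecs[:, axis, 2])
    align[linearity < MIN_LINEARITY] = 0.0
    scores[tuple(idx.T)] = align
    return scores


def select_fiber_voxels(field_: TensorField, roi: FiberROI) -> ALPSMeasurement:
    """Select one voxel per fiber on a shared x index.

    For every x index present in all three fiber regions, the best-aligned
    valid voxel of each fiber at that x is found; the x maximizing the
    summed alignment over the three fibers wins. Ties between voxels are
    broken toward the lowest linear (C-order) voxel index, ties between x
    indices toward the lowest x. The measurement is flagged when any
    selected alignment falls below ``roi.alignment_floor``.

    Raises
    ------
    GeometryError
        If the three regions share no x index.
    SelectionError
        If no x index has a valid voxel in all three fibers.
    """
    shape = field_.grid_shape
    masks = {}
    x_sets = []
    for name in FIBERS:
        (x0, x1), (y0, y1), (z0, z1) = roi.regions[name]
        if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1] and 0 <= z0 < z1 <= shape[2]):
            raise GeometryError(f"{name} ROI bounds {roi.regions[name]} exceed grid {shape}")
        m = np.zeros(shape, dtype=bool)
        m[x0:x1, y0:y1, z0:z1] = True
        masks[name] = m
        x_sets.append(set(range(x0, x1)))
    common_x = sorted(set.intersection(*x_sets))
    if not common_x:
        raise GeometryError("fiber ROIs share no x index")

    scores = {
        name: _alignment_scores(field_, masks[name], roi.expected_axes[name])
        for name in FIBERS
    }

    best_total, best_x, best_voxels = -np.inf, None, None
    for x in common_x:
        voxels, total, ok = {}, 0.0, True
        for name in FIBERS:
            plane = scores[name][x]  # (ny, nz)
            if not np.isfinite(plane).any():
                ok = False
                break
            # argmax on the flattened C-order plane -> lowest linear index tie-break
            j = int(np.argmax(plane))
            y, z = divmod(j, shape[2])
            voxels[name] = (x, int(y), int(z))
            total += plane[y, z]
        if ok and total > best_total:  # strict: ties keep the lowest x
            best_total, best_x, best_voxels = total, x, voxels
    if best_voxels is None:
        raise SelectionError("no x index has a valid voxel in all three fiber regions")

    samples = {}
    for name in FIBERS:
        v = best_voxels[name]
        t = field_.tensors[v]
        samples[name] = FiberSample(
            voxel=v,
            diffusivities=(float(t[0, 0]), float(t[1, 1]), float(t[2, 2])),
            alignment=float(scores[name][v]),
        )
    flagged = any(s.alignment < roi.alignment_floor for s in samples.values())
    return ALPSMeasurement(
        samples=samples, flagged=flagged, expected_axes=dict(roi.expected_axes)
    )


def compute_alps(measurement: ALPSMeasurement) -> float:
    """ALPS index = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc).

    The numerator is the perivascular-axis (x) diffusivity of the
    projection and association voxels; each denominator term is the
    diffusivity perpendicular to both x and that fiber's axis, which is
    Dyy for the projection and Dzz for the association fiber under the
    default convention. Dimensionless and invariant to a common rescaling
    of the four inputs.
    """
    num_terms, den_terms = [], []
    for fiber in ("projection", "association"):
        axis = measurement.expected_axes[fiber]
        if axis == 0:
            raise ComputationError(
                f"{fiber} fiber assigned to the perivascular (x) axis; "
                "the ALPS construction is undefined"
            )
        num_terms.append(measurement.samples[fiber].along(0))
        den_terms.append(measurement.samples[fiber].along(3 - axis))
    num = 0.5 * sum(num_terms)
    den = 0.5 * sum(den_terms)
    if not all(np.isfinite(num_terms + den_terms)):
        raise ComputationError("non-finite diffusivity in ALPS measurement")
    if den <= 0:
        voxels = {f: s.voxel for f, s in measurement.samples.items()}
        raise ComputationError(
            f"nonpositive ALPS denominator mean(Dyy_proj, Dzz_assoc) = {den:g} "
            f"(selected voxels: {voxels})"
        )
    return num / den


def subject_alps(dwi, roi: FiberROI, mask: np.ndarray | None = None) -> ALPSResult:
    """Full per-subject pipeline: tensor fit, voxel selection, index."""
    field_ = fit_tensor(dwi, mask=mask)
    measurement = select_fiber_voxels(field_, roi)
    return ALPSResult(measurement=measurement, index=compute_alps(measurement))
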
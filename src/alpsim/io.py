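"""File I/O: NIfTI volumes with FSL-dialect gradient tables, ROI JSON,
cohort CSV and pipeline configuration files."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .alps import FiberROI
from .cohort import SubjectRecord
from .containers import DWIVolume, TensorField
from .errors import FormatError
from .protocol import AcquisitionProtocol

#: relative deviation from unit norm tolerated (bvecs renormalized) before
#: a weighted direction is rejected as malformed
BVEC_NORM_TOLERANCE = 0.01


def write_dwi(dwi: DWIVolume, nifti_path, bval_path, bvec_path) -> None:
    """Write a 4-D NIfTI plus FSL-style .bval (one row) and .bvec
    (three rows: x, y, z components per column)."""
    affine = np.diag(list(dwi.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(dwi.signal.astype(np.float64), affine)
    img.header["descrip"] = dwi.axis_convention[:79].encode()
    nib.save(img, str(nifti_path))
    np.savetxt(bval_path, dwi.protocol.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, dwi.protocol.bvecs.T, fmt="%.10f")


def read_dwi(nifti_path, bval_path, bvec_path, s0: float | None = None) -> DWIVolume:
    """Read a 4-D NIfTI with its FSL gradient table.

    The measurement count must agree between image, .bval and .bvec.
    Weighted directions off unit norm by less than 1% are renormalized;
    larger deviations are a format error. If ``s0`` is not given it is
    estimated as the mean b=0 signal.
    """
    try:
        img = nib.load(str(nifti_path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise FormatError(f"cannot read NIfTI {nifti_path}: {exc}") from exc
    if data.ndim != 4:
        raise FormatError(f"{nifti_path}: expected a 4-D volume, got {data.ndim}-D")
    try:
        bvals = np.loadtxt(bval_path, ndmin=1).ravel()
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except Exception as exc:
        raise FormatError(f"cannot parse gradient table: {exc}") from exc
    if bvecs.shape[0] != 3:
        raise FormatError(f"{bvec_path}: expected 3 rows (FSL dialect)")
    bvecs = bvecs.T
    if not (data.shape[3] == bvals.size == bvecs.shape[0]):
        raise FormatError(
            f"measurement count mismatch: image {data.shape[3]}, "
            f"bval {bvals.size}, bvec {bvecs.shape[0]}"
        )
    weighted = bvals > 0
    norms = np.linalg.norm(bvecs[weighted], axis=1)
    if np.any(np.abs(norms - 1.0) > BVEC_NORM_TOLERANCE):
        worst = norms[np.argmax(np.abs(norms - 1.0))]
        raise FormatError(
            f"{bvec_path}: weighted gradient direction with norm {worst:.4g} "
            "deviates from unit by more than 1%"
        )
    bvecs = bvecs.copy()
    bvecs[weighted] /= norms[:, None]
    bvecs[~weighted] = 0.0
    if s0 is None:
        s0 = float(data[..., weighted == False].mean())  # noqa: E712
        if s0 <= 0:
            s0 = 1.0
    voxel = img.header.get_zooms()[:3]
    protocol = AcquisitionProtocol(bvals=bvals, bvecs=bvecs, s0=s0)
    return DWIVolume(signal=data, protocol=protocol, voxel_size_mm=tuple(voxel))


def write_tensor_field(field: TensorField, tensor_path, mask_path) -> None:
    """Tensor field as a 4-D NIfTI with 6 volumes in lower-triangular
    order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz) plus a validity-mask NIfTI."""
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(field.elements(), affine), str(tensor_path))
    nib.save(nib.Nifti1Image(field.valid.astype(np.uint8), affine), str(mask_path))


def write_roi(roi: FiberROI, path) -> None:
    payload = {
        "regions": {k: [list(ax) for ax in v] for k, v in roi.regions.items()},
        "expected_axes": roi.expected_axes,
        "alignment_floor": roi.alignment_floor,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_roi(path) -> FiberROI:
    try:
        payload = json.loads(Path(path).read_text())
        return FiberROI(
            regions={
                k: tuple(tuple(int(i) for i in ax) for ax in v)
                for k, v in payload["regions"].items()
            },
            expected_axes={k: int(v) for k, v in payload["expected_axes"].items()},
            alignment_floor=float(payload.get("alignment_floor", 0.5)),
        )
    except (KeyError, ValueError, TypeError, AttributeError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed ROI file {path}: {exc}") from exc


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records to one row per subject (labs as columns)."""
    rows = []
    for r in records:
        row = dict(
            subject_id=r.subject_id,
            arm=r.arm,
            age_years=r.age_years,
            male=r.male,
            hemodialysis=r.hemodialysis,
            dialysis_months=r.dialysis_months,
            lambda_pv_true=r.lambda_pv_true,
            alps=r.alps,
        )
        row.update(r.labs)
        if r.alps_measurement is not None:
            m = r.alps_measurement
            for fiber, sample in m.samples.items():
                for axis, label in enumerate("xyz"):
                    # report in the conventional 1e-3 mm^2/s
                    row[f"d{label}{label}_{fiber}"] = sample.along(axis) * 1e3
                row[f"alignment_{fiber}"] = sample.alignment
            row["alps_flagged"] = m.flagged
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: list[SubjectRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def load_config(path) -> dict:
    """Pipeline configuration from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed config {path}: {exc}") from exc
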
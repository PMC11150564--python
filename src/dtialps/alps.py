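"""ALPS (Analysis aLong the Perivascular Space) index from diffusion scalar maps.

At the level of the lateral-ventricle body, the medullary veins run along the
image x axis, perpendicular both to the projection fibers (running along z)
and to the association fibers (running along y). Water diffusivity measured
along x in those two fiber areas is therefore sensitive to diffusion along
the perivascular space, while Dyy in the projection area and Dzz in the
association area capture the fiber-perpendicular background. The index is

    ALPS = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)

with all four quantities extracted from 6-mm circular ROIs drawn on one
axial slice of the FA map, either as ROI means (default) or from the single
voxel with maximal principal-direction alignment to the ROI's fiber axis.
An index of 1 means no preferential diffusion along the perivascular axis;
healthy adult white matter typically sits well above 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    DataQualityError,
    PlacementError,
    SelectionError,
    ValidationError,
)
from .io import ScalarMap
from .tensor import DiffusionMaps

__all__ = [
    "RoiSpec",
    "AlpsInputs",
    "AlpsResult",
    "resolve_rois",
    "select_max_orientation_voxel",
    "extract_alps_inputs",
    "compute_alps_index",
    "alps_for_cohort",
    "FIBER_AXIS",
]

#: image axis along which each fiber class predominantly runs
FIBER_AXIS = {"projection": 2, "association": 1, "subcortical": 0}

#: ALPS numerator/denominator map per fiber class: (numerator axis, denominator axis)
_DEFAULT_DIAMETER_MM = 6.0


@dataclass(frozen=True)
class RoiSpec:
    """A circular single-slice ROI on the axial plane of the FA map.

    ``center`` is a 0-based voxel coordinate; the ROI voxel set is every voxel
    in the same axial slice whose in-plane world distance to the center is at
    most ``diameter_mm / 2``.
    """

    fiber_class: str
    center: tuple[int, int, int]
    diameter_mm: float = _DEFAULT_DIAMETER_MM
    slice_axis: int = 2
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.fiber_class not in FIBER_AXIS:
            raise ConfigError(
                f"unknown fiber class {self.fiber_class!r}; "
                f"expected one of {sorted(FIBER_AXIS)}"
            )
        if not self.diameter_mm > 0:
            raise ValidationError("diameter_mm must be positive")
        if self.slice_axis != 2:
            raise ConfigError("only axial (slice_axis=2) ROIs are supported")
        if self.hemisphere not in ("left", "right"):
            raise ConfigError(f"unknown hemisphere {self.hemisphere!r}")
        object.__setattr__(self, "center", tuple(int(c) for c in self.center))

    def voxel_indices(
        self, shape: tuple[int, int, int], affine: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Indices (i, j, k arrays) of the ROI disc, clipped to the grid."""
        cx, cy, cz = self.center
        if not all(0 <= c < s for c, s in zip(self.center, shape)):
            raise PlacementError(f"ROI center {self.center} outside grid {shape}")
        sx = float(np.linalg.norm(affine[:3, 0]))
        sy = float(np.linalg.norm(affine[:3, 1]))
        r = self.diameter_mm / 2.0
        ni = int(np.floor(r / sx))
        nj = int(np.floor(r / sy))
        ii, jj = np.meshgrid(
            np.arange(cx - ni, cx + ni + 1), np.arange(cy - nj, cy + nj + 1), indexing="ij"
        )
        dist = np.hypot((ii - cx) * sx, (jj - cy) * sy)
        keep = (dist <= r) & (ii >= 0) & (ii < shape[0]) & (jj >= 0) & (jj < shape[1])
        i = ii[keep].astype(int)
        j = jj[keep].astype(int)
        k = np.full(i.shape, cz, dtype=int)
        return i, j, k

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        return cls(
            fiber_class=d["fiber_class"],
            center=tuple(d["center"]),
            diameter_mm=float(d.get("diameter_mm", _DEFAULT_DIAMETER_MM)),
            slice_axis=int(d.get("slice_axis", 2)),
            hemisphere=d.get("hemisphere", "left"),
        )


def load_roi_config(path: str | Path) -> list[RoiSpec]:
    """Read a JSON list of ROI specifications."""
    with open(path) as fh:
        entries = json.load(fh)
    return [RoiSpec.from_dict(e) for e in entries]


def resolve_rois(
    config,
    fa: ScalarMap,
    dmaps: DiffusionMaps | None = None,
    sidecar: dict | None = None,
) -> list[RoiSpec]:
    """Validate an ROI configuration against the FA map.

    ``config`` is a list of :class:`RoiSpec` (or dicts), or the string
    ``"auto"``, in which case ROI centers are taken from a synthetic phantom's
    ground-truth sidecar (key ``roi_centers``: fiber class -> voxel coordinate).
    At least one projection and one association ROI are required. Every ROI
    must overlap the positive-FA support (equivalently the fit mask).
    """
    if config == "auto":
        if sidecar is None or "roi_centers" not in sidecar:
            raise ConfigError("auto ROI mode needs a phantom ground-truth sidecar")
        rois = [
            RoiSpec(fiber_class=fc, center=tuple(int(v) for v in c))
            for fc, c in sidecar["roi_centers"].items()
            if fc in FIBER_AXIS
        ]
    else:
        rois = [r if isinstance(r, RoiSpec) else RoiSpec.from_dict(r) for r in config]

    classes = {r.fiber_class for r in rois}
    for needed in ("projection", "association"):
        if needed not in classes:
            raise ConfigError(f"ROI configuration lacks a {needed}-fiber ROI")

    support = fa.data > 0 if dmaps is None else dmaps.mask
    for roi in rois:
        i, j, k = roi.voxel_indices(fa.shape, fa.affine)
        if i.size == 0 or not support[i, j, k].any():
            raise PlacementError(
                f"{roi.fiber_class} ROI at {roi.center} lies outside the image support"
            )
    return rois


def select_max_orientation_voxel(
    roi: RoiSpec, dmaps: DiffusionMaps
) -> tuple[int, int, int]:
    """ROI voxel whose principal eigenvector best aligns with the fiber axis.

    Maximizes ``|V1 . e_axis|`` (z for projection, y for association, x for
    subcortical); ties broken by smallest linear (C-order) index.
    """
    axis = FIBER_AXIS[roi.fiber_class]
    i, j, k = roi.voxel_indices(dmaps.FA.shape, dmaps.affine)
    inside = dmaps.mask[i, j, k]
    i, j, k = i[inside], j[inside], k[inside]
    if i.size == 0:
        raise SelectionError("ROI contains no masked voxels")
    v1 = dmaps.V1[i, j, k]
    defined = np.isfinite(v1).all(axis=1) & (np.linalg.norm(v1, axis=1) > 0)
    if not defined.any():
        raise SelectionError("principal direction undefined throughout the ROI")
    i, j, k, v1 = i[defined], j[defined], k[defined], v1[defined]
    align = np.abs(v1[:, axis])
    lin = np.ravel_multi_index((i, j, k), dmaps.FA.shape)
    best = np.lexsort((lin, -align))[0]  # max alignment, then smallest index
    return int(i[best]), int(j[best]), int(k[best])


@dataclass(frozen=True)
class AlpsInputs:
    """The four axis-wise diffusivities entering the ALPS ratio (mm^2/s)."""

    dx_proj: float
    dx_assoc: float
    dy_proj: float
    dz_assoc: float
    mode: str = "roi_mean"
    voxel_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("dx_proj", "dx_assoc", "dy_proj", "dz_assoc"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DataQualityError(f"{name} = {v!r} is not a positive diffusivity")


@dataclass(frozen=True)
class AlpsResult:
    """ALPS index for one subject, with its four input diffusivities."""

    index: float
    inputs: AlpsInputs
    subject_id: str = ""

    def as_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "Dxproj": self.inputs.dx_proj,
            "Dxassoc": self.inputs.dx_assoc,
            "Dyproj": self.inputs.dy_proj,
            "Dzassoc": self.inputs.dz_assoc,
            "alps": self.index,
            "mode": self.inputs.mode,
        }


def _roi_value(
    dmaps: DiffusionMaps, roi: RoiSpec, axis: int, mode: str
) -> tuple[float, int]:
    amap = dmaps.axis_map(axis).data
    if mode == "roi_mean":
        i, j, k = roi.voxel_indices(dmaps.FA.shape, dmaps.affine)
        inside = dmaps.mask[i, j, k]
        i, j, k = i[inside], j[inside], k[inside]
        if i.size == 0:
            raise PlacementError(f"{roi.fiber_class} ROI has no masked voxels")
        return float(amap[i, j, k].mean()), int(i.size)
    if mode == "max_orientation_voxel":
        v = select_max_orientation_voxel(roi, dmaps)
        return float(amap[v]), 1
    raise ConfigError(f"unknown extraction mode {mode!r}")


def extract_alps_inputs(
    dmaps: DiffusionMaps, rois: list[RoiSpec], mode: str = "roi_mean"
) -> AlpsInputs:
    """Measure Dx_proj, Dx_assoc, Dy_proj, Dz_assoc from the diagonal maps.

    Dx reads the Dxx map, Dy the Dyy map, Dz the Dzz map (tensor diagonals in
    the image frame). When both hemispheres provide an ROI of a fiber class,
    the hemisphere values are averaged.
    """
    by_class: dict[str, list[RoiSpec]] = {}
    for roi in rois:
        by_class.setdefault(roi.fiber_class, []).append(roi)
    for needed in ("projection", "association"):
        if needed not in by_class:
            raise ConfigError(f"no {needed}-fiber ROI supplied")

    counts: dict[str, int] = {}

    def measure(fiber_class: str, axis: int) -> float:
        vals = []
        n = 0
        for roi in by_class[fiber_class]:
            v, c = _roi_value(dmaps, roi, axis, mode)
            vals.append(v)
            n += c
        counts[f"{fiber_class}_ax{axis}"] = n
        return float(np.mean(vals))

    return AlpsInputs(
        dx_proj=measure("projection", 0),
        dx_assoc=measure("association", 0),
        dy_proj=measure("projection", 1),
        dz_assoc=measure("association", 2),
        mode=mode,
        voxel_counts=counts,
    )


def compute_alps_index(inputs: AlpsInputs, subject_id: str = "") -> AlpsResult:
    """ALPS index = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)."""
    num = 0.5 * (inputs.dx_proj + inputs.dx_assoc)
    den = 0.5 * (inputs.dy_proj + inputs.dz_assoc)
    if den <= 0:
        raise ZeroDivisionError("non-positive ALPS denominator")
    return AlpsResult(index=num / den, inputs=inputs, subject_id=subject_id)


def alps_for_cohort(
    subjects,
    roi_config="auto",
    mode: str = "roi_mean",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Compute the ALPS index for every subject in a batch.

    Parameters
    ----------
    subjects : iterable of (subject_id, DiffusionMaps) or
        (subject_id, DiffusionMaps, sidecar dict) tuples.
    roi_config : "auto" | list of RoiSpec/dict
        Shared explicit ROI list, or per-subject auto placement from each
        subject's ground-truth sidecar.

    Returns
    -------
    (table, errors)
        ``table`` has one row per successful subject (subject_id, the four
        diffusivities, alps, mode); ``errors`` maps failed subject ids to the
        error message. Per-subject failures never abort the batch.
    """
    rows: list[dict] = []
    errors: dict[str, str] = {}
    for item in subjects:
        subject_id, dmaps = item[0], item[1]
        sidecar = item[2] if len(item) > 2 else None
        try:
            rois = resolve_rois(roi_config, dmaps.FA, dmaps, sidecar=sidecar)
            inputs = extract_alps_inputs(dmaps, rois, mode=mode)
            rows.append(compute_alps_index(inputs, subject_id=str(subject_id)).as_row())
        except Exception as exc:
            errors[str(subject_id)] = f"{type(exc).__name__}: {exc}"
    columns = ["subject_id", "Dxproj", "Dxassoc", "Dyproj", "Dzassoc", "alps", "mode"]
    table = pd.DataFrame(rows, columns=columns)
    return table, errors
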
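"""File I/O for the pipeline: NIfTI volumes, FSL-style gradient tables, cohort CSVs.

Gradient directions are interpreted in the image (voxel-axis) frame, matching
the FSL bval/bvec dialect: the bvals file is a single whitespace-separated row
of b-values (s/mm^2) and the bvecs file has three rows (x, y, z components),
one column per diffusion-weighted volume. No radiological flip is applied;
the ALPS axes are image axes and all synthetic data use the same frame.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError, SchemaError, ValidationError

__all__ = [
    "GradientTable",
    "Volume4D",
    "ScalarMap",
    "read_gradient_table",
    "write_gradient_table",
    "read_volume",
    "write_map",
    "read_cohort_table",
    "write_cohort_table",
    "validate_cohort",
    "REQUIRED_COHORT_COLUMNS",
    "OPTIONAL_COHORT_COLUMNS",
    "GROUP_LABELS",
]

#: b-values below this (s/mm^2) are treated as non-diffusion-weighted (b~0).
DEFAULT_B0_THRESHOLD = 50.0

#: tolerance on the unit norm of a diffusion-weighted gradient direction
BVEC_NORM_TOL = 1e-3


@dataclass(frozen=True)
class GradientTable:
    """Per-volume b-values and unit gradient directions of an acquisition.

    Parameters
    ----------
    bvals : (N,) array
        b-value of each volume, s/mm^2, all >= 0.
    bvecs : (N, 3) array
        Gradient direction of each volume in the image frame. Unit norm
        (within ``1e-3``) wherever ``bvals`` exceeds ``b0_threshold``;
        may be zero for b~0 volumes.
    b0_threshold : float
        b-values strictly below this count as b~0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise FormatError(
                f"bvals has {bvals.shape[0]} entries but bvecs has {bvecs.shape[0]}"
            )
        if bvals.shape[0] < 1:
            raise FormatError("gradient table is empty")
        if np.any(bvals < 0):
            raise ValidationError("negative b-values are not physical")
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals >= self.b0_threshold
        bad = np.flatnonzero(dw & (np.abs(norms - 1.0) > BVEC_NORM_TOL))
        if bad.size:
            raise ValidationError(
                f"non-unit gradient direction at volume index {bad[0]} "
                f"(|g| = {norms[bad[0]]:.6f}, tolerance {BVEC_NORM_TOL})"
            )

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask of the b~0 volumes."""
        return self.bvals < self.b0_threshold

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def n_directions(self) -> int:
        """Number of diffusion-weighted volumes."""
        return self.n_volumes - self.n_b0

    def suitable_for_fit(self) -> bool:
        """At least one b~0 volume and six independent directions."""
        if self.n_b0 < 1 or self.n_directions < 6:
            return False
        g = self.bvecs[~self.b0_mask]
        # outer products g g^T span a 6-dim space iff directions are independent
        outer = np.stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                g[:, 0] * g[:, 1],
                g[:, 0] * g[:, 2],
                g[:, 1] * g[:, 2],
            ],
            axis=1,
        )
        return int(np.linalg.matrix_rank(outer)) >= 6


def _parse_rows(text: str, what: str) -> list[np.ndarray]:
    rows = []
    for line in text.strip().splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            rows.append(np.array([float(tok) for tok in line.split()]))
        except ValueError as exc:
            raise FormatError(f"non-numeric token in {what}: {exc}") from exc
    if not rows:
        raise FormatError(f"{what} is empty")
    return rows


def read_gradient_table(
    bval_text: str, bvec_text: str, b0_threshold: float = DEFAULT_B0_THRESHOLD
) -> GradientTable:
    """Parse FSL-dialect bval/bvec text into a validated :class:`GradientTable`.

    ``bval_text`` is one row of N b-values; ``bvec_text`` is exactly three rows
    (x, y, z) of N direction components each.
    """
    bval_rows = _parse_rows(bval_text, "bvals")
    bvals = np.concatenate(bval_rows)
    bvec_rows = _parse_rows(bvec_text, "bvecs")
    if len(bvec_rows) != 3:
        raise FormatError(f"bvecs must have exactly 3 rows, got {len(bvec_rows)}")
    lengths = {len(r) for r in bvec_rows}
    if len(lengths) != 1:
        raise FormatError(f"bvec rows have unequal lengths {sorted(lengths)}")
    bvecs = np.stack(bvec_rows, axis=1)
    if bvals.shape[0] != bvecs.shape[0]:
        raise FormatError(
            f"{bvals.shape[0]} bvals but {bvecs.shape[0]} bvec columns"
        )
    return GradientTable(bvals=bvals, bvecs=bvecs, b0_threshold=b0_threshold)


def write_gradient_table(gtab: GradientTable) -> tuple[str, str]:
    """Serialize a gradient table back to FSL bval/bvec text (row/3-row form)."""
    bval_text = " ".join(format(b, ".6g") for b in gtab.bvals) + "\n"
    lines = [
        " ".join(format(v, ".17g") for v in gtab.bvecs[:, ax]) for ax in range(3)
    ]
    return bval_text, "\n".join(lines) + "\n"


def load_gradient_table(
    bval_path: str | Path, bvec_path: str | Path, **kw
) -> GradientTable:
    return read_gradient_table(
        Path(bval_path).read_text(), Path(bvec_path).read_text(), **kw
    )


def save_gradient_table(
    gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path
) -> None:
    bval_text, bvec_text = write_gradient_table(gtab)
    Path(bval_path).write_text(bval_text)
    Path(bvec_path).write_text(bvec_text)


@dataclass
class ScalarMap:
    """A 3-D scalar image with its voxel-to-world affine.

    ``name`` is a semantic label (FA, MD, AD, RD, Dxx, Dyy, Dzz, mask,
    tstat, tfce, pcorr, ...) used when writing files and in reports.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    name: str = "map"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"ScalarMap data must be 3-D, got {self.data.ndim}-D")
        _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray, name: str | None = None) -> "ScalarMap":
        return ScalarMap(data=data, affine=self.affine, name=name or self.name)


@dataclass
class Volume4D:
    """A 4-D diffusion-weighted series (x, y, z, volume) with gradients."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    gradients: GradientTable | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError(f"Volume4D data must be 4-D, got {self.data.ndim}-D")
        _check_affine(self.affine)
        if self.gradients is not None and self.gradients.n_volumes != self.data.shape[3]:
            raise ValidationError(
                f"4th dimension has {self.data.shape[3]} volumes but gradient "
                f"table has {self.gradients.n_volumes}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def _check_affine(affine: np.ndarray) -> None:
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")
    if not np.isfinite(affine).all() or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine is not invertible")


def read_volume(
    path: str | Path,
    name: str | None = None,
    gradients: GradientTable | None = None,
):
    """Load a NIfTI-1 file; 3-D data yields a :class:`ScalarMap`, 4-D a :class:`Volume4D`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise OSError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    affine = np.asarray(img.affine)
    if data.ndim == 3:
        return ScalarMap(data=data, affine=affine, name=name or path.name.split(".")[0])
    if data.ndim == 4:
        return Volume4D(data=data, affine=affine, gradients=gradients)
    raise FormatError(f"{path}: expected 3-D or 4-D image, got {data.ndim}-D")


def write_map(obj: ScalarMap | Volume4D, path: str | Path) -> None:
    """Write a map or 4-D volume as NIfTI-1, preserving data and affine exactly."""
    path = Path(path)
    if not path.parent.is_dir():
        raise OSError(f"parent directory does not exist: {path.parent}")
    data = obj.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, obj.affine)
    nib.save(img, str(path))


def write_vector_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a per-voxel 3-vector field (x, y, z, 3) as a 4-D NIfTI."""
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValidationError(f"vector map must be (x, y, z, 3), got {data.shape}")
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine, float)), str(path))


# ---------------------------------------------------------------------------
# cohort tables

GROUP_LABELS = ("T2DM", "HC")

REQUIRED_COHORT_COLUMNS = ("subject_id", "group")

#: optional columns, mirroring the demographic/laboratory/cognitive variables
OPTIONAL_COHORT_COLUMNS = (
    "age",
    "sex",
    "education_years",
    "BMI",
    "HbA1c",
    "insulin",
    "FG",
    "cholesterol",
    "triglyceride",
    "HDL",
    "LDL",
    "Hcy",
    "SDMT",
    "MoCA",
    "MMSE",
    "alps",
)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a cohort table (one row per subject).

    Required columns: ``subject_id`` and ``group`` (restricted to T2DM/HC).
    Missing values in optional columns are preserved as NaN.
    """
    for col in REQUIRED_COHORT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort table is missing required column '{col}'")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate subject_id '{dup}'")
    groups = df["group"].astype(str)
    unknown = sorted(set(groups) - set(GROUP_LABELS))
    if unknown:
        raise ValidationError(
            f"unknown group label(s) {unknown}; expected one of {list(GROUP_LABELS)}"
        )
    df["group"] = pd.Categorical(groups, categories=list(GROUP_LABELS))
    for col in OPTIONAL_COHORT_COLUMNS:
        if col in df.columns and col != "sex":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "alps" in df.columns:
        bad = df["alps"].dropna() <= 0
        if bad.any():
            raise ValidationError("alps must be positive where present")
    for col, hi in (("MoCA", 30), ("MMSE", 30)):
        if col in df.columns:
            v = df[col].dropna()
            if ((v < 0) | (v > hi)).any():
                raise ValidationError(f"{col} outside [0, {hi}]")
    return df


def read_cohort_table(path_or_buf) -> pd.DataFrame:
    """Read and validate a cohort CSV (header row required)."""
    if isinstance(path_or_buf, (str, Path)) and not Path(path_or_buf).exists():
        raise OSError(f"cohort table not found: {path_or_buf}")
    df = pd.read_csv(path_or_buf)
    return validate_cohort(df)


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def cohort_from_csv_text(text: str) -> pd.DataFrame:
    return read_cohort_table(_stdio.StringIO(text))
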
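"""Diffusion-tensor forward model, per-voxel estimation, and derived scalar maps.

The signal model is the standard mono-exponential tensor model

    S(b, g) = S0 * exp(-b * g^T D g)

with D a symmetric positive (in tissue) 3x3 tensor in mm^2/s. Estimation is
log-linear least squares: taking logs gives a linear model in the seven
unknowns (ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz). The default is weighted
least squares (WLS) with weights equal to the squared predicted signals from
an initial ordinary (OLS) pass, which undoes the noise distortion introduced
by the log transform; plain OLS is retained for testing and comparison.

Derived maps follow the usual conventions: eigenvalues sorted l1 >= l2 >= l3,
axial diffusivity AD = l1, radial RD = (l2 + l3)/2, mean MD = trace/3, and

    FA = sqrt(3/2) * sqrt(sum (li - MD)^2) / sqrt(sum li^2)

with FA defined as 0 where the tensor is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import EstimationError, MaskingError, ValidationError
from .io import GradientTable, ScalarMap, Volume4D, write_map, write_vector_map

__all__ = [
    "TensorField",
    "DiffusionMaps",
    "predict_signal",
    "fit_tensor",
    "scalar_maps",
    "compute_mask",
    "TENSOR_COMPONENTS",
]

#: storage order of the six unique tensor components
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

#: relative signal floor applied before the log transform
SIGNAL_FLOOR = 1e-6


def _design_matrix(gtab: GradientTable) -> np.ndarray:
    """(N, 7) design for ln S = X @ (ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)."""
    b = gtab.bvals
    gx, gy, gz = gtab.bvecs.T
    return np.stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -b * gy * gy,
            -2.0 * b * gy * gz,
            -b * gz * gz,
        ],
        axis=1,
    )


def _to_6(D: np.ndarray) -> np.ndarray:
    """Flatten symmetric (..., 3, 3) tensors to (..., 6) component vectors."""
    return np.stack(
        [D[..., 0, 0], D[..., 0, 1], D[..., 0, 2], D[..., 1, 1], D[..., 1, 2], D[..., 2, 2]],
        axis=-1,
    )


def _to_3x3(d6: np.ndarray) -> np.ndarray:
    """Expand (..., 6) component vectors to symmetric (..., 3, 3) tensors."""
    d6 = np.asarray(d6)
    out = np.zeros(d6.shape[:-1] + (3, 3), dtype=d6.dtype)
    out[..., 0, 0] = d6[..., 0]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 1]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 2]
    out[..., 1, 1] = d6[..., 3]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 4]
    out[..., 2, 2] = d6[..., 5]
    return out


def predict_signal(D: np.ndarray, S0: float, gradients: GradientTable) -> np.ndarray:
    """Forward model: per-volume signal for one tensor.

    Parameters
    ----------
    D : (3, 3) array
        Symmetric diffusion tensor, mm^2/s.
    S0 : float
        Non-diffusion-weighted signal, > 0.
    gradients : GradientTable

    Returns
    -------
    (N,) array of signals; equals ``S0`` at every b~0 volume.
    """
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ValidationError(f"D must be 3x3, got {D.shape}")
    if not np.allclose(D, D.T, atol=1e-12, rtol=0.0):
        raise ValidationError("D must be symmetric")
    if not S0 > 0:
        raise ValidationError("S0 must be positive")
    g = gradients.bvecs
    adc = np.einsum("ni,ij,nj->n", g, D, g)
    return S0 * np.exp(-gradients.bvals * adc)


@dataclass
class TensorField:
    """Per-voxel fitted tensor (6 unique components), S0, and fit mask.

    Outside the mask every field is zero. ``eigensystem`` returns eigenvalues
    in non-increasing order l1 >= l2 >= l3 with matching eigenvectors.
    """

    D: np.ndarray  # (x, y, z, 6) in TENSOR_COMPONENTS order
    S0: np.ndarray  # (x, y, z)
    mask: np.ndarray  # (x, y, z) bool
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.D.shape != self.mask.shape + (6,):
            raise ValidationError("D must have shape mask.shape + (6,)")
        if not np.isfinite(self.D[self.mask]).all():
            raise ValidationError("non-finite tensor components inside the mask")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def tensors_3x3(self) -> np.ndarray:
        return _to_3x3(self.D)

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (x,y,z,3), descending, and eigenvectors (x,y,z,3,3).

        ``evecs[..., :, k]`` is the unit eigenvector of ``evals[..., k]``;
        zero outside the mask.
        """
        evals = np.zeros(self.spatial_shape + (3,))
        evecs = np.zeros(self.spatial_shape + (3, 3))
        if self.mask.any():
            w, v = np.linalg.eigh(_to_3x3(self.D[self.mask]))
            order = np.argsort(w, axis=-1)[..., ::-1]
            w = np.take_along_axis(w, order, axis=-1)
            v = np.take_along_axis(v, order[..., None, :], axis=-1)
            evals[self.mask] = w
            evecs[self.mask] = v
        return evals, evecs


def fit_tensor(
    dwi: Volume4D,
    mask: ScalarMap | np.ndarray | None = None,
    method: str = "WLS",
) -> TensorField:
    """Estimate a diffusion tensor in every masked voxel by log-linear least squares.

    ``method`` is ``"OLS"`` (one pass on log signals) or ``"WLS"`` (default;
    reweighted by squared OLS-predicted signals). Signals are clamped to
    ``1e-6 * S0`` (S0 approximated by the per-voxel mean b~0 signal) before
    the log so non-positive samples cannot produce -inf.
    """
    method = method.upper()
    if method not in ("OLS", "WLS"):
        raise ValueError(f"unknown fit method {method!r}")
    gtab = dwi.gradients
    if gtab is None:
        raise ValidationError("Volume4D has no gradient table attached")
    if gtab.n_b0 < 1 or not gtab.suitable_for_fit():
        raise EstimationError(
            "tensor fit needs >= 1 b~0 volume and >= 6 independent directions"
        )
    X = _design_matrix(gtab)
    if np.linalg.matrix_rank(X) < 7:
        raise EstimationError("rank-deficient design: directions are not independent")

    if mask is None:
        mask_arr = np.ones(dwi.spatial_shape, dtype=bool)
    else:
        mask_arr = np.asarray(mask.data if isinstance(mask, ScalarMap) else mask) > 0
    if mask_arr.shape != dwi.spatial_shape:
        raise ValidationError("mask shape does not match the DWI spatial shape")
    if not mask_arr.any():
        raise EstimationError("mask is empty")

    S = dwi.data[mask_arr].astype(float)  # (nvox, N)
    s0_proxy = S[:, gtab.b0_mask].mean(axis=1)
    s0_proxy = np.where(s0_proxy > 0, s0_proxy, np.abs(S).max(axis=1))
    s0_proxy = np.maximum(s0_proxy, np.finfo(float).tiny)
    floor = SIGNAL_FLOOR * s0_proxy[:, None]
    logS = np.log(np.maximum(S, floor))

    beta = np.linalg.lstsq(X, logS.T, rcond=None)[0].T  # (nvox, 7)
    if method == "WLS":
        # weights = squared predicted signals from the OLS pass
        w = np.exp(2.0 * (beta @ X.T))  # (nvox, N)
        Xw = X[None, :, :] * w[:, :, None]  # w_i x_i
        XtWX = np.einsum("vnp,nq->vpq", Xw, X)
        XtWy = np.einsum("vnp,vn->vp", Xw, logS)
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]

    shape = dwi.spatial_shape
    D = np.zeros(shape + (6,))
    S0 = np.zeros(shape)
    D[mask_arr] = beta[:, 1:]
    S0[mask_arr] = np.exp(beta[:, 0])
    return TensorField(D=D, S0=S0, mask=mask_arr, affine=np.asarray(dwi.affine))


@dataclass
class DiffusionMaps:
    """Scalar maps derived from a fitted tensor field.

    FA is dimensionless in [0, 1]; MD/AD/RD and the diagonal maps are in
    mm^2/s; V1 is the per-voxel principal-direction unit vector (x, y, z, 3).
    """

    FA: ScalarMap
    MD: ScalarMap
    AD: ScalarMap
    RD: ScalarMap
    Dxx: ScalarMap
    Dyy: ScalarMap
    Dzz: ScalarMap
    V1: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def axis_map(self, axis: int) -> ScalarMap:
        """Diagonal diffusivity map along image axis 0 (x), 1 (y), or 2 (z)."""
        return (self.Dxx, self.Dyy, self.Dzz)[axis]

    def save(self, out_dir: str | Path, prefix: str = "") -> None:
        out_dir = Path(out_dir)
        for m in (self.FA, self.MD, self.AD, self.RD, self.Dxx, self.Dyy, self.Dzz):
            write_map(m, out_dir / f"{prefix}{m.name}.nii.gz")
        write_map(
            ScalarMap(self.mask.astype(np.uint8), self.affine, "mask"),
            out_dir / f"{prefix}mask.nii.gz",
        )
        write_vector_map(self.V1, self.affine, out_dir / f"{prefix}V1.nii.gz")


def scalar_maps(tf: TensorField) -> DiffusionMaps:
    """Compute FA/MD/AD/RD, diagonal diffusivities, and V1 from a tensor field."""
    evals, evecs = tf.eigensystem()
    md = evals.mean(axis=-1)
    num = np.sqrt(((evals - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    fa = np.zeros_like(md)
    nz = den > 0
    fa[nz] = np.sqrt(1.5) * num[nz] / den[nz]
    np.clip(fa, 0.0, 1.0, out=fa)
    ad = evals[..., 0]
    rd = 0.5 * (evals[..., 1] + evals[..., 2])
    v1 = evecs[..., :, 0]
    aff = tf.affine

    def m(data: np.ndarray, name: str) -> ScalarMap:
        return ScalarMap(data=data, affine=aff, name=name)

    return DiffusionMaps(
        FA=m(fa, "FA"),
        MD=m(md, "MD"),
        AD=m(ad, "AD"),
        RD=m(rd, "RD"),
        Dxx=m(tf.D[..., 0], "Dxx"),
        Dyy=m(tf.D[..., 3], "Dyy"),
        Dzz=m(tf.D[..., 5], "Dzz"),
        V1=v1,
        mask=tf.mask,
        affine=aff,
    )


def compute_mask(
    b0: ScalarMap, method: str = "otsu", fraction: float = 0.25
) -> ScalarMap:
    """Threshold a b~0 image into a foreground mask, keeping the largest component.

    ``method="otsu"`` picks the threshold by Otsu's criterion;
    ``method="fraction-of-max"`` uses ``fraction * max(b0)``.
    """
    data = np.asarray(b0.data, dtype=float)
    if np.any(data < 0):
        raise ValidationError("b0 image must be non-negative")
    if method == "otsu":
        if np.ptp(data) == 0:
            raise MaskingError("b0 image is constant; cannot threshold")
        thr = threshold_otsu(data.ravel())  # 1-D: histogram only, any grid shape
    elif method == "fraction-of-max":
        thr = fraction * data.max()
    else:
        raise ValueError(f"unknown masking method {method!r}")
    fg = data > thr
    if not fg.any():
        raise MaskingError("empty foreground after thresholding")
    labels, n = ndimage.label(fg)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    return ScalarMap(data=mask, affine=b0.affine, name="mask")
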
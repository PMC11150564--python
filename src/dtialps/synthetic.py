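"""Synthetic inputs with known ground truth: DWI phantoms and cohort tables.

Phantoms
--------
The phantom mimics the ROI geometry of an axial slice at the level of the
lateral-ventricle body: three fiber slabs arranged lateral-to-medial along x
inside an isotropic tissue block — subcortical fibers (principal axis x),
association fibers (axis y), and projection fibers (axis z) — surrounded by
zero-signal background. Region tensors are diagonal in the image frame, and a
"perivascular" increment is added to the xx component of the projection and
association regions, so the ground-truth ALPS index is available in closed
form from the spec alone:

    ALPS_true = ((Dxx_proj + Dxx_assoc)/2) / ((Dyy_proj + Dzz_assoc)/2).

Signals follow the mono-exponential tensor model and are corrupted with
Rician noise, S_noisy = sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma^2), with
sigma = S0 / SNR. The default acquisition is 64 electrostatically spread
directions at b = 1000 s/mm^2 plus one b=0 volume; the default grid is
32 x 32 x 8 voxels at 2 mm isotropic — large enough to hold 6-mm ROIs,
small enough for seconds-scale simulation.

Cohorts
-------
Cohort tables emulate the study's demographics: 41 T2DM patients vs 27
healthy controls, per-variable group means/SDs matching the published
demographics table, sex drawn at the published proportions, an ALPS group
difference of 1.30 +/- 0.13 vs 1.44 +/- 0.11, and a prescribed Spearman
correlation between the ALPS index and MoCA within the patient group,
realised through a Gaussian copula using the bivariate-normal conversion
rho_pearson = 2 sin(pi * rho_spearman / 6). Covariates are generated
mutually independent (the publication gives no covariance structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import SpecError
from .io import GradientTable, Volume4D, validate_cohort
from .utils import derive_seed

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "electrostatic_directions",
    "make_gradient_table",
    "simulate_phantom",
    "simulate_phantom_cohort",
    "simulate_cohort",
    "null_cohort",
    "table1_fixture",
]


# ---------------------------------------------------------------------------
# gradient scheme


def electrostatic_directions(n: int, n_iter: int = 300, step: float = 2e-3) -> np.ndarray:
    """``n`` unit vectors spread by antipodally-symmetric electrostatic repulsion.

    Deterministic: initialised on a golden-spiral point set and relaxed by
    gradient steps on the Coulomb energy of the +/- charge pairs.
    """
    if n < 6:
        raise SpecError("need at least 6 directions")
    idx = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * idx / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * idx
    p = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    eye = np.eye(n, dtype=bool)
    for _ in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]
        anti = p[:, None, :] + p[None, :, :]
        d3 = np.linalg.norm(diff, axis=-1, keepdims=True) ** 3
        a3 = np.linalg.norm(anti, axis=-1, keepdims=True) ** 3
        d3[eye] = np.inf
        a3[np.linalg.norm(anti, axis=-1) < 1e-9] = np.inf
        force = (diff / d3).sum(axis=1) + (anti / a3).sum(axis=1)
        force -= (force * p).sum(axis=1, keepdims=True) * p  # tangential part
        p = p + step * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def make_gradient_table(
    n_directions: int = 64, b_value: float = 1000.0, n_b0: int = 1
) -> GradientTable:
    """Acquisition scheme: ``n_b0`` b=0 volumes then ``n_directions`` DWIs."""
    dirs = electrostatic_directions(n_directions)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


# ---------------------------------------------------------------------------
# phantom

#: fiber slabs ordered lateral -> medial along x (start, stop) in a 32-wide grid
_REGION_ORDER = ("subcortical", "association", "projection")


class _Block(NamedTuple):
    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    def slices(self):
        return tuple(slice(lo, hi) for lo, hi in self)

    def center(self) -> tuple[int, int, int]:
        return tuple((lo + hi - 1) // 2 for lo, hi in self)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, diffusivities, acquisition, and noise of one synthetic subject.

    Region eigenvalues are given per fiber class as (principal, second, third)
    in mm^2/s and laid along the class axis (x for subcortical, y for
    association, z for projection); ``perivascular_dx`` is added to the xx
    component of the projection and association tensors. ``snr = None`` means
    noiseless; otherwise sigma = s0 / snr.
    """

    shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size_mm: float = 2.0
    b_value: float = 1000.0
    n_directions: int = 64
    n_b0: int = 1
    s0: float = 500.0
    snr: float | None = None
    fiber_eigenvalues: tuple[float, float, float] = (1.4e-3, 0.4e-3, 0.4e-3)
    isotropic_diffusivity: float = 0.8e-3
    perivascular_dx: float = 0.176e-3

    def __post_init__(self) -> None:
        if self.n_directions < 6:
            raise SpecError("need >= 6 diffusion directions")
        if any(ev <= 0 for ev in self.fiber_eigenvalues):
            raise SpecError("eigenvalues must be positive")
        if self.isotropic_diffusivity <= 0 or self.s0 <= 0:
            raise SpecError("diffusivities and s0 must be positive")
        if self.snr is not None and self.snr <= 0:
            raise SpecError("snr must be positive (or None for noiseless)")
        if self.perivascular_dx < 0:
            raise SpecError("perivascular_dx must be non-negative")
        for lo, hi in zip(self.shape, (16, 16, 4)):
            if lo < hi:
                raise SpecError(f"grid {self.shape} too small; need >= (16, 16, 4)")

    # -- geometry -----------------------------------------------------------

    def _blocks(self) -> dict[str, _Block]:
        nx, ny, nz = self.shape
        y = (ny // 4, ny - ny // 4)
        z = (nz // 4, nz - nz // 4)
        width = max(3, (nx - 12) // 3)
        gap = 1
        x0 = (nx - 3 * width - 2 * gap) // 2
        blocks = {}
        for i, name in enumerate(_REGION_ORDER):
            lo = x0 + i * (width + gap)
            blocks[name] = _Block((lo, lo + width), y, z)
        spans = sorted(b.x for b in blocks.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if b_lo < a_hi:
                raise SpecError("fiber regions overlap")
        return blocks

    def labels(self) -> np.ndarray:
        """Region label map: 0 background, 1 tissue, 2 subcortical, 3 association, 4 projection."""
        lab = np.zeros(self.shape, dtype=np.uint8)
        nx, ny, nz = self.shape
        lab[2 : nx - 2, 2 : ny - 2, :] = 1
        for i, name in enumerate(_REGION_ORDER):
            lab[self._blocks()[name].slices()] = 2 + i
        return lab

    def roi_centers(self) -> dict[str, tuple[int, int, int]]:
        return {name: blk.center() for name, blk in self._blocks().items()}

    # -- tensors ------------------------------------------------------------

    def region_tensors(self) -> dict[str, np.ndarray]:
        """Diagonal (Dxx, Dyy, Dzz) per region, mm^2/s."""
        e1, e2, e3 = self.fiber_eigenvalues
        d = {
            "tissue": np.full(3, self.isotropic_diffusivity),
            "subcortical": np.array([e1, e2, e3]),
            "association": np.array([e2, e1, e3]),
            "projection": np.array([e2, e3, e1]),
        }
        d["association"] = d["association"] + np.array([self.perivascular_dx, 0, 0])
        d["projection"] = d["projection"] + np.array([self.perivascular_dx, 0, 0])
        return d

    def true_alps_index(self) -> float:
        """Closed-form ground-truth ALPS index implied by the region tensors."""
        t = self.region_tensors()
        num = 0.5 * (t["projection"][0] + t["association"][0])
        den = 0.5 * (t["projection"][1] + t["association"][2])
        return float(num / den)

    def with_alps_index(self, target: float) -> "PhantomSpec":
        """Adjust the perivascular increment so the true index equals ``target``.

        Solves target = (dxx0 + dx) / den for dx given the base eigenvalues;
        targets below the baseline ratio are infeasible.
        """
        # projection = (e2, e3, e1), association = (e2, e1, e3), so the
        # denominator (Dyy_proj + Dzz_assoc)/2 = e3 and the numerator e2 + dx
        e1, e2, e3 = self.fiber_eigenvalues
        dx = target * e3 - e2
        if dx < 0:
            raise SpecError(
                f"target index {target} below the baseline ratio {e2 / e3:.3f}"
            )
        return replace(self, perivascular_dx=float(dx))

    @property
    def sigma(self) -> float:
        return 0.0 if self.snr is None else self.s0 / self.snr

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff


def simulate_phantom(
    spec: PhantomSpec, seed: int | None = None, gtab: GradientTable | None = None
) -> tuple[Volume4D, dict]:
    """Simulate one subject's DWI series plus its ground-truth sidecar.

    Returns a :class:`Volume4D` (gradient table attached) and a sidecar dict
    with the region label map, the true per-region diagonal tensors, the
    closed-form true ALPS index, and the auto-placement ROI centers.
    Deterministic given ``seed``.
    """
    if gtab is None:
        gtab = make_gradient_table(spec.n_directions, spec.b_value, spec.n_b0)
    labels = spec.labels()
    tensors = spec.region_tensors()
    diag = np.zeros(spec.shape + (3,))
    for i, name in enumerate(("tissue", *_REGION_ORDER)):
        diag[labels == 1 + i] = tensors[name]

    # diagonal tensors: ADC_n = sum_i g_ni^2 * d_i
    g2 = gtab.bvecs**2  # (N, 3)
    adc = diag.reshape(-1, 3) @ (g2.T)  # (nvox, N)
    signal = np.where(
        (labels.reshape(-1) > 0)[:, None], spec.s0 * np.exp(-gtab.bvals * adc), 0.0
    )
    if spec.snr is not None:
        rng = np.random.default_rng(seed)
        sigma = spec.sigma
        e1 = rng.normal(0.0, sigma, signal.shape)
        e2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2**2)
    data = signal.reshape(spec.shape + (gtab.n_volumes,))
    vol = Volume4D(data=data, affine=spec.affine(), gradients=gtab)
    sidecar = {
        "labels": labels,
        "region_tensors": {k: v.tolist() for k, v in tensors.items()},
        "true_alps": spec.true_alps_index(),
        "roi_centers": {k: list(v) for k, v in spec.roi_centers().items()},
        "voxel_size_mm": spec.voxel_size_mm,
        "sigma": spec.sigma,
    }
    return vol, sidecar


def simulate_phantom_cohort(
    n_subjects: int,
    base_spec: PhantomSpec = PhantomSpec(),
    alps_mean: float = 1.44,
    alps_sd: float = 0.11,
    seed: int = 0,
):
    """Phantom series for a cohort with per-subject true ALPS ~ N(mean, sd).

    Yields ``(subject_id, Volume4D, sidecar)`` tuples; per-subject noise and
    target indices derive deterministically from ``seed``.
    """
    rng = np.random.default_rng(derive_seed(seed, "phantom-cohort-targets"))
    e2, e3 = base_spec.fiber_eigenvalues[1], base_spec.fiber_eigenvalues[2]
    floor = e2 / e3 + 1e-6
    out = []
    for i in range(n_subjects):
        target = max(float(rng.normal(alps_mean, alps_sd)), floor)
        spec = base_spec.with_alps_index(target)
        vol, sidecar = simulate_phantom(spec, seed=derive_seed(seed, f"subject-{i}"))
        out.append((f"sub-{i:03d}", vol, sidecar))
    return out


# ---------------------------------------------------------------------------
# cohort tables


class SummaryRow(NamedTuple):
    """Per-variable group summaries: T2DM mean/SD vs HC mean/SD."""

    t2dm_mean: float
    t2dm_sd: float
    hc_mean: float
    hc_sd: float


_TABLE1_ROWS = MappingProxyType(
    {
        "age": SummaryRow(60.49, 8.88, 58.00, 7.63),
        "BMI": SummaryRow(25.48, 3.09, 23.60, 3.22),
        "HbA1c": SummaryRow(7.58, 1.45, 5.50, 0.26),
        "insulin": SummaryRow(9.13, 8.67, 6.78, 3.92),
        "FG": SummaryRow(8.24, 2.58, 4.88, 0.46),
        "cholesterol": SummaryRow(4.72, 0.95, 5.01, 0.92),
        "triglyceride": SummaryRow(1.82, 1.28, 1.22, 0.63),
        "HDL": SummaryRow(1.06, 0.25, 1.29, 0.28),
        "LDL": SummaryRow(2.57, 0.60, 2.74, 0.65),
        "Hcy": SummaryRow(12.32, 3.43, 12.53, 3.17),
        "SDMT": SummaryRow(33.97, 2.41, 41.02, 2.69),
        "MoCA": SummaryRow(25.42, 2.37, 26.33, 2.57),
        "MMSE": SummaryRow(28.49, 3.45, 28.85, 0.91),
    }
)

_TABLE1_FIXTURE = MappingProxyType(
    {
        "n": (41, 27),
        # (female, male) per group
        "sex_counts": ((20, 21), (17, 10)),
        "rows": _TABLE1_ROWS,
        "alps": SummaryRow(1.30, 0.13, 1.44, 0.11),
    }
)


def table1_fixture():
    """The published per-group summary statistics (means, SDs, counts).

    Returns an immutable mapping with keys ``n`` (group sizes), ``sex_counts``
    ((female, male) per group), ``rows`` (variable -> :class:`SummaryRow`),
    and ``alps``. The same frozen object is returned on every call.
    """
    return _TABLE1_FIXTURE


#: instrument / physiology ranges applied after sampling
_VALUE_RANGES = {
    "MoCA": (0, 30, True),
    "MMSE": (0, 30, True),
    "SDMT": (0, 110, True),
    "age": (18, 100, True),
    "education_years": (0, 25, True),
    "BMI": (10.0, None, False),
    "HbA1c": (3.0, None, False),
    "insulin": (0.1, None, False),
    "FG": (2.0, None, False),
    "cholesterol": (0.5, None, False),
    "triglyceride": (0.1, None, False),
    "HDL": (0.1, None, False),
    "LDL": (0.1, None, False),
    "Hcy": (1.0, None, False),
}


@dataclass(frozen=True)
class CohortSpec:
    """Distributional spec of a synthetic cohort.

    Defaults reproduce the published demographics: group sizes 41/27,
    per-variable means and SDs from the demographics table, ALPS
    1.30 +/- 0.13 (T2DM) vs 1.44 +/- 0.11 (HC), and a Spearman correlation
    of 0.39 between ALPS and MoCA within the patient group. Education years
    are not tabulated in the publication (groups were education-matched);
    12 +/- 3 is used for both groups.
    """

    n_t2dm: int = 41
    n_hc: int = 27
    variables: MappingProxyType = field(default_factory=lambda: _TABLE1_ROWS)
    education: SummaryRow = SummaryRow(12.0, 3.0, 12.0, 3.0)
    alps: SummaryRow = SummaryRow(1.30, 0.13, 1.44, 0.11)
    p_female: tuple[float, float] = (20 / 41, 17 / 27)
    target_spearman_alps_moca: float = 0.39
    round_scores: bool = True

    def __post_init__(self) -> None:
        if self.n_t2dm < 1 or self.n_hc < 1:
            raise SpecError("group sizes must be positive")
        if not abs(self.target_spearman_alps_moca) < 1:
            raise SpecError("|target Spearman| must be < 1")
        for row in (*self.variables.values(), self.education, self.alps):
            if row.t2dm_sd <= 0 or row.hc_sd <= 0:
                raise SpecError("all SDs must be positive")

    @classmethod
    def null(cls) -> "CohortSpec":
        """Both groups share every distribution; no ALPS effect, no correlation."""
        rows = {
            k: SummaryRow(r.hc_mean, r.hc_sd, r.hc_mean, r.hc_sd)
            for k, r in _TABLE1_ROWS.items()
        }
        return cls(
            variables=MappingProxyType(rows),
            alps=SummaryRow(1.44, 0.11, 1.44, 0.11),
            p_female=(17 / 27, 17 / 27),
            target_spearman_alps_moca=0.0,
        )


def _clip_round(name: str, values: np.ndarray, round_scores: bool) -> np.ndarray:
    rng = _VALUE_RANGES.get(name)
    if rng is None:
        return values
    lo, hi, integer = rng
    out = np.clip(values, lo, hi if hi is not None else np.inf)
    if integer and round_scores:
        out = np.round(out)
    return out


def simulate_cohort(spec: CohortSpec = CohortSpec(), seed: int = 0) -> pd.DataFrame:
    """Draw a cohort table from a :class:`CohortSpec`. Deterministic given seed.

    Within the T2DM group, (ALPS, MoCA) come from a Gaussian copula whose
    latent Pearson correlation is 2 sin(pi * rho_s / 6), the exact
    bivariate-normal inverse of the Spearman correlation; in the HC group the
    two are drawn independently. All other covariates are independent.
    Cognitive scores are rounded to integers and clipped to instrument ranges;
    laboratory values are clipped to physiological floors.
    """
    rng = np.random.default_rng(seed)
    rho_s = spec.target_spearman_alps_moca
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)

    frames = []
    for gi, (group, n) in enumerate((("T2DM", spec.n_t2dm), ("HC", spec.n_hc))):
        data: dict[str, np.ndarray] = {}
        data["subject_id"] = np.array([f"{group.lower()}-{i:03d}" for i in range(n)])
        data["group"] = np.full(n, group)
        data["sex"] = np.where(rng.random(n) < spec.p_female[gi], "F", "M")
        for var, row in spec.variables.items():
            if var == "MoCA":
                continue  # drawn jointly with ALPS below
            m, s = (row.t2dm_mean, row.t2dm_sd) if gi == 0 else (row.hc_mean, row.hc_sd)
            data[var] = _clip_round(var, rng.normal(m, s, n), spec.round_scores)
        em, es = (
            (spec.education.t2dm_mean, spec.education.t2dm_sd)
            if gi == 0
            else (spec.education.hc_mean, spec.education.hc_sd)
        )
        data["education_years"] = _clip_round(
            "education_years", rng.normal(em, es, n), spec.round_scores
        )

        am, asd = (
            (spec.alps.t2dm_mean, spec.alps.t2dm_sd)
            if gi == 0
            else (spec.alps.hc_mean, spec.alps.hc_sd)
        )
        mrow = spec.variables["MoCA"]
        mm, ms = (mrow.t2dm_mean, mrow.t2dm_sd) if gi == 0 else (mrow.hc_mean, mrow.hc_sd)
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        r = rho_p if group == "T2DM" else 0.0
        z2 = r * z1 + np.sqrt(1.0 - r * r) * z2
        alps = np.maximum(am + asd * z1, 1e-3)
        moca = _clip_round("MoCA", mm + ms * z2, spec.round_scores)
        data["alps"] = alps
        data["MoCA"] = moca
        frames.append(pd.DataFrame(data))

    df = pd.concat(frames, ignore_index=True)
    ordered = [
        "subject_id",
        "group",
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
    ]
    return validate_cohort(df[ordered])


def null_cohort(seed: int = 0, n_t2dm: int = 41, n_hc: int = 27) -> pd.DataFrame:
    """A cohort where both groups share every distribution (type-I-error fixture)."""
    spec = CohortSpec.null()
    spec = replace(spec, n_t2dm=n_t2dm, n_hc=n_hc)
    return simulate_cohort(spec, seed=seed)
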
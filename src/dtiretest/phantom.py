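"""Synthetic repeated-measures DWI cohorts with known reliability structure.

The phantom emulates a two-group test-retest study: each subject is scanned
twice back-to-back with a single-shell scheme, and the goal is to recover
configured between-subject and within-subject (scan-rescan) variability from
the images.  Regions are axis-aligned boxes in a small grid, each with a
homogeneous ground-truth tensor.  Per subject, each region's eigenvalues are
scaled by a log-normal factor with coefficient of variation
``between_subject_cv``; per scan, by an independent log-normal factor with CV
``within_subject_cv``.  Rician noise of scale ``rician_sigma`` is added to
the magnitude signal.  Because scaling is a positive scalar on all three
eigenvalues, positive-definiteness is preserved by construction, region-mean
MD inherits the configured variance structure exactly, and FA carries no
configured variability (its scan-rescan variance is purely noise-driven).

The disease group ("hd", emulating early Huntington's disease) receives a
deterministic mean shift: diffusivity in every region is scaled up and
white-matter eigenvalues are flattened toward isotropy (lower FA), giving
the larger between-subject spread expected of a patient group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionScheme, write_bvals_bvecs
from .tensor import metrics_from_eigenvalues, tensor_to_vec

__all__ = [
    "RegionSpec",
    "PhantomConfig",
    "SubjectData",
    "GroundTruthCohort",
    "default_regions",
    "default_phantom_config",
    "predict_signal",
    "add_rician_noise",
    "generate_cohort",
    "implied_icc",
    "cv_between_for_icc",
    "simulate_paired_series",
    "simulate_lognormal_paired_means",
]

GROUPS = ("control", "hd")


@dataclass(frozen=True)
class RegionSpec:
    """One homogeneous phantom region.

    ``mean_eigenvalues`` are descending, non-negative diffusivities (mm²/s);
    ``principal_direction`` is the unit direction of the largest eigenvalue.
    ``min_corner``/``max_corner`` bound an axis-aligned box (half-open, voxel
    indices).  ``tissue`` is "wm" or "gm" (the disease-group FA flattening
    applies to "wm" only); ``atlas`` marks regions whose means are computed
    under the template FA threshold downstream.
    """

    label_id: int
    region_name: str
    mean_eigenvalues: tuple[float, float, float]
    principal_direction: tuple[float, float, float]
    min_corner: tuple[int, int, int]
    max_corner: tuple[int, int, int]
    tissue: str = "wm"
    atlas: bool = True

    def __post_init__(self) -> None:
        ev = np.asarray(self.mean_eigenvalues, dtype=float)
        if ev.shape != (3,) or np.any(ev < 0):
            raise ValueError(f"region {self.region_name}: need 3 eigenvalues >= 0")
        if np.any(np.diff(ev) > 0):
            raise ValueError(
                f"region {self.region_name}: eigenvalues must be non-increasing"
            )
        if self.label_id <= 0:
            raise ValueError("label_id must be > 0 (0 is reserved for background)")
        d = np.asarray(self.principal_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError(f"region {self.region_name}: direction must be unit norm")
        if self.tissue not in ("wm", "gm"):
            raise ValueError("tissue must be 'wm' or 'gm'")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.min_corner, self.max_corner))

    def frame(self) -> np.ndarray:
        """Orthonormal eigenvector frame: principal direction plus a
        deterministic completion of the orthogonal complement."""
        e1 = np.asarray(self.principal_direction, dtype=float)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(e1 @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e2 = helper - (helper @ e1) * e1
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        return np.column_stack([e1, e2, e3])

    def tensor(self) -> np.ndarray:
        """Mean tensor R·diag(λ)·Rᵀ in the region's frame."""
        R = self.frame()
        return R @ np.diag(self.mean_eigenvalues) @ R.T


@dataclass(frozen=True)
class PhantomConfig:
    """Full specification of one simulated test-retest cohort."""

    grid_shape: tuple[int, int, int] = (20, 20, 10)
    regions: tuple[RegionSpec, ...] = ()
    n_control: int = 12
    n_hd: int = 10
    between_subject_cv: float = 0.10
    within_subject_cv: float = 0.02
    rician_sigma: float = 1.0
    s0: float = 100.0
    seed: int = 0
    hd_md_scale: float = 1.10
    hd_fa_flatten: float = 0.10

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.n_control < 0 or self.n_hd < 0:
            raise ValueError("group sizes must be non-negative")
        for name, v in (
            ("between_subject_cv", self.between_subject_cv),
            ("within_subject_cv", self.within_subject_cv),
            ("rician_sigma", self.rician_sigma),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        labels = [r.label_id for r in self.regions]
        if len(labels) != len(set(labels)):
            raise ValueError("region label_ids must be unique")

    def to_flat_dict(self) -> dict[str, str]:
        d = {
            "grid_shape": ",".join(map(str, self.grid_shape)),
            "n_control": str(self.n_control),
            "n_hd": str(self.n_hd),
            "between_subject_cv": repr(self.between_subject_cv),
            "within_subject_cv": repr(self.within_subject_cv),
            "rician_sigma": repr(self.rician_sigma),
            "s0": repr(self.s0),
            "seed": str(self.seed),
            "hd_md_scale": repr(self.hd_md_scale),
            "hd_fa_flatten": repr(self.hd_fa_flatten),
        }
        return d


def default_regions() -> tuple[RegionSpec, ...]:
    """Nine non-overlapping box regions in the default 20×20×10 grid.

    White-matter-like regions are anisotropic with distinct principal
    directions; grey-matter-like regions are near-isotropic.  Bilateral
    structures are represented as separate left/right labels.
    """
    e3 = 1e-3
    return (
        RegionSpec(1, "genu_cc", (1.7 * e3, 0.3 * e3, 0.2 * e3), (1, 0, 0),
                   (2, 8, 3), (6, 12, 7), tissue="wm", atlas=True),
        RegionSpec(2, "splenium_cc", (1.8 * e3, 0.25 * e3, 0.2 * e3), (1, 0, 0),
                   (14, 8, 3), (18, 12, 7), tissue="wm", atlas=True),
        RegionSpec(3, "internal_capsule_l", (1.5 * e3, 0.4 * e3, 0.3 * e3), (0, 0, 1),
                   (6, 3, 2), (9, 6, 8), tissue="wm", atlas=True),
        RegionSpec(4, "internal_capsule_r", (1.5 * e3, 0.4 * e3, 0.3 * e3), (0, 0, 1),
                   (6, 14, 2), (9, 17, 8), tissue="wm", atlas=True),
        RegionSpec(5, "cerebral_wm", (1.2 * e3, 0.5 * e3, 0.45 * e3),
                   (0, 1, 0), (10, 2, 2), (14, 6, 8), tissue="wm", atlas=False),
        RegionSpec(6, "caudate_l", (0.80 * e3, 0.78 * e3, 0.76 * e3), (1, 0, 0),
                   (10, 7, 2), (13, 10, 5), tissue="gm", atlas=False),
        RegionSpec(7, "caudate_r", (0.80 * e3, 0.78 * e3, 0.76 * e3), (1, 0, 0),
                   (10, 11, 2), (13, 14, 5), tissue="gm", atlas=False),
        RegionSpec(8, "putamen_l", (0.74 * e3, 0.73 * e3, 0.72 * e3), (1, 0, 0),
                   (15, 2, 2), (18, 5, 6), tissue="gm", atlas=False),
        RegionSpec(9, "putamen_r", (0.74 * e3, 0.73 * e3, 0.72 * e3), (1, 0, 0),
                   (15, 15, 2), (18, 18, 6), tissue="gm", atlas=False),
    )


def default_phantom_config(**overrides) -> PhantomConfig:
    """Desk-scale study defaults: 12 controls + 10 patients, 20×20×10 grid."""
    cfg = PhantomConfig(regions=default_regions())
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# forward signal model and noise


def predict_signal(tensor: np.ndarray, s0: float, scheme: AcquisitionScheme) -> np.ndarray:
    """Stejskal-Tanner signal S_i = s0·exp(−b_i·gᵢᵀ D gᵢ) for one tensor."""
    D = np.asarray(tensor, dtype=float)
    if D.shape != (3, 3):
        raise ValueError(f"tensor must be 3×3, got {D.shape}")
    if not np.allclose(D, D.T, atol=1e-10, rtol=0):
        raise ValueError("tensor must be symmetric")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    quad = np.einsum("ni,ij,nj->n", scheme.bvecs, D, scheme.bvecs)
    return s0 * np.exp(-scheme.bvals * quad)


def add_rician_noise(signal, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MR noise: |(s + n₁) + i·n₂| with n₁, n₂ ~ N(0, σ²).

    σ = 0 is the identity.  At low SNR this positively biases the magnitude
    (a zero signal becomes Rayleigh with mean σ·sqrt(π/2)).
    """
    s = np.asarray(signal, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return s.copy()
    real = s + rng.normal(0.0, sigma, size=s.shape)
    imag = rng.normal(0.0, sigma, size=s.shape)
    return np.hypot(real, imag)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class SubjectData:
    """One simulated subject: truth tensors, two DWI repeats, applied scales."""

    subject_id: str
    group: str
    truth_tensors: np.ndarray  # (X, Y, Z, 6), subject-level truth
    dwi: list  # two (X, Y, Z, n) repeat volumes
    subject_region_scales: dict  # label_id -> between-subject scale factor
    repeat_region_scales: list  # [ {label_id -> total scale}, same for repeat 2 ]


@dataclass
class GroundTruthCohort:
    """A full simulated cohort plus everything needed to audit it."""

    subjects: list
    labels: np.ndarray
    region_names: dict
    scheme: AcquisitionScheme
    config: PhantomConfig
    affine: np.ndarray = field(
        default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0])
    )

    def subject(self, subject_id: str) -> SubjectData:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def truth_manifest(self) -> pd.DataFrame:
        """Per (subject, region): true mean FA/MD/AD/RD at the subject level."""
        rows = []
        by_label = {r.label_id: r for r in self.config.regions}
        for s in self.subjects:
            for label_id, scale in sorted(s.subject_region_scales.items()):
                region = by_label[label_id]
                ev = _group_eigenvalues(region, s.group, self.config) * scale
                m = metrics_from_eigenvalues(ev)
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "region": region.region_name,
                        "true_FA": float(m["FA"]),
                        "true_MD": float(m["MD"]),
                        "true_AD": float(m["AD"]),
                        "true_RD": float(m["RD"]),
                    }
                )
        return pd.DataFrame(rows)

    def to_directory(self, path) -> None:
        """Write the cohort in portable formats: NIfTI-1, FSL bval/bvec, TSV."""
        import nibabel as nib

        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        write_bvals_bvecs(self.scheme, out / "bvals", out / "bvecs")
        nib.save(
            nib.Nifti1Image(self.labels.astype(np.int16), self.affine),
            out / "labels.nii.gz",
        )
        pd.DataFrame(
            sorted(self.region_names.items()), columns=["label_id", "region_name"]
        ).to_csv(out / "labels.tsv", sep="\t", index=False)
        self.truth_manifest().to_csv(
            out / "truth.tsv", sep="\t", index=False, float_format="%.12g"
        )
        lines = [f"{k} = {v}" for k, v in self.config.to_flat_dict().items()]
        (out / "config.txt").write_text("\n".join(lines) + "\n")
        for s in self.subjects:
            for rep, vol in enumerate(s.dwi, start=1):
                nib.save(
                    nib.Nifti1Image(vol.astype(np.float32), self.affine),
                    out / f"{s.subject_id}_rep{rep}_dwi.nii.gz",
                )


def _lognormal_scale(cv: float, rng: np.random.Generator, size=None):
    """Log-normal factor with mean exactly 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def _group_eigenvalues(
    region: RegionSpec, group: str, config: PhantomConfig
) -> np.ndarray:
    """Region mean eigenvalues after the deterministic disease-group shift."""
    ev = np.asarray(region.mean_eigenvalues, dtype=float)
    if group == "hd":
        if region.tissue == "wm" and config.hd_fa_flatten > 0:
            ev = ev + config.hd_fa_flatten * (ev.mean() - ev)
        ev = ev * config.hd_md_scale
    return ev


def _region_tensor(region: RegionSpec, eigenvalues: np.ndarray) -> np.ndarray:
    # (possibly shifted/scaled) eigenvalues placed in the region's frame
    R = region.frame()
    return R @ np.diag(eigenvalues) @ R.T


def _subject_rng(seed: int, subject_index: int, repeat: int) -> np.random.Generator:
    # substream per (seed, subject, repeat): adding subjects never changes
    # existing ones, and the two repeats are independent
    return np.random.default_rng([seed & 0x7FFFFFFF, subject_index, repeat])


def generate_cohort(
    config: PhantomConfig, scheme: AcquisitionScheme
) -> GroundTruthCohort:
    """Simulate the full two-repeat cohort described by ``config``.

    Per subject, one between-subject scale per region; per repeat, one
    independent within-subject scale per region; Rician noise per voxel and
    volume.  Fully reproducible from ``config.seed``.
    """
    if not config.regions:
        raise ValueError("region_spec is empty: the phantom needs at least one region")
    grid = tuple(config.grid_shape)
    labels = np.zeros(grid, dtype=np.int16)
    for region in config.regions:
        lo, hi = region.min_corner, region.max_corner
        if any(l < 0 or h > g or l >= h for l, h, g in zip(lo, hi, grid)):
            raise ValueError(
                f"region {region.region_name} does not fit in grid {grid}"
            )
        sl = region.slices()
        if np.any(labels[sl] != 0):
            raise ValueError(f"region {region.region_name} overlaps another region")
        labels[sl] = region.label_id

    subjects = []
    subject_ids = [(f"control_{i+1:02d}", "control") for i in range(config.n_control)]
    subject_ids += [(f"hd_{i+1:02d}", "hd") for i in range(config.n_hd)]

    n_meas = len(scheme)
    for si, (sid, group) in enumerate(subject_ids):
        rng_sub = _subject_rng(config.seed, si, 0)
        subj_scales = {
            r.label_id: float(_lognormal_scale(config.between_subject_cv, rng_sub))
            for r in config.regions
        }
        truth = np.zeros(grid + (6,))
        group_ev = {r.label_id: _group_eigenvalues(r, group, config) for r in config.regions}
        for r in config.regions:
            D = _region_tensor(r, group_ev[r.label_id] * subj_scales[r.label_id])
            truth[r.slices()] = tensor_to_vec(D)

        dwi = []
        repeat_scales = []
        for rep in (1, 2):
            rng_rep = _subject_rng(config.seed, si, rep)
            total = {}
            vol = np.zeros(grid + (n_meas,))
            for r in config.regions:
                scan_scale = float(_lognormal_scale(config.within_subject_cv, rng_rep))
                total[r.label_id] = subj_scales[r.label_id] * scan_scale
                D = _region_tensor(r, group_ev[r.label_id] * total[r.label_id])
                vol[r.slices()] = predict_signal(D, config.s0, scheme)
            vol = add_rician_noise(vol, config.rician_sigma, rng_rep)
            dwi.append(vol)
            repeat_scales.append(total)
        subjects.append(
            SubjectData(
                subject_id=sid,
                group=group,
                truth_tensors=truth,
                dwi=dwi,
                subject_region_scales=subj_scales,
                repeat_region_scales=repeat_scales,
            )
        )

    region_names = {r.label_id: r.region_name for r in config.regions}
    return GroundTruthCohort(
        subjects=subjects,
        labels=labels,
        region_names=region_names,
        scheme=scheme,
        config=config,
    )


# ---------------------------------------------------------------------------
# measurement-level simulators (region-mean statistical model, no images)


def implied_icc(between_cv: float, within_cv: float) -> float:
    """True raw-scale ICC of the multiplicative (log-normal) variance model.

    With x_ij = m·b_i·w_ij, E[b]=E[w]=1, the between-subject variance is
    m²·cv_b² and the expected within-subject variance m²·(1+cv_b²)·cv_w²,
    hence ICC = cv_b² / (cv_b² + (1+cv_b²)·cv_w²).
    """
    b2, w2 = between_cv**2, within_cv**2
    denom = b2 + (1.0 + b2) * w2
    if denom == 0:
        return float("nan")
    return b2 / denom


def cv_between_for_icc(target_icc: float, within_cv: float) -> float:
    """Between-subject CV giving exactly ``target_icc`` under the log-normal model."""
    if not 0 < target_icc < 1:
        raise ValueError("target_icc must be in (0, 1)")
    w2 = within_cv**2
    denom = 1.0 - target_icc * (1.0 + w2)
    if denom <= 0:
        raise ValueError("target_icc unreachable with this within_cv")
    return float(np.sqrt(target_icc * w2 / denom))


def simulate_paired_series(
    n: int,
    var_between: float,
    var_within: float,
    mean: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian one-way random-effects paired data: x_ij = μ + b_i + e_ij, (n, 2)."""
    rng = np.random.default_rng() if rng is None else rng
    b = rng.normal(0.0, np.sqrt(var_between), size=(n, 1))
    e = rng.normal(0.0, np.sqrt(var_within), size=(n, 2))
    return mean + b + e


def simulate_lognormal_paired_means(
    n: int,
    between_cv: float,
    within_cv: float,
    mean: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Paired region-mean values under the image simulator's scaling model.

    Statistically identical to the region-mean MD produced by
    :func:`generate_cohort` with ``rician_sigma = 0``, without forming images.
    """
    rng = np.random.default_rng() if rng is None else rng
    b = _lognormal_scale(between_cv, rng, size=(n, 1))
    w = _lognormal_scale(within_cv, rng, size=(n, 2))
    return mean * b * w
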
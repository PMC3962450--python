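"""Diffusion tensor estimation and scalar metric derivation.

The signal model is the mono-exponential Stejskal-Tanner equation

    S_i = S0 · exp(-b_i · gᵢᵀ D gᵢ)

with D a symmetric 3×3 diffusion tensor (mm²/s).  Per voxel, a log-linear
ordinary-least-squares fit initializes a nonlinear least-squares refinement
(Levenberg–Marquardt on the 6 tensor components and S0 jointly).  The four
scalar metrics analysed downstream are derived from the tensor eigenvalues
λ1 ≥ λ2 ≥ λ3:

    MD = (λ1+λ2+λ3)/3        mean diffusivity
    AD = λ1                  axial diffusivity
    RD = (λ2+λ3)/2           radial diffusivity
    FA = sqrt(3/2)·sqrt(Σ(λᵢ-MD)²)/sqrt(Σλᵢ²)   fractional anisotropy in [0, 1]

Negative eigenvalues (possible in noisy fits) are clamped to zero for metric
derivation only; the unclamped fit is retained in the tensor field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .acquisition import AcquisitionScheme

__all__ = [
    "TENSOR_COMPONENTS",
    "METRICS",
    "TensorFit",
    "EigenSystem",
    "ScalarMap",
    "VolumeFit",
    "tensor_to_vec",
    "vec_to_tensor",
    "fit_loglinear",
    "fit_nlls",
    "eigensystem",
    "scalar_metrics",
    "metrics_from_eigenvalues",
    "default_mask",
    "fit_volume",
]

logger = logging.getLogger(__name__)

#: component order used everywhere a tensor is stored as a 6-vector
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")
METRICS = ("FA", "MD", "AD", "RD")
METRIC_UNITS = {"FA": "1", "MD": "mm^2/s", "AD": "mm^2/s", "RD": "mm^2/s"}

_VEC_IDX = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def tensor_to_vec(tensor: np.ndarray) -> np.ndarray:
    """Symmetric 3×3 → 6-vector (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)."""
    t = np.asarray(tensor, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) tensor, got {t.shape}")
    if not np.allclose(t, np.swapaxes(t, -1, -2), atol=1e-10, rtol=0):
        raise ValueError("tensor must be symmetric")
    return np.stack([t[..., i, j] for i, j in _VEC_IDX], axis=-1)


def vec_to_tensor(vec: np.ndarray) -> np.ndarray:
    """6-vector (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) → symmetric 3×3."""
    v = np.asarray(vec, dtype=float)
    if v.shape[-1] != 6:
        raise ValueError(f"expected (..., 6) component vector, got {v.shape}")
    out = np.empty(v.shape[:-1] + (3, 3), dtype=float)
    for k, (i, j) in enumerate(_VEC_IDX):
        out[..., i, j] = v[..., k]
        out[..., j, i] = v[..., k]
    return out


@dataclass
class TensorFit:
    """One voxel's fitted tensor: 6 components (mm²/s), S0, and fit diagnostics."""

    d_components: np.ndarray
    s0_est: float
    residual_sse: float
    converged: bool
    n_iter: int

    def tensor(self) -> np.ndarray:
        return vec_to_tensor(self.d_components)


@dataclass
class EigenSystem:
    """Sorted eigendecomposition of a diffusion tensor.

    ``eigenvalues`` are descending (λ1 ≥ λ2 ≥ λ3, mm²/s); ``eigenvectors``
    holds the matching unit vectors as columns.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class ScalarMap:
    """A 3D volume of one derived metric, tagged with its name and units."""

    data: np.ndarray
    metric: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}, expected one of {METRICS}")
        if not self.units:
            self.units = METRIC_UNITS[self.metric]


class ScalarMetrics(NamedTuple):
    fa: float
    md: float
    ad: float
    rd: float


def _as_signal_vector(signals, scheme: AcquisitionScheme) -> np.ndarray:
    s = np.atleast_1d(np.asarray(signals, dtype=float))
    if s.ndim != 1 or len(s) != len(scheme):
        raise ValueError(
            f"signal vector length {s.shape} does not match scheme length {len(scheme)}"
        )
    if not np.all(np.isfinite(s)):
        raise ValueError("signals contain non-finite values")
    return s


def _floor_signals(signals: np.ndarray, b0_mask: np.ndarray) -> np.ndarray:
    """Floor non-positive signals so the log transform is defined.

    Magnitude data can hit zero under noise; the floor is 1e-6 of the b0-mean
    S0 estimate (or an absolute 1e-12 if even the b0 mean is non-positive).
    """
    s0_guess = signals[..., b0_mask].mean(axis=-1, keepdims=True)
    eps = np.where(s0_guess > 0, 1e-6 * s0_guess, 1e-12)
    return np.maximum(signals, eps)


def fit_loglinear(signals, scheme: AcquisitionScheme) -> TensorFit:
    """Ordinary least squares of ln(S) on the tensor design matrix.

    Requires >= 7 measurements including at least one b=0.  The reported
    ``residual_sse`` is evaluated under the *nonlinear* signal model so it is
    directly comparable with :func:`fit_nlls`.
    """
    s = _as_signal_vector(signals, scheme)
    if len(s) < 7:
        raise ValueError(f"need >= 7 measurements to fit a tensor, got {len(s)}")
    if not np.any(scheme.b0_mask):
        raise ValueError("need at least one b=0 measurement")
    X = scheme.design_matrix()
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("degenerate gradient direction set: design matrix rank < 7")
    sf = _floor_signals(s, scheme.b0_mask)
    beta, *_ = np.linalg.lstsq(X, np.log(sf), rcond=None)
    d = beta[1:]
    s0 = float(np.exp(beta[0]))
    sse = _nlls_sse(s[None, :], np.concatenate([[s0], d])[None, :], X[:, 1:])[0]
    return TensorFit(
        d_components=d, s0_est=s0, residual_sse=float(sse), converged=True, n_iter=0
    )


def _nlls_model(params: np.ndarray, design_dw: np.ndarray) -> np.ndarray:
    """params (V, 7) = [S0, D6] → model signals (V, n)."""
    return params[:, :1] * np.exp(params[:, 1:] @ design_dw.T)


def _nlls_sse(signals: np.ndarray, params: np.ndarray, design_dw: np.ndarray) -> np.ndarray:
    r = signals - _nlls_model(params, design_dw)
    return np.einsum("vn,vn->v", r, r)


def _lm_fit_batch(
    signals: np.ndarray,
    design_dw: np.ndarray,
    init_params: np.ndarray,
    gtol: float = 1e-10,
    xtol: float = 1e-12,
    max_iter: int = 200,
):
    """Batched Levenberg–Marquardt over voxels.

    Minimizes Σ (S_i − S0·exp(q_i))², q = design_dw @ D6, jointly over
    (S0, D6) per voxel.  Only strictly improving steps are accepted, so the
    returned objective never exceeds the initializer's.

    Returns (params (V,7), sse (V,), converged (V,), n_iter (V,)).
    """
    V = signals.shape[0]
    p = np.array(init_params, dtype=float)
    sse = _nlls_sse(signals, p, design_dw)
    lam = np.full(V, 1e-3)
    converged = np.zeros(V, dtype=bool)
    n_iter = np.zeros(V, dtype=int)
    eye = np.eye(7)

    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        pa = p[active]
        sa = signals[active]
        model = _nlls_model(pa, design_dw)
        r = sa - model
        # Jacobian of the model wrt (S0, D6): (Va, n, 7)
        J = np.empty(pa.shape[:1] + (design_dw.shape[0], 7))
        with np.errstate(divide="ignore", invalid="ignore"):
            J[:, :, 0] = np.where(pa[:, :1] != 0, model / pa[:, :1], 1.0)
        J[:, :, 1:] = model[:, :, None] * design_dw[None, :, :]
        g = np.einsum("vnp,vn->vp", J, r)
        sse_a = sse[active]
        grad_ok = np.abs(g).max(axis=1) <= gtol * (1.0 + sse_a)
        JTJ = np.einsum("vnp,vnq->vpq", J, J)
        diag = np.einsum("vpp->vp", JTJ)
        damped = JTJ + lam[active, None, None] * (
            diag[:, :, None] * eye[None] + 1e-12 * eye[None]
        )
        try:
            delta = np.linalg.solve(damped, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.stack(
                [np.linalg.lstsq(A, rhs, rcond=None)[0] for A, rhs in zip(damped, g)]
            )
        trial = pa + delta
        valid = (trial[:, 0] > 0) & np.all(np.isfinite(trial), axis=1)
        trial_sse = np.full_like(sse_a, np.inf)
        if valid.any():
            trial_sse[valid] = _nlls_sse(sa[valid], trial[valid], design_dw)
        improve = trial_sse < sse_a

        new_p = np.where(improve[:, None], trial, pa)
        new_sse = np.where(improve, trial_sse, sse_a)
        step_small = improve & (
            (sse_a - trial_sse) <= xtol * (sse_a + 1e-300)
        )
        rel_step = np.abs(delta).max(axis=1) / (1.0 + np.abs(pa).max(axis=1))
        step_small |= improve & (rel_step <= xtol)

        idx = np.flatnonzero(active)
        p[idx] = new_p
        sse[idx] = new_sse
        lam[idx] = np.where(improve, lam[idx] * 0.3, np.minimum(lam[idx] * 10.0, 1e12))
        n_iter[idx] += 1
        # stalled: no improving step even at maximal damping -> local minimum
        stalled = ~improve & (lam[idx] >= 1e12)
        converged[idx] = grad_ok | step_small | stalled
    return p, sse, converged, n_iter


def fit_nlls(
    signals,
    scheme: AcquisitionScheme,
    init: TensorFit | None = None,
    gtol: float = 1e-10,
    max_iter: int = 200,
) -> TensorFit:
    """Nonlinear least-squares tensor fit (Levenberg–Marquardt, joint S0).

    Starts from ``init`` (default: the log-linear fit) and only accepts
    improving steps, so the returned objective never exceeds the
    initializer's under the same nonlinear model.  On non-convergence the
    best iterate is returned with ``converged=False``; this never raises.
    """
    s = _as_signal_vector(signals, scheme)
    if np.any(s < 0):
        raise ValueError("signals must be non-negative")
    if init is None:
        init = fit_loglinear(s, scheme)
    p0 = np.concatenate([[init.s0_est], np.asarray(init.d_components, dtype=float)])
    if not np.all(np.isfinite(p0)) or p0[0] <= 0:
        raise ValueError("initializer has non-finite components or non-positive S0")
    design_dw = scheme.design_matrix()[:, 1:]
    p, sse, conv, n_iter = _lm_fit_batch(
        s[None, :], design_dw, p0[None, :], gtol=gtol, max_iter=max_iter
    )
    return TensorFit(
        d_components=p[0, 1:],
        s0_est=float(p[0, 0]),
        residual_sse=float(sse[0]),
        converged=bool(conv[0]),
        n_iter=int(n_iter[0]),
    )


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first nonzero component >= 0 (per column)."""
    out = vecs.copy()
    for j in range(out.shape[-1]):
        col = out[..., :, j]
        nz = np.abs(col) > 1e-12
        first = np.argmax(nz, axis=-1)
        sign = np.take_along_axis(col, first[..., None], axis=-1)[..., 0]
        flip = sign < 0
        out[..., :, j] = np.where(flip[..., None], -col, col)
    return out


def eigensystem(fit) -> EigenSystem:
    """Symmetric eigendecomposition, eigenvalues sorted descending.

    Accepts a :class:`TensorFit`, a 6-component vector, or a 3×3 matrix.
    Negative eigenvalues are passed through unchanged; clamping is applied
    only at metric derivation.
    """
    if isinstance(fit, TensorFit):
        D = fit.tensor()
    else:
        arr = np.asarray(fit, dtype=float)
        D = vec_to_tensor(arr) if arr.shape == (6,) else arr
    if D.shape != (3, 3):
        raise ValueError(f"expected a 3×3 tensor, got {D.shape}")
    if not np.all(np.isfinite(D)):
        raise ValueError("tensor has non-finite components")
    vals, vecs = np.linalg.eigh(D)
    order = np.argsort(vals, kind="stable")[::-1]
    vals = vals[order]
    vecs = _fix_eigenvector_signs(vecs[:, order])
    return EigenSystem(eigenvalues=vals, eigenvectors=vecs)


def metrics_from_eigenvalues(evals: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized FA/MD/AD/RD from descending eigenvalues (..., 3).

    Negative eigenvalues are clamped to 0 here (metric derivation only),
    keeping FA in [0, 1] and diffusivities non-negative.  FA of the all-zero
    tensor is defined as 0.
    """
    ev = np.maximum(np.asarray(evals, dtype=float), 0.0)
    md = ev.mean(axis=-1)
    ad = ev[..., 0]
    rd = 0.5 * (ev[..., 1] + ev[..., 2])
    num = np.sqrt(((ev - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    return {"FA": fa, "MD": md, "AD": ad, "RD": rd}


def scalar_metrics(eig) -> ScalarMetrics:
    """(FA, MD, AD, RD) for one voxel from an :class:`EigenSystem` or eigenvalues."""
    evals = eig.eigenvalues if isinstance(eig, EigenSystem) else np.asarray(eig, float)
    if evals.shape != (3,):
        raise ValueError("expected exactly 3 eigenvalues")
    if np.any(np.diff(evals) > 1e-15):
        raise ValueError("eigenvalues must be sorted descending")
    m = metrics_from_eigenvalues(evals)
    return ScalarMetrics(
        fa=float(m["FA"]), md=float(m["MD"]), ad=float(m["AD"]), rd=float(m["RD"])
    )


def default_mask(dwi: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Foreground mask: mean b0 signal above 10% of its 99th percentile."""
    mean_b0 = np.asarray(dwi, dtype=float)[..., scheme.b0_mask].mean(axis=-1)
    thr = 0.10 * np.percentile(mean_b0, 99)
    return mean_b0 > thr


@dataclass
class VolumeFit:
    """Per-volume fit results: scalar maps, tensor field, S0, diagnostics."""

    maps: dict[str, ScalarMap]
    tensors: np.ndarray  # (X, Y, Z, 6), component order TENSOR_COMPONENTS
    s0: np.ndarray
    mask: np.ndarray
    n_nonconverged: int
    n_iter: np.ndarray = field(repr=False, default=None)


def fit_volume(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    chunk_size: int = 20000,
) -> VolumeFit:
    """Fit every masked voxel (log-linear init → NLLS) and derive scalar maps.

    Unmasked voxels are zero in every output.  The count of voxels whose
    NLLS did not converge within the iteration budget is logged and reported.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError(f"expected 4D DWI volume, got shape {dwi.shape}")
    if dwi.shape[-1] != len(scheme):
        raise ValueError(
            f"DWI has {dwi.shape[-1]} volumes but scheme has {len(scheme)}"
        )
    grid = dwi.shape[:3]
    if mask is None:
        mask = default_mask(dwi, scheme)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid}")

    X = scheme.design_matrix()
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("degenerate gradient direction set: design matrix rank < 7")
    design_dw = X[:, 1:]
    pinv = np.linalg.pinv(X)

    S = dwi[mask]  # (V, n)
    V = S.shape[0]
    params = np.zeros((V, 7))
    sse = np.zeros(V)
    conv = np.ones(V, dtype=bool)
    n_iter = np.zeros(V, dtype=int)
    for lo in range(0, V, chunk_size):
        sl = slice(lo, min(lo + chunk_size, V))
        Sc = S[sl]
        Sf = _floor_signals(Sc, scheme.b0_mask)
        beta = (pinv @ np.log(Sf).T).T
        p0 = np.column_stack([np.exp(beta[:, 0]), beta[:, 1:]])
        p, e, c, it = _lm_fit_batch(Sc, design_dw, p0)
        params[sl], sse[sl], conv[sl], n_iter[sl] = p, e, c, it

    tensors = np.zeros(grid + (6,))
    tensors[mask] = params[:, 1:]
    s0 = np.zeros(grid)
    s0[mask] = params[:, 0]

    D = vec_to_tensor(params[:, 1:])
    evals = np.linalg.eigvalsh(D)[..., ::-1]  # descending
    metric_vals = metrics_from_eigenvalues(evals)
    maps = {}
    for name in METRICS:
        vol = np.zeros(grid)
        vol[mask] = metric_vals[name]
        maps[name] = ScalarMap(data=vol, metric=name)

    n_bad = int((~conv).sum())
    if n_bad:
        logger.info("fit_volume: %d of %d voxels did not converge", n_bad, V)
    iter_map = np.zeros(grid, dtype=int)
    iter_map[mask] = n_iter
    return VolumeFit(
        maps=maps,
        tensors=tensors,
        s0=s0,
        mask=mask,
        n_nonconverged=n_bad,
        n_iter=iter_map,
    )
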
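"""Diffusion acquisition schemes and FSL-dialect gradient-table I/O.

An acquisition scheme is the list of b-values (s/mm²) and unit gradient
directions of one DWI series.  The default scheme mirrors a clinical
single-shell protocol: a block of b=0 volumes followed by diffusion-weighted
volumes at one shell, with directions spread quasi-uniformly over the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "default_scheme",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values and unit gradient directions of one DWI acquisition.

    Parameters
    ----------
    bvals : (n,) array
        Diffusion weightings in s/mm², all >= 0.
    bvecs : (n, 3) array
        Gradient directions; unit norm wherever ``bval > 0``, the zero
        vector is allowed (and conventional) for b=0 entries.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise ValueError(
                f"bvals ({len(bvals)}) and bvecs ({len(bvecs)}) differ in length"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > 0
        if np.any(np.abs(norms[dw] - 1.0) > _UNIT_TOL):
            raise ValueError("gradient directions must be unit norm where b > 0")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    def design_matrix(self) -> np.ndarray:
        """Log-linear design matrix, one row per measurement.

        Columns: [1, -b·gx², -2b·gx·gy, -2b·gx·gz, -b·gy², -2b·gy·gz, -b·gz²]
        so that ``X @ [ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz] = ln S``.
        """
        b = self.bvals
        gx, gy, gz = self.bvecs.T
        return np.column_stack(
            [
                np.ones_like(b),
                -b * gx * gx,
                -2.0 * b * gx * gy,
                -2.0 * b * gx * gz,
                -b * gy * gy,
                -2.0 * b * gy * gz,
                -b * gz * gz,
            ]
        )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic quasi-uniform unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def default_scheme(
    n_directions: int = 42, n_b0: int = 7, b: float = 1000.0
) -> AcquisitionScheme:
    """Single-shell scheme: ``n_b0`` b=0 volumes then ``n_directions`` at shell ``b``.

    Directions are placed on a spherical Fibonacci lattice, which is
    deterministic and close to an electrostatic-repulsion layout.  At least
    6 directions are required for the diffusion tensor to be identifiable.
    """
    if n_directions < 6:
        raise ValueError(
            f"need >= 6 gradient directions to identify a tensor, got {n_directions}"
        )
    if n_b0 < 1:
        raise ValueError("need at least one b=0 volume")
    if b <= 0:
        raise ValueError("shell b-value must be positive")
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), _fibonacci_sphere(n_directions)])
    return AcquisitionScheme(bvals, bvecs)


def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write FSL-dialect gradient tables: one row of b-values, three rows (x, y, z)."""
    Path(bval_path).write_text(
        " ".join(format(v, ".6g") for v in scheme.bvals) + "\n"
    )
    rows = [
        " ".join(format(v, ".10g") for v in scheme.bvecs[:, axis])
        for axis in range(3)
    ]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def read_bvals_bvecs(bval_path, bvec_path) -> AcquisitionScheme:
    """Read FSL-dialect bval/bvec text files into an :class:`AcquisitionScheme`."""
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention stores components in rows
        bvecs = bvecs.T
    return AcquisitionScheme(bvals, bvecs)
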
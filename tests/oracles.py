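"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: sums of squares are
accumulated in explicit Python loops, and tensors/metrics are evaluated
directly from their defining formulas.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_anova(table) -> tuple[float, float]:
    """One-way random-effects variance components from first principles.

    Explicit loops over an n×k table: MSW from within-row deviations, MSB
    from row means, σ̂²_b = max(0, (MSB − MSW)/k), σ̂²_w = MSW.
    """
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    row_means = [sum(row) / k for row in x]
    grand = sum(sum(row) for row in x) / (n * k)
    ssw = 0.0
    for i in range(n):
        for j in range(k):
            ssw += (x[i, j] - row_means[i]) ** 2
    msw = ssw / (n * (k - 1))
    ssb = 0.0
    for i in range(n):
        ssb += (row_means[i] - grand) ** 2
    msb = k * ssb / (n - 1)
    return max(0.0, (msb - msw) / k), msw


def metrics_by_formula(lambdas) -> dict[str, float]:
    """FA/MD/AD/RD from the defining formulas, plain Python arithmetic."""
    l1, l2, l3 = (max(v, 0.0) for v in lambdas)
    md = (l1 + l2 + l3) / 3.0
    sq = l1 * l1 + l2 * l2 + l3 * l3
    if sq == 0.0:
        fa = 0.0
    else:
        fa = math.sqrt(1.5) * math.sqrt(
            (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
        ) / math.sqrt(sq)
    return {"FA": fa, "MD": md, "AD": l1, "RD": (l2 + l3) / 2.0}


def random_pd_tensor(rng: np.random.Generator) -> np.ndarray:
    """Random positive-definite tensor with physiological-scale eigenvalues."""
    evals = rng.uniform(0.1e-3, 2.5e-3, size=3)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    return Q @ np.diag(evals) @ Q.T


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
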
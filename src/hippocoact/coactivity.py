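"""Peer-controlled pairwise coactivity graphs and signed weighted metrics.

For every ordered cell pair (i, j) the coactivity weight is the
regression coefficient beta_ij of the peer-controlled model

    x_j ~ beta_ij * x_i + alpha_ij * P

where x are z-scored event-nested spike-count series (one value per
50 ms event window, or per theta cycle in waking) and P is the summed
activity of the other N-2 units.  Because all inputs are z-scored, the
model is fit as Gaussian identity-link least squares.  Weights are
collected into an adjacency matrix, symmetrized to (A + A^T)/2 with a
zero diagonal, and summarized by the Onnela signed weighted clustering
coefficient and the per-node mean coactivity strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .popvec import PopulationVectorMatrix


@dataclass
class CoactivityMatrix:
    """Symmetric N x N beta-weight graph with zero diagonal."""

    A: np.ndarray
    unit_ids: list[int]
    condition: str = ""
    dropped_units: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("A must be symmetric")
        if not np.allclose(np.diag(self.A), 0.0):
            raise ValueError("A must have zero diagonal")
        if len(self.unit_ids) != n:
            raise ValueError("unit_ids length must match A")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def edge_list(self):
        import pandas as pd

        rows = [
            (self.unit_ids[i], self.unit_ids[j], self.A[i, j])
            for i in range(self.n)
            for j in range(i + 1, self.n)
        ]
        return pd.DataFrame(rows, columns=["i", "j", "beta"])


def _zscore_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row; returns (z, keep mask for non-constant rows)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    z = np.zeros_like(x, dtype=float)
    z[keep] = (x[keep] - mu[keep]) / sd[keep]
    return z, keep


def pair_coactivity_glm(
    mat: PopulationVectorMatrix | np.ndarray,
    unit_ids: list[int] | None = None,
    condition: str = "",
) -> CoactivityMatrix:
    """Peer-controlled pairwise coactivity from event-nested counts.

    Accepts a :class:`PopulationVectorMatrix` or a raw units x events
    array.  Constant (zero-variance) units are dropped with a warning and
    reported on the result.  Requires N >= 3 units after dropping and
    more events than the 2 regressors + intercept.
    """
    if isinstance(mat, PopulationVectorMatrix):
        counts = mat.counts.astype(float)
        if unit_ids is None:
            unit_ids = list(mat.unit_ids)
    else:
        counts = np.asarray(mat, float)
        if unit_ids is None:
            unit_ids = list(range(counts.shape[0]))
    z, keep = _zscore_rows(counts)
    dropped = [u for u, k in zip(unit_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant units from coactivity fit")
    z = z[keep]
    kept_ids = [u for u, k in zip(unit_ids, keep) if k]
    n, m = z.shape
    if n - 2 < 1:
        raise ValueError("need at least 3 non-constant units")
    if m <= 3:
        raise ValueError("need more events than regressors")

    total = z.sum(axis=0)
    beta = np.zeros((n, n))
    for i in range(n):
        xi = z[i]
        for j in range(n):
            if i == j:
                continue
            peers = total - z[i] - z[j]  # summed activity of the other N-2 units
            design = np.column_stack([xi, peers])
            coef, *_ = np.linalg.lstsq(design, z[j], rcond=None)
            beta[i, j] = coef[0]
    A = (beta + beta.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return CoactivityMatrix(A, kept_ids, condition, dropped)


def clustering_coefficient(cmat: CoactivityMatrix) -> np.ndarray:
    """Onnela signed weighted clustering coefficient per node.

    Weights are normalized by the maximum *signed* weight (as defined;
    normalized magnitudes can exceed 1 when negative weights dominate).
    C_i sums the signed cube root of the triple product over all ordered
    neighbor pairs (j, q), divided by k_i (k_i - 1) with k_i = N - 1, so
    a triangle of maximal positive weights gives C_i = 1 and a triad with
    an odd number of negative edges contributes negatively.
    """
    n = cmat.n
    if n < 3:
        raise ValueError("clustering coefficient needs N >= 3")
    wmax = cmat.A.max()
    if wmax <= 0:
        raise ValueError("degenerate normalization: maximum weight is not positive")
    w = cmat.A / wmax
    # signed real cube roots preserve triad sign parity
    cw = np.cbrt(w)
    k = n - 1
    c = np.empty(n)
    for i in range(n):
        # ordered-pair sum over (j, q), j != q, both != i
        m = cw[i][:, None] * cw[i][None, :] * cw
        m[i, :] = 0.0
        m[:, i] = 0.0
        np.fill_diagonal(m, 0.0)
        c[i] = m.sum() / (k * (k - 1))
    return c


def node_strength(cmat: CoactivityMatrix) -> np.ndarray:
    """Mean coactivity strength per node: off-diagonal row mean of A."""
    if cmat.n < 2:
        raise ValueError("strength needs N >= 2")
    return cmat.A.sum(axis=1) / (cmat.n - 1)
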
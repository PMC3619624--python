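"""Factor Analysis of Dynamic Structures (FADS).

Decorrelates the pixel time-activity curves of a gated study by
eigenanalysis of their temporal autocorrelation. With ``X_m`` the
``P x K`` TAC matrix after per-pixel temporal centering, the temporal
autocorrelation ``C = X_m' X_m / P`` is eigendecomposed as
``C = V diag(lambda) V'`` and the per-pixel factor coordinates are

    F = X_m V D,

with ``D`` a diagonal rescaling of the eigenvalues. The default
``D = diag(lambda)^(-1/2)`` whitens the factor coordinates (unit second
moment per retained factor), which makes the per-subject point clouds
dimensionless and comparable across subjects — the property the pooled
density model downstream relies on. The eigenvalue magnitudes measure
each temporal factor's share of the total variance; in gated cardiac
series the three largest factors carry the bulk of it.

Eigenvector signs are arbitrary; they are fixed deterministically by
orienting each eigenvector along the mean centered ventricular TAC
(falling back to making the largest-magnitude element positive), so that
pooled factor clouds from different subjects share one orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import TacMatrix

__all__ = [
    "FactorDecomposition",
    "FadsError",
    "center_tacs",
    "temporal_autocorrelation",
    "decompose",
    "variance_explained",
    "extract_3msf",
]

#: eigenvalues below this fraction of the largest are treated as zero
_ZERO_EIG_REL = 1e-12

_SCALINGS = ("inv_sqrt", "sqrt", "none")


class FadsError(ValueError):
    """Invalid input to the factor decomposition."""


@dataclass
class FactorDecomposition:
    """Result of the temporal eigendecomposition of a TAC matrix.

    ``eigenvalues`` are sorted descending and clamped at zero;
    ``eigenvectors`` holds the temporal patterns as orthonormal columns;
    ``scaling`` is the diagonal of ``D``; ``factors`` is the ``P x K``
    coordinate matrix ``F``; ``removed_means`` records the per-pixel
    temporal means subtracted before the decomposition.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scaling: np.ndarray
    factors: np.ndarray
    variance_fraction: np.ndarray
    removed_means: np.ndarray
    scaling_mode: str = "inv_sqrt"

    @property
    def frames(self) -> int:
        return self.eigenvalues.size

    @property
    def n_pixels(self) -> int:
        return self.factors.shape[0]


def center_tacs(tac: TacMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove each pixel's temporal mean; returns ``(X_m, removed_means)``."""
    values = tac.values if isinstance(tac, TacMatrix) else np.atleast_2d(
        np.asarray(tac, dtype=float))
    if values.shape[0] < 1 or values.shape[1] < 2:
        raise FadsError("need at least 1 pixel and 2 frames")
    means = values.mean(axis=1)
    return values - means[:, None], means


def temporal_autocorrelation(x_m: np.ndarray) -> np.ndarray:
    """``K x K`` temporal autocorrelation ``X_m' X_m / P`` (symmetric PSD).

    The ``1/P`` normalization keeps the eigenvalue scale independent of the
    number of selected pixels, so results do not depend on ventricle size.
    """
    x_m = np.atleast_2d(np.asarray(x_m, dtype=float))
    p = x_m.shape[0]
    c = x_m.T @ x_m / p
    return 0.5 * (c + c.T)


def _fix_signs(vectors: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector orientation.

    Each column is flipped so its inner product with ``reference`` (the mean
    centered ventricular TAC) is non-negative; when that inner product is
    numerically zero the largest-magnitude element is made positive instead.
    """
    out = vectors.copy()
    for c in range(out.shape[1]):
        dot = float(reference @ out[:, c])
        if abs(dot) >= 1e-12:
            if dot < 0:
                out[:, c] = -out[:, c]
        else:
            lead = np.argmax(np.abs(out[:, c]))
            if out[lead, c] < 0:
                out[:, c] = -out[:, c]
    return out


def decompose(tac: TacMatrix | np.ndarray,
              scaling: str = "inv_sqrt") -> FactorDecomposition:
    """Full FADS decomposition ``F = X_m V D`` of a TAC matrix.

    ``scaling`` selects the diagonal ``D``: ``inv_sqrt`` (default,
    whitening), ``sqrt`` or ``none``. Zero eigenvalues always map to zero
    factor columns. A constant (all-zero after centering) input yields a
    valid all-zero decomposition with a warning rather than an error.
    """
    if scaling not in _SCALINGS:
        raise FadsError(f"unknown factor scaling {scaling!r}")
    x_m, removed = center_tacs(tac)
    p, k = x_m.shape
    corr = temporal_autocorrelation(x_m)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    eigvecs = _fix_signs(eigvecs, x_m.mean(axis=0))

    total = eigvals.sum()
    if total <= 0:
        warnings.warn("degenerate TAC matrix: all temporal variance is zero",
                      RuntimeWarning, stacklevel=2)
        zeros = np.zeros(k)
        return FactorDecomposition(
            eigenvalues=zeros, eigenvectors=eigvecs, scaling=zeros,
            factors=np.zeros((p, k)), variance_fraction=zeros,
            removed_means=removed, scaling_mode=scaling)

    nonzero = eigvals > _ZERO_EIG_REL * eigvals[0]
    d = np.zeros(k)
    if scaling == "inv_sqrt":
        d[nonzero] = 1.0 / np.sqrt(eigvals[nonzero])
    elif scaling == "sqrt":
        d[nonzero] = np.sqrt(eigvals[nonzero])
    else:
        d[nonzero] = 1.0
    factors = x_m @ eigvecs @ np.diag(d)
    return FactorDecomposition(
        eigenvalues=eigvals, eigenvectors=eigvecs, scaling=d,
        factors=factors, variance_fraction=eigvals / total,
        removed_means=removed, scaling_mode=scaling)


def variance_explained(decomp: FactorDecomposition, top_n: int) -> float:
    """Fraction of total variance carried by the ``top_n`` largest factors."""
    k = decomp.frames
    if not 1 <= top_n <= k:
        raise FadsError(f"top_n must be in 1..{k}, got {top_n}")
    total = decomp.eigenvalues.sum()
    if total <= 0:
        return 0.0
    return float(decomp.eigenvalues[:top_n].sum() / total)


def extract_3msf(decomp: FactorDecomposition) -> np.ndarray:
    """The three most significant factors: ``P x 3`` slice of ``F``.

    Columns correspond to the three largest eigenvalues in descending
    order, under the decomposition's sign convention.
    """
    if decomp.frames < 3:
        raise FadsError("need at least 3 frames for the 3-MSF")
    return decomp.factors[:, :3].copy()
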
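"""Gaussian mixture density modeling with constrained covariance families.

The contraction-pattern reference model is a mixture of ``R`` trivariate
Gaussians fitted to the pooled three-factor coordinates of a control
population,

    p(f) = sum_r  w_r  N(f | mu_r, Sigma_r),        sum_r w_r = 1,

fitted by expectation maximization with the covariance matrices constrained
to one of five families (the volume/shape/orientation coding used by
model-based clustering software):

========  ==========================================================
family    constraint on ``Sigma_r``
========  ==========================================================
``EII``   spherical, equal volume: ``lambda * I``
``VII``   spherical, variable volume: ``lambda_r * I``
``EEE``   one shared full covariance
``VEV``   ``lambda_r * D_r * A * D_r'`` — same shape ``A`` (det 1),
          variable volume and orientation
``VVV``   unconstrained per-component full covariance
========  ==========================================================

Model order and family are selected by the Bayes information criterion,
``BIC = -2 logL + m ln n``, minimized (``m`` = free-parameter count).
Because mixture software in the wild also reports the negated convention
``2 logL - m ln n`` (maximized), selection tables carry both columns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COVARIANCE_FAMILIES",
    "GaussianMixture",
    "FitInfo",
    "MixtureError",
    "log_density",
    "em_fit",
    "bic",
    "n_free_parameters",
    "select_model",
    "sample",
]

#: recognised covariance family codes, in tie-breaking order
COVARIANCE_FAMILIES = ("EII", "VII", "EEE", "VEV", "VVV")

_LOG_2PI = math.log(2.0 * math.pi)


class MixtureError(ValueError):
    """Invalid mixture parameters or an unrecoverable EM failure."""


@dataclass
class FitInfo:
    """Bookkeeping attached to a fitted mixture."""

    n: int
    d: int
    log_likelihood: float
    bic: float
    converged: bool
    n_iter: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "d": int(self.d),
            "log_likelihood": float(self.log_likelihood),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "seed": None if self.seed is None else int(self.seed),
        }


@dataclass
class GaussianMixture:
    """A mixture of ``R`` multivariate Gaussians in factor space.

    Parameters are stored unpacked: ``weights`` (R,), ``means`` (R, d) and
    ``covariances`` (R, d, d). ``family`` records the covariance constraint
    the parameters satisfy; ``fit`` is present on fitted/loaded models and
    required by :func:`bic`.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    family: str = "VVV"
    fit: FitInfo | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        self.validate()

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def validate(self, weight_tol: float = 1e-9) -> None:
        R = self.n_components
        if R < 1:
            raise MixtureError("mixture needs at least one component")
        if self.means.shape != (R, self.dim):
            raise MixtureError("means shape inconsistent with weights")
        if self.covariances.shape != (R, self.dim, self.dim):
            raise MixtureError("covariances shape inconsistent with weights")
        if np.any(self.weights < -1e-12) or np.any(self.weights > 1 + 1e-12):
            raise MixtureError("weights must lie in [0, 1]")
        if abs(self.weights.sum() - 1.0) > weight_tol:
            raise MixtureError(
                f"weights sum to {self.weights.sum():.12g}, expected 1"
            )
        if self.family not in COVARIANCE_FAMILIES:
            raise MixtureError(f"unknown covariance family {self.family!r}")
        for r, cov in enumerate(self.covariances, start=1):
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise MixtureError(f"covariance {r} not SPD")
            if np.linalg.eigvalsh(0.5 * (cov + cov.T)).min() <= 0:
                raise MixtureError(f"covariance {r} not SPD")


# ---------------------------------------------------------------------------
# density evaluation


def _component_log_pdfs(points: np.ndarray, means: np.ndarray,
                        covariances: np.ndarray) -> np.ndarray:
    """Log N(x | mu_r, Sigma_r) for every point and component, shape (n, R)."""
    n, d = points.shape
    R = means.shape[0]
    out = np.empty((n, R))
    for r in range(R):
        chol = np.linalg.cholesky(covariances[r])
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        prec = np.linalg.inv(covariances[r])
        diff = points - means[r]
        maha = np.einsum("ij,jk,ik->i", diff, prec, diff)
        out[:, r] = -0.5 * (d * _LOG_2PI + logdet + np.maximum(maha, 0.0))
    return out


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp (finite even when every entry is very negative)."""
    amax = a.max(axis=1)
    with np.errstate(divide="ignore"):
        return amax + np.log(np.exp(a - amax[:, None]).sum(axis=1))


def log_density(model: GaussianMixture, points: np.ndarray) -> np.ndarray:
    """Log mixture density ``log p(f)`` at each row of ``points``.

    Evaluated through the log-sum-exp identity so that points arbitrarily
    far from every component yield a finite large-negative value rather
    than ``log(0)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != model.dim:
        raise MixtureError(
            f"points have dimension {points.shape[1]}, model is {model.dim}-D"
        )
    bad = ~np.isfinite(points).all(axis=1)
    if bad.any():
        raise MixtureError(f"non-finite point at row {int(np.flatnonzero(bad)[0])}")
    comp = _component_log_pdfs(points, model.means, model.covariances)
    with np.errstate(divide="ignore"):
        logw = np.log(model.weights)
    return _logsumexp_rows(comp + logw)


# ---------------------------------------------------------------------------
# EM fitting

def n_free_parameters(R: int, family: str, d: int = 3) -> int:
    """Free-parameter count of an ``(R, family)`` mixture in ``d`` dimensions.

    Weights contribute ``R - 1`` and means ``R * d``; the covariance block
    depends on the family: 1 (EII), R (VII), d(d+1)/2 (EEE),
    ``R + (d - 1) + R d(d-1)/2`` (VEV: volumes + det-1 shape + orientations)
    and ``R d(d+1)/2`` (VVV).
    """
    full = d * (d + 1) // 2
    orient = d * (d - 1) // 2
    cov = {
        "EII": 1,
        "VII": R,
        "EEE": full,
        "VEV": R + (d - 1) + R * orient,
        "VVV": R * full,
    }[family]
    return (R - 1) + R * d + cov


def _vev_covariances(scatter: np.ndarray, nk: np.ndarray,
                     inner_tol: float = 1e-8,
                     max_inner: int = 100) -> np.ndarray:
    """M-step for the VEV family: Sigma_r = lambda_r D_r A D_r'.

    With the scatter matrices eigendecomposed as ``W_r = L_r Omega_r L_r'``
    (eigenvalues descending), the optimal orientation is ``D_r = L_r``
    regardless of the shared shape, leaving an alternating update between
    the volumes ``lambda_r`` and the shape ``A`` (diagonal, det 1):

        A  ∝  sum_r Omega_r / lambda_r        (normalized to det 1)
        lambda_r = tr(A^{-1} Omega_r) / (d n_r)

    iterated to a relative tolerance. No closed form exists.
    """
    R, d, _ = scatter.shape
    omega = np.empty((R, d))
    rot = np.empty((R, d, d))
    for r in range(R):
        w, v = np.linalg.eigh(0.5 * (scatter[r] + scatter[r].T))
        order = np.argsort(w)[::-1]
        omega[r] = np.clip(w[order], 0.0, None)
        rot[r] = v[:, order]
    lam = np.maximum(omega.sum(axis=1) / (d * nk), 1e-300)
    shape = np.ones(d)
    for _ in range(max_inner):
        b = (omega / lam[:, None]).sum(axis=0)
        b = np.maximum(b, 1e-300)
        shape_new = b / np.prod(b) ** (1.0 / d)
        lam_new = (omega / shape_new[None, :]).sum(axis=1) / (d * nk)
        lam_new = np.maximum(lam_new, 1e-300)
        delta = max(
            np.abs(shape_new - shape).max() / max(shape.max(), 1e-300),
            np.abs(lam_new - lam).max() / max(lam.max(), 1e-300),
        )
        shape, lam = shape_new, lam_new
        if delta < inner_tol:
            break
    covs = np.empty_like(scatter)
    for r in range(R):
        covs[r] = rot[r] @ np.diag(lam[r] * shape) @ rot[r].T
    return covs


def _m_step_covariances(data: np.ndarray, resp: np.ndarray, means: np.ndarray,
                        family: str) -> np.ndarray:
    n, d = data.shape
    R = means.shape[0]
    nk = resp.sum(axis=0)
    scatter = np.empty((R, d, d))
    for r in range(R):
        diff = data - means[r]
        scatter[r] = (resp[:, r, None] * diff).T @ diff
    if family == "VVV":
        covs = scatter / nk[:, None, None]
    elif family == "EEE":
        covs = np.broadcast_to(scatter.sum(axis=0) / n, (R, d, d)).copy()
    elif family == "VII":
        lam = np.trace(scatter, axis1=1, axis2=2) / (d * nk)
        covs = lam[:, None, None] * np.eye(d)
    elif family == "EII":
        lam = np.trace(scatter, axis1=1, axis2=2).sum() / (d * n)
        covs = np.broadcast_to(lam * np.eye(d), (R, d, d)).copy()
    elif family == "VEV":
        covs = _vev_covariances(scatter, nk)
    else:  # pragma: no cover - guarded by validate()
        raise MixtureError(f"unknown covariance family {family!r}")
    return covs


def _apply_floor(covs: np.ndarray, floor: float) -> np.ndarray:
    """Regularize any component whose smallest eigenvalue falls below floor."""
    d = covs.shape[1]
    for r in range(covs.shape[0]):
        if np.linalg.eigvalsh(0.5 * (covs[r] + covs[r].T)).min() < floor:
            covs[r] = covs[r] + floor * np.eye(d)
    return covs


def _kmeans_pp_centers(data: np.ndarray, R: int,
                       rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers over the data."""
    n = data.shape[0]
    centers = np.empty((R, data.shape[1]))
    centers[0] = data[rng.integers(n)]
    closest = np.square(data - centers[0]).sum(axis=1)
    for r in range(1, R):
        total = closest.sum()
        if total <= 0:
            centers[r] = data[rng.integers(n)]
            continue
        probs = closest / total
        centers[r] = data[rng.choice(n, p=probs)]
        closest = np.minimum(closest, np.square(data - centers[r]).sum(axis=1))
    return centers


def _initial_responsibilities(data: np.ndarray, R: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Hard assignment to k-means++ seed centers, softened slightly."""
    n = data.shape[0]
    centers = _kmeans_pp_centers(data, R, rng)
    dist = np.square(data[:, None, :] - centers[None]).sum(axis=2)
    resp = np.zeros((n, R))
    resp[np.arange(n), dist.argmin(axis=1)] = 1.0
    resp = resp + 1e-10
    resp /= resp.sum(axis=1, keepdims=True)
    return resp


def _em_run(data: np.ndarray, family: str, resp: np.ndarray, tol: float,
            max_iter: int, floor: float):
    """EM iterations from given responsibilities; returns state + history."""
    n, d = data.shape
    log_lik = -np.inf
    history: list[float] = []
    converged = False
    weights = means = covs = None
    it = 0
    for it in range(1, max_iter + 1):
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8) or not np.isfinite(nk).all():
            raise _ComponentCollapse(f"component occupancy collapsed ({nk.min():.3g})")
        weights = nk / n
        means = (resp.T @ data) / nk[:, None]
        covs = _m_step_covariances(data, resp, means, family)
        covs = _apply_floor(covs, floor)
        # E-step
        comp = _component_log_pdfs(data, means, covs)
        with np.errstate(divide="ignore"):
            joint = comp + np.log(weights)
        norm = _logsumexp_rows(joint)
        new_log_lik = float(norm.sum())
        if not np.isfinite(new_log_lik):
            raise _ComponentCollapse("non-finite log-likelihood")
        history.append(new_log_lik)
        resp = np.exp(joint - norm[:, None])
        if np.isfinite(log_lik):
            rel = abs(new_log_lik - log_lik) / max(abs(new_log_lik), 1.0)
            log_lik = new_log_lik
            if rel < tol:
                converged = True
                break
        else:
            log_lik = new_log_lik
    return weights, means, covs, resp, log_lik, converged, it, history


class _ComponentCollapse(RuntimeError):
    pass


def em_fit(data: np.ndarray, R: int, family: str = "VVV", *,
           seed: int | None = 0, tol: float = 1e-6, max_iter: int = 500,
           n_init: int = 5, burn_in: int = 25,
           retry_budget: int = 3) -> GaussianMixture:
    """Fit an ``R``-component mixture of the given family by EM.

    Initialization is k-means++-style seeding from ``seed`` with ``n_init``
    restarts. Each restart runs a short burn-in of ``burn_in`` EM
    iterations; the restart with the best burn-in log-likelihood is then
    continued to convergence (relative log-likelihood change below ``tol``
    or ``max_iter`` total iterations). A covariance floor of
    ``1e-6 * tr(S)/d`` (``S`` the data covariance) guards against component
    collapse; if every restart collapses the fit is retried with a fresh
    sub-seed, up to ``retry_budget`` times.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if not np.isfinite(data).all():
        raise MixtureError("data contains non-finite values")
    n, d = data.shape
    if family not in COVARIANCE_FAMILIES:
        raise MixtureError(f"unknown covariance family {family!r}")
    if n <= R:
        raise MixtureError(f"need more points than components (n={n}, R={R})")

    total_cov = np.cov(data, rowvar=False)
    floor = 1e-6 * float(np.trace(np.atleast_2d(total_cov))) / d
    floor = max(floor, np.finfo(float).tiny)

    seed_seq = np.random.SeedSequence(seed)
    best = None
    attempts = 0
    while best is None and attempts <= retry_budget:
        streams = seed_seq.spawn(n_init)
        short_runs = []
        for stream in streams:
            rng = np.random.default_rng(stream)
            try:
                resp0 = _initial_responsibilities(data, R, rng)
                short_runs.append(_em_run(data, family, resp0, tol,
                                          min(burn_in, max_iter), floor))
            except _ComponentCollapse:
                continue
        # continue the most promising burn-in to full convergence
        for state in sorted(short_runs, key=lambda s: s[4], reverse=True):
            weights, means, covs, resp, log_lik, converged, it, history = state
            if converged or it >= max_iter:
                best = state
                break
            try:
                cont = _em_run(data, family, resp, tol, max_iter - it, floor)
            except _ComponentCollapse:
                continue
            best = (cont[0], cont[1], cont[2], cont[3], cont[4], cont[5],
                    it + cont[6], history + cont[7])
            break
        if best is None:
            attempts += 1
            seed_seq = np.random.SeedSequence([0 if seed is None else seed,
                                               attempts])
    if best is None:
        raise MixtureError(
            f"EM failed for R={R} family={family}: all restarts collapsed"
        )
    weights, means, covs, _, log_lik, converged, n_iter, history = best
    model = GaussianMixture(weights, means, covs, family=family)
    m = n_free_parameters(R, family, d)
    model.fit = FitInfo(n=n, d=d, log_likelihood=log_lik,
                        bic=-2.0 * log_lik + m * math.log(n),
                        converged=converged, n_iter=n_iter, seed=seed)
    # per-iteration log-likelihood path of the winning restart (diagnostics)
    model.log_likelihood_path_ = np.asarray(history)
    return model


def bic(model: GaussianMixture) -> float:
    """Bayes information criterion ``-2 logL + m ln n`` (lower is better)."""
    if model.fit is None:
        raise MixtureError("model has no fit record; BIC needs n and logL")
    m = n_free_parameters(model.n_components, model.family, model.dim)
    return -2.0 * model.fit.log_likelihood + m * math.log(model.fit.n)


def select_model(data: np.ndarray,
                 r_range: Iterable[int] = range(1, 10),
                 families: Sequence[str] = COVARIANCE_FAMILIES,
                 seed: int | None = 0, *,
                 tol: float = 1e-6, max_iter: int = 500,
                 n_init: int = 5) -> tuple[GaussianMixture, pd.DataFrame]:
    """Fit every ``(R, family)`` candidate and keep the minimum-BIC model.

    Returns the selected model and a selection table with one row per
    candidate (family, components, log-likelihood and BIC in both sign
    conventions); candidates whose fit fails are recorded with an error
    message and skipped. Ties break toward fewer components, then family
    order as listed.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    r_values = sorted(set(int(r) for r in r_range))
    rows = []
    best_model = None
    best_key = None
    seed_seq = np.random.SeedSequence(seed)
    sub = {pair: s for pair, s in
           zip(itertools.product(r_values, families),
               seed_seq.generate_state(len(r_values) * len(families)))}
    for fam_idx, family in enumerate(families):
        for R in r_values:
            cand_seed = int(sub[(R, family)] % (2 ** 31))
            try:
                model = em_fit(data, R, family, seed=cand_seed, tol=tol,
                               max_iter=max_iter, n_init=n_init)
            except MixtureError as exc:
                rows.append({"family": family, "n_components": R,
                             "log_likelihood": np.nan, "bic": np.nan,
                             "bic_negated": np.nan, "converged": False,
                             "error": str(exc)})
                continue
            b = model.fit.bic
            rows.append({"family": family, "n_components": R,
                         "log_likelihood": model.fit.log_likelihood,
                         "bic": b, "bic_negated": -b,
                         "converged": model.fit.converged, "error": ""})
            key = (b, R, fam_idx)
            if best_key is None or key < best_key:
                best_key, best_model = key, model
    if best_model is None:
        raise MixtureError("every candidate model failed to fit")
    table = pd.DataFrame(rows)
    return best_model, table


def sample(model: GaussianMixture, n: int, seed: int | None = 0,
           return_components: bool = False):
    """Draw ``n`` points from the mixture (component then Gaussian draw)."""
    rng = np.random.default_rng(seed)
    if n == 0:
        pts = np.empty((0, model.dim))
        return (pts, np.empty(0, dtype=int)) if return_components else pts
    labels = rng.choice(model.n_components, size=n, p=model.weights)
    points = np.empty((n, model.dim))
    for r in range(model.n_components):
        idx = np.flatnonzero(labels == r)
        if idx.size:
            points[idx] = rng.multivariate_normal(
                model.means[r], model.covariances[r], size=idx.size,
                method="cholesky")
    if return_components:
        return points, labels
    return points
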
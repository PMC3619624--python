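"""Mixture density, EM fitting, covariance families and BIC selection."""

import math

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal

import fadsync as fs
from fadsync.mixture import (FitInfo, MixtureError, _component_log_pdfs,
                             _logsumexp_rows, n_free_parameters)


def brute_force_log_density(model, points):
    """Direct-formula summation oracle (no log-sum-exp, no shortcuts)."""
    out = []
    for x in np.atleast_2d(points):
        total = sum(w * multivariate_normal.pdf(x, mean=mu, cov=cov)
                    for w, mu, cov in zip(model.weights, model.means,
                                          model.covariances))
        out.append(math.log(total))
    return np.array(out)


def test_log_density_single_component_closed_form():
    model = fs.GaussianMixture([1.0], np.zeros((1, 3)), np.eye(3)[None])
    value = fs.log_density(model, np.zeros((1, 3)))[0]
    assert value == pytest.approx(-1.5 * math.log(2 * math.pi), abs=1e-12)


def test_log_density_matches_brute_force_oracle(reference_model):
    pts = np.array([[1.661, -2.524, -0.036],
                    [0.336, -1.080, 0.010],
                    [0.0, 0.0, 0.0],
                    [2.0, -2.0, 1.0]])
    np.testing.assert_allclose(fs.log_density(reference_model, pts),
                               brute_force_log_density(reference_model, pts),
                               atol=1e-10)


def test_log_density_far_points_stay_finite(reference_model):
    far = np.full((1, 3), 200.0 * 5.0)  # hundreds of sigma from every mean
    value = fs.log_density(reference_model, far)[0]
    assert np.isfinite(value)
    assert value < -1e4


def test_log_density_rejects_non_finite_point(reference_model):
    pts = np.zeros((3, 3))
    pts[1, 2] = np.nan
    with pytest.raises(MixtureError, match="row 1"):
        fs.log_density(reference_model, pts)


def test_responsibilities_sum_to_one(reference_model):
    rng = np.random.default_rng(0)
    pts = rng.normal(0, 2, size=(100, 3))
    comp = _component_log_pdfs(pts, reference_model.means,
                               reference_model.covariances)
    joint = comp + np.log(reference_model.weights)
    resp = np.exp(joint - _logsumexp_rows(joint)[:, None])
    np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)


def test_single_component_fit_is_sample_moments(reference_sample):
    data = reference_sample[:500]
    for family in ("VVV", "EII"):
        model = fs.em_fit(data, 1, family, seed=0)
        np.testing.assert_allclose(model.means[0], data.mean(axis=0),
                                   atol=1e-10)
        mle_cov = np.cov(data, rowvar=False, ddof=0)
        if family == "VVV":
            np.testing.assert_allclose(model.covariances[0], mle_cov,
                                       atol=1e-10)
        else:
            lam = np.trace(mle_cov) / 3.0
            np.testing.assert_allclose(model.covariances[0], lam * np.eye(3),
                                       atol=1e-10)


@pytest.mark.parametrize("family", ["EII", "VII", "EEE", "VEV", "VVV"])
def test_em_log_likelihood_monotone(reference_sample, family):
    model = fs.em_fit(reference_sample[:1000], 3, family, seed=1)
    path = model.log_likelihood_path_
    assert path.size >= 2
    assert (np.diff(path) > -1e-8).all()


def test_fitted_weights_normalized(reference_sample):
    model = fs.em_fit(reference_sample[:1500], 4, "VVV", seed=2)
    assert abs(model.weights.sum() - 1.0) < 1e-9


def test_parameter_recovery_from_reference_model(reference_model,
                                                 reference_sample):
    model = fs.em_fit(reference_sample, 5, "VVV", seed=0)
    cost = np.linalg.norm(model.means[:, None, :]
                          - reference_model.means[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    matched_error = np.abs(model.means[rows] - reference_model.means[cols])
    assert matched_error.max() < 0.15


def test_family_constraints_hold(reference_sample):
    data = reference_sample[:1500]
    vii = fs.em_fit(data, 3, "VII", seed=3)
    for cov in vii.covariances:
        assert np.allclose(cov, cov[0, 0] * np.eye(3), atol=1e-10)
    eee = fs.em_fit(data, 3, "EEE", seed=3)
    for cov in eee.covariances[1:]:
        np.testing.assert_allclose(cov, eee.covariances[0], atol=1e-10)
    # VEV: same normalized eigenvalue shape across components
    vev = fs.em_fit(data, 3, "VEV", seed=3)
    shapes = []
    for cov in vev.covariances:
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        shapes.append(eig / np.prod(eig) ** (1.0 / 3.0))
    for shape in shapes[1:]:
        np.testing.assert_allclose(shape, shapes[0], atol=1e-6)


def test_nested_families_order_log_likelihood(reference_sample):
    data = reference_sample[:1200]
    fits = {family: fs.em_fit(data, 2, family, seed=5).fit.log_likelihood
            for family in ("EEE", "VEV", "VVV")}
    assert fits["VVV"] >= fits["VEV"] - 1e-6
    assert fits["VEV"] >= fits["EEE"] - 1e-6


def test_free_parameter_counts():
    assert n_free_parameters(1, "VVV") == 9
    assert n_free_parameters(5, "VVV") == 4 + 15 + 30
    assert n_free_parameters(5, "EII") == 4 + 15 + 1
    assert n_free_parameters(5, "VII") == 4 + 15 + 5
    assert n_free_parameters(5, "EEE") == 4 + 15 + 6
    assert n_free_parameters(5, "VEV") == 4 + 15 + (5 + 2 + 15)


def test_bic_hand_computed_on_small_fixture():
    rng = np.random.default_rng(8)
    data = rng.normal(size=(10, 3))
    model = fs.em_fit(data, 1, "VVV", seed=0)
    # closed-form Gaussian MLE log-likelihood oracle
    cov = np.cov(data, rowvar=False, ddof=0)
    log_lik = -0.5 * 10 * (3 * math.log(2 * math.pi)
                           + math.log(np.linalg.det(cov)) + 3)
    assert model.fit.log_likelihood == pytest.approx(log_lik, abs=1e-8)
    assert fs.bic(model) == pytest.approx(-2 * log_lik + 9 * math.log(10),
                                          abs=1e-6)


def test_bic_scales_with_sample_size(reference_sample):
    model = fs.em_fit(reference_sample[:400], 2, "VVV", seed=1)
    doubled = fs.GaussianMixture(model.weights, model.means,
                                 model.covariances, family=model.family)
    doubled.fit = FitInfo(n=2 * model.fit.n, d=3,
                          log_likelihood=model.fit.log_likelihood,
                          bic=float("nan"), converged=True, n_iter=1)
    m = n_free_parameters(2, "VVV")
    assert fs.bic(doubled) - fs.bic(model) == pytest.approx(m * math.log(2),
                                                            rel=1e-12)


def test_bic_requires_fit_record():
    model = fs.GaussianMixture([1.0], np.zeros((1, 3)), np.eye(3)[None])
    with pytest.raises(MixtureError, match="fit"):
        fs.bic(model)


def test_em_rejects_undersized_data():
    with pytest.raises(MixtureError, match="more points"):
        fs.em_fit(np.zeros((3, 3)), 3, "VVV")


def test_selection_recovers_single_gaussian():
    rng = np.random.default_rng(12)
    data = rng.normal(size=(2000, 3))
    model, table = fs.select_model(data, r_range=range(1, 4),
                                   families=("EII", "VVV"), seed=0)
    assert model.n_components == 1
    assert len(table) == 3 * 2


def test_sampling_contracts(reference_model):
    assert fs.sample(reference_model, 0, seed=1).shape == (0, 3)
    a = fs.sample(reference_model, 50, seed=9)
    b = fs.sample(reference_model, 50, seed=9)
    np.testing.assert_array_equal(a, b)
    pts, labels = fs.sample(reference_model, 100_000, seed=3,
                            return_components=True)
    occupancy = np.bincount(labels, minlength=5) / labels.size
    np.testing.assert_allclose(occupancy, reference_model.weights, atol=0.01)


def test_density_integrates_to_one(reference_model):
    # importance sampling against an overdispersed proposal
    proposal = fs.GaussianMixture(reference_model.weights,
                                  reference_model.means,
                                  4.0 * reference_model.covariances)
    n = 40_000
    pts = fs.sample(proposal, n, seed=17)
    log_ratio = fs.log_density(reference_model, pts) \
        - fs.log_density(proposal, pts)
    ratio = np.exp(log_ratio)
    estimate = ratio.mean()
    se = ratio.std(ddof=1) / math.sqrt(n)
    assert abs(estimate - 1.0) < 3.0 * se


def test_sklearn_agrees_with_log_density(reference_model):
    # independent evaluation of the same parameters
    sklearn_gm = pytest.importorskip("sklearn.mixture").GaussianMixture
    gm = sklearn_gm(n_components=5, covariance_type="full")
    gm.weights_ = reference_model.weights
    gm.means_ = reference_model.means
    gm.covariances_ = reference_model.covariances
    from scipy.linalg import solve_triangular
    gm.precisions_cholesky_ = np.array(
        [solve_triangular(np.linalg.cholesky(c), np.eye(3), lower=True).T
         for c in reference_model.covariances])
    rng = np.random.default_rng(23)
    pts = rng.normal(0, 2, size=(200, 3))
    np.testing.assert_allclose(fs.log_density(reference_model, pts),
                               gm.score_samples(pts), atol=1e-8)
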
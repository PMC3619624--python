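"""Reference-model training and the likelihood normality index."""

import math

import numpy as np
import pytest

import fadsync as fs
from fadsync.normality import NormalityError

from conftest import small_cohort_spec, small_config

# compact training settings used throughout this module
TRAIN_KW = dict(group_count=2, group_size=3, r_range=range(1, 3),
                families=("EII", "VVV"), seed=11)


@pytest.fixture(scope="module")
def small_controls():
    return fs.generate_cohort(small_cohort_spec("normal", n=5, seed=31))


@pytest.fixture(scope="module")
def small_training(small_controls):
    return fs.train_reference_model(small_controls, **TRAIN_KW)


def test_subject_factor_points_shape_and_determinism(small_subject):
    series, mask = small_subject
    pts = fs.subject_factor_points(series, mask)
    n_vent = int((mask.labels > 0).sum())
    assert pts.shape == (n_vent, 3)
    np.testing.assert_array_equal(pts,
                                  fs.subject_factor_points(series, mask))


def test_noiseless_normal_subject_has_degenerate_third_factor(
        noiseless_subject):
    # a pure cosine spans two temporal dimensions; F3 carries nothing
    series, mask = noiseless_subject
    pts = fs.subject_factor_points(series, mask)
    assert np.ptp(pts[:, 2]) < 1e-6


def test_training_structure_and_reference_selection(small_training):
    assert len(small_training.groups) == 2
    best = min(range(2), key=lambda g: small_training.groups[g].bic)
    assert small_training.selected_group == best
    assert small_training.selected is small_training.groups[best].model
    for fit in small_training.groups:
        assert len(fit.subject_ids) == 3
        assert len(fit.selection_table) == 2 * 2  # |R_range| x |families|
    table = small_training.summary_table()
    assert table["selected"].sum() == 1


def test_training_reproducible_and_order_invariant(small_controls):
    first = fs.train_reference_model(small_controls, **TRAIN_KW)
    again = fs.train_reference_model(small_controls, **TRAIN_KW)
    np.testing.assert_array_equal(first.selected.means, again.selected.means)
    assert [g.subject_ids for g in first.groups] == \
        [g.subject_ids for g in again.groups]
    # permuting subjects (with their ids) leaves the result unchanged
    ids = list(range(5))
    perm = [3, 0, 4, 1, 2]
    shuffled = fs.train_reference_model(
        [small_controls[i] for i in perm], **TRAIN_KW,
        subject_ids=[ids[i] for i in perm])
    np.testing.assert_array_equal(first.selected.means,
                                  shuffled.selected.means)


def test_training_degenerate_single_group(small_controls):
    result = fs.train_reference_model(small_controls, group_count=1,
                                      group_size=5, r_range=range(1, 3),
                                      families=("VVV",), seed=2)
    assert len(result.groups) == 1
    assert sorted(result.groups[0].subject_ids) == list(range(5))
    assert result.selected is result.groups[0].model


def test_training_rejects_too_few_subjects(small_controls):
    with pytest.raises(NormalityError, match="group_size"):
        fs.train_reference_model(small_controls[:2], group_size=10)


def test_normality_index_closed_form():
    model = fs.GaussianMixture([1.0], np.zeros((1, 3)), np.eye(3)[None])
    value = fs.normality_index(model, np.zeros((1, 3)))
    assert value == pytest.approx(-1.5 * math.log(2 * math.pi), abs=1e-12)
    assert fs.normality_index(model, np.zeros((1, 3)),
                              orientation="abnormality") == -value


def test_normality_index_matches_entropy_oracle(reference_model):
    # I_N of a large model sample estimates E[log p] (negative entropy)
    pts = fs.sample(reference_model, 30_000, seed=41)
    values = fs.log_density(reference_model, pts)
    se = values.std(ddof=1) / math.sqrt(values.size)
    independent = fs.log_density(reference_model,
                                 fs.sample(reference_model, 30_000, seed=42))
    assert abs(fs.normality_index(reference_model, pts)
               - independent.mean()) < 3.0 * se * math.sqrt(2.0)


def test_normality_index_decreases_away_from_the_modes(reference_model):
    pts = fs.sample(reference_model, 500, seed=13)
    base = fs.normality_index(reference_model, pts)
    drifted = [fs.normality_index(reference_model, pts + shift)
               for shift in (2.0, 5.0, 10.0)]
    assert base > drifted[0] > drifted[1] > drifted[2]


def test_normality_index_rejects_empty_set(reference_model):
    with pytest.raises(NormalityError, match="empty"):
        fs.normality_index(reference_model, np.empty((0, 3)))


def test_score_cohort_counts_and_comparisons(small_training, small_controls):
    dcm = fs.generate_cohort(small_cohort_spec("dcm_like", n=3, seed=77))
    report = fs.score_cohort(small_training.selected, small_controls + dcm,
                             classes=["normal"] * 5 + ["dcm"] * 3)
    assert len(report.subjects) == 8
    assert len(report.group_summaries) == 2
    assert len(report.comparisons) == 1
    comp = report.comparisons[0]
    assert (comp.group_a, comp.group_b) == ("normal", "dcm")
    assert 0.0 <= comp.p_value <= 1.0
    with pytest.raises(NormalityError, match="empty"):
        fs.score_cohort(small_training.selected, [])


def test_trainers_score_above_dcm_subjects(small_training, small_controls):
    # the model explains its own training class better than dcm-like
    # subjects, here averaged over 20 independently seeded dcm subjects
    dcm = fs.generate_cohort(small_cohort_spec("dcm_like", n=20, seed=55))
    report = fs.score_cohort(small_training.selected, small_controls + dcm,
                             classes=["trainer"] * 5 + ["dcm"] * 20)
    by_class = report.group_summaries.set_index("class")["mean"]
    assert by_class["trainer"] >= by_class["dcm"]
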
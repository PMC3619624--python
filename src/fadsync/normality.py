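"""Reference-model training and the likelihood normality index.

The two-stage procedure:

**Training** (controls only). Each control subject's ventricular pixels are
projected to their three most significant FADS factor coordinates. Several
resampled groups of controls are assembled (default six groups of ten drawn
without replacement within each group; subjects may recur across groups,
bootstrap-style); each group's pooled factor cloud is fitted by
BIC-selected Gaussian-mixture search, and the group model with the overall
minimum BIC becomes the reference normal-contraction model.

**Scoring.** A subject's normality index is the average log-likelihood of
its ventricular factor points under the reference mixture,

    I_N = (1/|S|) sum_{s in S} log sum_r w_r N(f_s | mu_r, Sigma_r),

implemented literally (natural log; typically negative, higher = more
normal). Because clinical reports sometimes quote the index on a scale
that *increases* with abnormality, the negated value is available as the
``abnormality`` orientation; every report records which orientation it
used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import fads
from .io import GatedSeries, RoiMask, build_tac_matrix
from .mixture import COVARIANCE_FAMILIES, GaussianMixture, log_density, select_model
from .stats import ALPHA, ComparisonResult, summarize, ttest_independent

__all__ = [
    "TrainingResult",
    "NormalityReport",
    "NormalityError",
    "subject_factor_points",
    "train_reference_model",
    "normality_index",
    "score_cohort",
]


class NormalityError(ValueError):
    pass


@dataclass
class GroupFit:
    """One resampled training group and its selected mixture."""

    subject_ids: list
    model: GaussianMixture
    bic: float
    log_likelihood: float
    selection_table: pd.DataFrame


@dataclass
class TrainingResult:
    groups: list
    selected: GaussianMixture
    selected_group: int
    provenance: dict = field(default_factory=dict)

    def summary_table(self) -> pd.DataFrame:
        """One row per group: selected family, components, BIC, logL."""
        rows = []
        for g, fit in enumerate(self.groups, start=1):
            rows.append({
                "group": g,
                "family": fit.model.family,
                "n_components": fit.model.n_components,
                "bic": fit.bic,
                "log_likelihood": fit.log_likelihood,
                "selected": g - 1 == self.selected_group,
                "subjects": ";".join(str(s) for s in fit.subject_ids),
            })
        return pd.DataFrame(rows)


@dataclass
class NormalityReport:
    subjects: pd.DataFrame        # id, class, n_points, index
    group_summaries: pd.DataFrame  # class, n, mean, sd, min, max
    comparisons: list             # ComparisonResult per class pair
    orientation: str = "literal"


def subject_factor_points(series: GatedSeries, mask: RoiMask,
                          regions=("LV", "RV"),
                          scaling: str = "inv_sqrt") -> np.ndarray:
    """Ventricular 3-MSF point cloud of one subject (``n x 3``).

    Composition of the pipeline stages: TAC matrix over the selected
    regions, per-pixel centering, temporal eigendecomposition, then the
    three most significant factor coordinates.
    """
    tac = build_tac_matrix(series, mask, regions=regions)
    decomp = fads.decompose(tac, scaling=scaling)
    return fads.extract_3msf(decomp)


def train_reference_model(subjects: Sequence, *,
                          group_count: int = 6, group_size: int = 10,
                          r_range=range(1, 10),
                          families: Sequence[str] = COVARIANCE_FAMILIES,
                          seed: int = 0, regions=("LV", "RV"),
                          scaling: str = "inv_sqrt",
                          subject_ids: Sequence | None = None,
                          **fit_kwargs) -> TrainingResult:
    """Resampled-group training of the reference contraction model.

    ``subjects`` is a sequence of ``(GatedSeries, RoiMask)`` pairs (the
    control cohort). Groups of ``group_size`` subjects are drawn without
    replacement within each group, independently across ``group_count``
    groups; each group's pooled factor cloud goes through BIC model
    selection, and the minimum-BIC group model is returned as the
    reference.
    """
    n = len(subjects)
    if n < group_size:
        raise NormalityError(
            f"need at least group_size={group_size} subjects, got {n}")
    if group_count < 1:
        raise NormalityError("group_count must be at least 1")
    ids = list(subject_ids) if subject_ids is not None else list(range(n))
    if len(ids) != n:
        raise NormalityError("subject_ids length must match subjects")
    # canonical order by subject id: group assembly then depends only on the
    # id set and the seed, not on the order subjects were passed in
    order = sorted(range(n), key=lambda i: str(ids[i]))
    ids = [ids[i] for i in order]
    subjects = [subjects[i] for i in order]

    points = [subject_factor_points(series, mask, regions=regions,
                                    scaling=scaling)
              for series, mask in subjects]

    rng = np.random.default_rng(seed)
    groups = []
    best = None
    for g in range(group_count):
        members = np.sort(rng.choice(n, size=group_size, replace=False))
        pooled = np.vstack([points[i] for i in members])
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        model, table = select_model(pooled, r_range=r_range,
                                    families=families, seed=sub_seed,
                                    **fit_kwargs)
        fit = GroupFit(subject_ids=[ids[i] for i in members], model=model,
                       bic=model.fit.bic,
                       log_likelihood=model.fit.log_likelihood,
                       selection_table=table)
        groups.append(fit)
        if best is None or fit.bic < groups[best].bic:
            best = g
    return TrainingResult(
        groups=groups, selected=groups[best].model, selected_group=best,
        provenance={"seed": seed, "group_count": group_count,
                    "group_size": group_size, "n_subjects": n,
                    "regions": tuple(regions), "scaling": scaling,
                    "r_range": [int(r) for r in r_range],
                    "families": list(families)})


def normality_index(model: GaussianMixture, points: np.ndarray,
                    orientation: str = "literal") -> float:
    """Average log-likelihood of a factor point cloud under the model.

    ``orientation='literal'`` returns the mean natural-log density
    (higher = more normal); ``'abnormality'`` returns its negation.
    """
    if orientation not in ("literal", "abnormality"):
        raise NormalityError(f"unknown orientation {orientation!r}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 1:
        raise NormalityError("empty point set")
    value = float(log_density(model, points).mean())
    return -value if orientation == "abnormality" else value


def score_cohort(model: GaussianMixture, subjects: Sequence, *,
                 classes: Sequence | None = None,
                 subject_ids: Sequence | None = None,
                 regions=("LV", "RV"), scaling: str = "inv_sqrt",
                 orientation: str = "literal",
                 variant: str = "welch", alpha: float = ALPHA) -> NormalityReport:
    """Score a cohort and compare the per-class normality-index groups.

    ``subjects`` is a sequence of ``(GatedSeries, RoiMask)`` pairs;
    ``classes`` assigns each subject a group label (one group when absent).
    Classes with at least two subjects are pairwise compared with the
    independent-samples t-test.
    """
    n = len(subjects)
    if n == 0:
        raise NormalityError("empty cohort")
    classes = list(classes) if classes is not None else ["all"] * n
    ids = list(subject_ids) if subject_ids is not None else list(range(n))
    if len(classes) != n or len(ids) != n:
        raise NormalityError("classes/subject_ids length must match subjects")

    rows = []
    for sid, cls, (series, mask) in zip(ids, classes, subjects):
        pts = subject_factor_points(series, mask, regions=regions,
                                    scaling=scaling)
        rows.append({"subject_id": sid, "class": cls,
                     "n_points": pts.shape[0],
                     "normality_index": normality_index(
                         model, pts, orientation=orientation)})
    table = pd.DataFrame(rows)

    summaries = []
    for cls, grp in table.groupby("class", sort=False):
        s = summarize(grp["normality_index"])
        summaries.append({"class": cls, "n": s.n, "mean": s.mean, "sd": s.sd,
                          "min": s.min, "max": s.max})
    summary_table = pd.DataFrame(summaries)

    comparisons: list[ComparisonResult] = []
    ordered = list(dict.fromkeys(classes))
    for i, ca in enumerate(ordered):
        for cb in ordered[i + 1:]:
            va = table.loc[table["class"] == ca, "normality_index"]
            vb = table.loc[table["class"] == cb, "normality_index"]
            if len(va) >= 2 and len(vb) >= 2:
                comparisons.append(ttest_independent(
                    va, vb, variant=variant, names=(ca, cb), alpha=alpha))
    return NormalityReport(subjects=table, group_summaries=summary_table,
                           comparisons=comparisons, orientation=orientation)
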
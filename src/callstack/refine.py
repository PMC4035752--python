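"""Refine a single caller's ranking with its quality score and filter outcomes.

Some callers expose more than a final call list: a continuous mutation
quality score, and the pass/fail outcome of each internal filter, for a
broader candidate set. Ranking the caller's detections by quality turns
its single (FP, TP) operating point into a curve; fitting a logistic
model on quality plus the filter indicators (the filters' definitions may
be proprietary — they are consumed as opaque 0/1 flags) can recover true
mutations that a miscalibrated filter discarded.

The refinement model reuses the penalized-path / cross-validation /
one-standard-error machinery of the stacking module. Its candidate
universe is the validated union universe (sites called by at least one
caller), so its scores remain comparable with every other caller here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from callstack.data_model import CallDataset, DataError
from callstack.stacking import (
    FeatureConfig,
    StackedFit,
    cross_validate,
    default_lambda_path,
    fit_l1_logistic_path,
    select_lambda_1se,
)

logger = logging.getLogger(__name__)


def _caller_extras(dataset: CallDataset, caller: str) -> pd.DataFrame:
    if caller not in dataset.extras:
        raise DataError(f"no extras (quality/filters) available for caller {caller!r}")
    return dataset.extras[caller]


def rank_by_quality(dataset: CallDataset, caller: str) -> np.ndarray:
    """Score the union universe by one caller's mutation quality.

    Sites the caller detected get their quality score; all other sites get
    ``-inf`` (they are never called, whatever the threshold), so the ROC of
    this score ends exactly at the caller's single operating point before
    the final jump to (100, 100).
    """
    extras = _caller_extras(dataset, caller)
    detected = dataset.calls[:, dataset.caller_index(caller)].astype(bool)
    quality = extras["quality"].to_numpy(dtype=float)
    if np.isnan(quality[detected]).any():
        raise DataError(f"missing quality score for sites detected by {caller!r}")
    scores = np.full(dataset.n, -np.inf)
    scores[detected] = quality[detected]
    return scores


def refinement_design(dataset: CallDataset, caller: str, rank_transform: bool = False):
    """Design columns {quality, one indicator per filter} over the caller's candidate set.

    Returns (candidate_mask, X, column_names). The candidate set is every
    union-universe site with extras for this caller (it may exceed the
    caller's final all-filters-passed calls). Zero-variance filter columns
    are dropped with a warning. ``rank_transform`` replaces raw quality by
    its fractional rank, for callers with wild score scales.
    """
    extras = _caller_extras(dataset, caller)
    quality = extras["quality"].to_numpy(dtype=float)
    candidates = np.isfinite(quality)
    detected = dataset.calls[:, dataset.caller_index(caller)].astype(bool)
    if (detected & ~candidates).any():
        raise DataError(f"caller {caller!r} has detections without quality scores")
    q = quality[candidates]
    if rank_transform:
        q = pd.Series(q).rank(pct=True).to_numpy()
    cols = ["quality"]
    blocks = [q]
    for name in [c for c in extras.columns if c != "quality"]:
        flags = extras[name].to_numpy(dtype=float)[candidates]
        if np.isnan(flags).any():
            raise DataError(f"missing filter flag {name!r} inside {caller!r}'s candidate set")
        if not set(np.unique(flags).tolist()) <= {0.0, 1.0}:
            raise DataError(f"filter flags for {name!r} must be 0/1")
        if len(np.unique(flags)) < 2:
            logger.warning("filter %r is constant on %s's candidate set; dropped", name, caller)
            continue
        cols.append(name)
        blocks.append(flags)
    return candidates, np.column_stack(blocks), cols


def fit_refinement(
    train: CallDataset,
    caller: str,
    seed: int = 0,
    rank_transform: bool = False,
    n_lambdas: int = 100,
    folds: int = 10,
    tol: float = 1e-7,
    cv_tol: float = 1e-6,
) -> StackedFit:
    """Fit the quality+filters logistic refinement model for one caller."""
    if train.labels is None:
        raise DataError("refinement training data must carry validation labels")
    candidates, X, cols = refinement_design(train, caller, rank_transform)
    y = train.labels[candidates].astype(float)
    if len(set(y.tolist())) < 2:
        raise DataError("candidate set must contain both validated classes")
    lambdas = default_lambda_path(X, y, n_lambdas)
    path = fit_l1_logistic_path(X, y, lambdas=lambdas, tol=tol)
    lambdas = path["lambdas"]  # path may stop early once the fit saturates
    cv = cross_validate(X, y, lambdas, folds=folds, seed=seed, tol=cv_tol)
    lam_sel, idx = select_lambda_1se(cv["cv_mean_error"], cv["cv_se"], lambdas)
    return StackedFit(
        config=FeatureConfig(include_combo=False, include_genomic=False,
                             include_substitution=False, include_interactions=False),
        caller_names=[caller],
        columns=cols,
        column_groups=["genomic"] * len(cols),
        lambdas=lambdas,
        coef_path=path["coefs"],
        intercept_path=path["intercepts"],
        cv_mean_error=cv["cv_mean_error"],
        cv_se=cv["cv_se"],
        lambda_selected=lam_sel,
        selected_index=idx,
        coefficients=path["coefs"][:, idx].copy(),
        intercept=float(path["intercepts"][idx]),
        medians={},
        missing_indicator_cols=[],
        seed=seed,
    )


def refined_scores(fit: StackedFit, data: CallDataset, rank_transform: bool = False) -> np.ndarray:
    """Refined ranking scores over the union universe for the fitted caller.

    Sites outside the caller's candidate set score ``-inf``. Columns the
    fit dropped (constant in training) are ignored at prediction time.
    """
    caller = fit.caller_names[0]
    candidates, X, cols = refinement_design(data, caller, rank_transform)
    keep = [cols.index(c) for c in fit.columns if c in cols]
    if len(keep) != len(fit.columns):
        missing = [c for c in fit.columns if c not in cols]
        raise DataError(f"new data lacks refinement columns {missing}")
    eta = X[:, keep] @ fit.coefficients + fit.intercept
    scores = np.full(data.n, -np.inf)
    scores[candidates] = eta
    return scores
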
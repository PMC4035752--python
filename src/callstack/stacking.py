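"""Feature-weighted stacking of mutation callers via L1-penalized logistic regression.

The combined caller is a logistic model for P(site is a true somatic
mutation) whose design matrix expands each site into:

* indicators of the caller-combination status (the ``2^K - 1`` mutually
  exclusive detection patterns, all-callers as the reference level),
* numeric genomic features (tumor/normal depth and variant allele fraction),
* indicators of the 12 substitution types (A>C as the reference level),
* all products of the status indicators with the other features.

Letting each caller's weight vary with per-site descriptors is the
feature-weighted linear stacking idea: the product columns make the model
a plain (but wide) logistic regression, so an L1 penalty keeps it sparse.
The penalty weight is chosen by 10-fold cross-validation with the
one-standard-error rule, and the model is then refit on the whole
training set at the chosen weight.

The path solver is a proximal-Newton coordinate descent in the glmnet
style: columns are standardized internally, the intercept is never
penalized, the penalty grid is descending with warm starts, active sets
grow by Karush-Kuhn-Tucker (KKT) violation, and convergence is declared
only when the KKT conditions hold to tolerance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from callstack.data_model import NUMERIC_FEATURES, SUBSTITUTION_TYPES, CallDataset, DataError
from callstack.venn import all_statuses

logger = logging.getLogger(__name__)

_P_CLIP = 1e-9
_W_MIN = 1e-5

try:  # compiled coordinate-descent kernel; pure-python fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class ConvergenceError(RuntimeError):
    """The path solver failed to reach the KKT tolerance."""


@dataclass(frozen=True)
class FeatureConfig:
    """Which column groups enter the design matrix.

    combo_encoding "status" uses the mutually exclusive combination-status
    indicators (no additivity assumption across callers); "marginal" uses
    one indicator per caller, the additive variant.
    """

    include_combo: bool = True
    include_genomic: bool = True
    include_substitution: bool = True
    include_interactions: bool = True
    combo_encoding: str = "status"

    def __post_init__(self) -> None:
        if self.combo_encoding not in ("status", "marginal"):
            raise DataError(f"combo_encoding must be 'status' or 'marginal', got {self.combo_encoding!r}")
        if self.include_interactions and not self.include_combo:
            raise DataError("interaction columns require the combo-status group")
        if self.include_interactions and not (self.include_genomic or self.include_substitution):
            raise DataError("interaction columns require genomic or substitution features")


@dataclass
class DesignMatrix:
    """Named, grouped design columns for the stacking model (no intercept column)."""

    columns: list[str]
    values: np.ndarray
    column_groups: list[str]
    medians: dict[str, float] = field(default_factory=dict)
    missing_indicator_cols: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_design_matrix(
    dataset: CallDataset,
    config: FeatureConfig = FeatureConfig(),
    medians: dict[str, float] | None = None,
    missing_indicator_cols: list[str] | None = None,
) -> DesignMatrix:
    """Expand a dataset into the stacking design matrix.

    With K=3 callers and the default configuration this yields 6 status
    indicators + 4 genomic features + 11 substitution indicators + 6*15
    interaction products = 111 columns (intercept excluded; it is added,
    unpenalized, by the solver).

    Missing numeric features are imputed by the column median and flagged
    with a companion 0/1 missingness-indicator column per affected column.
    When ``medians`` is given (prediction on new data) the stored training
    medians are used and the indicator column set is frozen to
    ``missing_indicator_cols`` so train and test designs align.
    """
    n = dataset.n
    cols: list[str] = []
    groups: list[str] = []
    blocks: list[np.ndarray] = []

    combo_cols: list[str] = []
    combo_vals: np.ndarray | None = None
    if config.include_combo:
        if config.combo_encoding == "status":
            statuses = all_statuses(dataset.caller_names)
            keep = statuses[1:]  # drop the all-callers reference level
            combo_cols = [f"status[{s.label}]" for s in keep]
            masks = np.array([s.mask for s in keep], dtype=np.int8)
            combo_vals = (dataset.calls[:, None, :] == masks[None, :, :]).all(axis=2).astype(float)
        else:
            combo_cols = [f"call[{name}]" for name in dataset.caller_names]
            combo_vals = dataset.calls.astype(float)
        cols += combo_cols
        groups += ["combo_status"] * len(combo_cols)
        blocks.append(combo_vals)

    fitted_medians: dict[str, float] = {}
    missing_cols_seen: list[str] = []
    other_cols: list[str] = []
    other_vals_list: list[np.ndarray] = []

    if config.include_genomic or config.include_substitution or config.include_interactions:
        if dataset.features is None:
            raise DataError("this feature configuration requires per-site genomic features")

    if config.include_genomic:
        for name in NUMERIC_FEATURES:
            raw = dataset.features[name].to_numpy(dtype=float)
            missing = ~np.isfinite(raw)
            if medians is None:
                med = float(np.nanmedian(raw)) if np.isfinite(raw).any() else 0.0
            else:
                med = medians.get(name, 0.0)
            fitted_medians[name] = med
            filled = np.where(missing, med, raw)
            other_cols.append(name)
            other_vals_list.append(filled)
            if missing.any():
                missing_cols_seen.append(name)
        cols += other_cols
        groups += ["genomic"] * len(other_cols)

    if config.include_substitution:
        subs = dataset.features["substitution"].to_numpy()
        unknown = set(subs) - set(SUBSTITUTION_TYPES)
        if unknown:
            raise DataError(f"unknown substitution types {sorted(unknown)}")
        keep = SUBSTITUTION_TYPES[1:]  # drop the A>C reference level
        for s in keep:
            other_cols.append(f"sub[{s}]")
            other_vals_list.append((subs == s).astype(float))
        cols += [f"sub[{s}]" for s in keep]
        groups += ["substitution"] * len(keep)

    other_vals = np.column_stack(other_vals_list) if other_vals_list else np.empty((n, 0))
    blocks.append(other_vals)

    if config.include_interactions and combo_vals is not None and other_vals.shape[1]:
        inter = combo_vals[:, :, None] * other_vals[:, None, :]
        inter = inter.reshape(n, -1)
        inter_cols = [f"{c}*{f}" for c in combo_cols for f in other_cols]
        cols += inter_cols
        groups += ["interaction"] * len(inter_cols)
        blocks.append(inter)

    # missingness indicators last, so the core column layout is stable
    indicator_set = missing_cols_seen if missing_indicator_cols is None else missing_indicator_cols
    for name in indicator_set:
        raw = dataset.features[name].to_numpy(dtype=float)
        cols.append(f"missing[{name}]")
        groups.append("genomic")
        blocks.append((~np.isfinite(raw)).astype(float)[:, None])

    values = np.hstack([b if b.ndim == 2 else b[:, None] for b in blocks]) if blocks else np.empty((n, 0))
    dm = DesignMatrix(
        columns=cols,
        values=values,
        column_groups=groups,
        medians=fitted_medians if medians is None else dict(medians),
        missing_indicator_cols=list(indicator_set),
    )
    _check_indicator_rows(dm, "combo_status")
    _check_indicator_rows(dm, "substitution")
    return dm


def _check_indicator_rows(dm: DesignMatrix, group: str) -> None:
    """Mutually exclusive indicator groups must sum to <= 1 per row.

    Marginal-encoded call columns are not mutually exclusive and are exempt.
    """
    idx = [i for i, g in enumerate(dm.column_groups) if g == group]
    if not idx or (group == "combo_status" and not dm.columns[idx[0]].startswith("status[")):
        return
    if (dm.values[:, idx].sum(axis=1) > 1 + 1e-9).any():
        raise DataError(f"{group} indicator columns must sum to <= 1 per row")


# ---------------------------------------------------------------------------
# L1 logistic path solver


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales < 1e-12, 1.0, scales)
    return (X - means) / scales, means, scales


def _logit(p: float) -> float:
    p = min(max(p, _P_CLIP), 1 - _P_CLIP)
    return float(np.log(p / (1 - p)))


def default_lambda_path(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100,
                        lambda_min_ratio: float | None = None, standardize: bool = True) -> np.ndarray:
    """Descending log-spaced penalty grid from the smallest all-zero penalty.

    ``lambda_max`` is the largest absolute score-gradient component of the
    intercept-only model; above it every penalized coefficient is exactly
    zero. The grid runs down to ``lambda_max * r`` with r = 1e-4 when
    n > L, else 1e-2.
    """
    n, L = X.shape
    Xs = _standardize(X)[0] if standardize else X
    lam_max = float(np.abs(Xs.T @ (y - y.mean())).max())
    lam_max = max(lam_max, 1e-3)
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-4 if n > L else 1e-2
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def _cd_quadratic_py(Xs, w, z_resid, coef, b, lam, active, wx2, inner_tol, max_sweeps):
    """Coordinate descent on the penalized weighted least-squares subproblem.

    ``z_resid`` is the working residual z - X coef - b and is updated in
    place; ``wx2[l] = sum(w * Xs[:,l]^2)``.
    """
    root_n = max(1.0, np.sqrt(len(z_resid)))
    for _ in range(max_sweeps):
        max_delta = 0.0
        for l in active:
            if wx2[l] < 1e-12:
                continue
            xl = Xs[:, l]
            g = xl @ (w * z_resid) + wx2[l] * coef[l]
            new = np.sign(g) * max(abs(g) - lam, 0.0) / wx2[l]
            d = new - coef[l]
            if d != 0.0:
                z_resid -= xl * d
                coef[l] = new
                max_delta = max(max_delta, abs(d) * np.sqrt(wx2[l]))
        sw = w.sum()
        db = (w @ z_resid) / sw
        if db != 0.0:
            z_resid -= db
            b += db
            max_delta = max(max_delta, abs(db) * np.sqrt(sw))
        if max_delta < inner_tol * root_n:
            break
    return b


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _cd_quadratic_jit(Xs, w, z_resid, coef, b, lam, active, wx2, inner_tol, max_sweeps):  # pragma: no cover - compiled
        n = z_resid.shape[0]
        root_n = max(1.0, np.sqrt(n))
        for _ in range(max_sweeps):
            max_delta = 0.0
            for ai in range(active.shape[0]):
                l = active[ai]
                if wx2[l] < 1e-12:
                    continue
                g = wx2[l] * coef[l]
                for i in range(n):
                    g += Xs[i, l] * w[i] * z_resid[i]
                if g > lam:
                    new = (g - lam) / wx2[l]
                elif g < -lam:
                    new = (g + lam) / wx2[l]
                else:
                    new = 0.0
                d = new - coef[l]
                if d != 0.0:
                    for i in range(n):
                        z_resid[i] -= Xs[i, l] * d
                    coef[l] = new
                    step = abs(d) * np.sqrt(wx2[l])
                    if step > max_delta:
                        max_delta = step
            sw = 0.0
            swz = 0.0
            for i in range(n):
                sw += w[i]
                swz += w[i] * z_resid[i]
            db = swz / sw
            if db != 0.0:
                for i in range(n):
                    z_resid[i] -= db
                b += db
                step = abs(db) * np.sqrt(sw)
                if step > max_delta:
                    max_delta = step
            if max_delta < inner_tol * root_n:
                break
        return b


def _cd_quadratic(Xs, w, z_resid, coef, b, lam, active, wx2, inner_tol=1e-8, max_sweeps=1000):
    active = np.asarray(active, dtype=np.int64)
    if _HAVE_NUMBA:
        return _cd_quadratic_jit(Xs, w, z_resid, coef, b, float(lam), active, wx2,
                                 float(inner_tol), int(max_sweeps))
    return _cd_quadratic_py(Xs, w, z_resid, coef, b, lam, active, wx2, inner_tol, max_sweeps)


def _fit_one_lambda(Xs, Xs2, y, lam, coef, b, tol, max_outer=500):
    """Solve one penalty value by proximal Newton with KKT-driven active sets.

    Objective: sum_i log(1 + exp(eta_i)) - y_i eta_i + lam * ||coef||_1,
    eta = Xs coef + b, intercept unpenalized. Convergence when the KKT
    residual (per-sample scale) drops below ``tol``. ``Xs2`` is the
    precomputed elementwise square of ``Xs``.
    """
    n, L = Xs.shape
    for _ in range(max_outer):
        eta = Xs @ coef + b
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Xs.T @ (p - y)  # score gradient of the smooth part
        viol = np.where(coef != 0.0, np.abs(grad + lam * np.sign(coef)), np.maximum(np.abs(grad) - lam, 0.0))
        kkt = max(float(viol.max(initial=0.0)), abs(float(p.sum() - y.sum())))
        if kkt <= tol * n:
            return coef, b, kkt / n
        # working set: currently active coordinates plus KKT violators
        working = np.flatnonzero((coef != 0.0) | (viol > tol * n)).tolist()
        w = np.clip(p * (1.0 - p), _W_MIN, None)
        z_resid = (y - p) / w  # z - eta with z the working response
        wx2 = w @ Xs2
        b = _cd_quadratic(Xs, w, z_resid, coef, b, lam, working, wx2,
                          inner_tol=3.0 * tol, max_sweeps=200)
    raise ConvergenceError(f"no convergence at lambda={lam:.6g} (KKT residual {kkt/n:.3g} > {tol})")


def fit_l1_logistic_path(
    X: np.ndarray | DesignMatrix,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 100,
    lambda_min_ratio: float | None = None,
    standardize: bool = True,
    tol: float = 1e-7,
    devmax: float = 0.999,
    fdev: float = 1e-4,
) -> dict:
    """Fit the L1-penalized logistic model along a descending penalty path.

    Columns are standardized to zero mean and unit variance internally
    before penalization (binary indicators included); returned coefficients
    are on the original scale. The intercept is unpenalized. Warm starts
    carry each solution to the next penalty value.

    As is conventional for penalized path software, the path stops early
    once the model saturates: when the fraction of null deviance explained
    exceeds ``devmax``, or when one penalty step improves it by less than
    ``fdev`` — the remaining penalties would only chase a near-separated,
    statistically useless fit. Set ``devmax=1, fdev=0`` to force the full
    grid. Returned arrays cover only the computed penalties.

    Returns a dict with ``lambdas``, ``coefs`` (L x n_computed, original
    scale), ``intercepts``, ``kkt_residuals`` and ``dev_ratio``.
    """
    if isinstance(X, DesignMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, L = X.shape
    classes = set(np.unique(y).tolist())
    if not classes <= {0.0, 1.0} or len(classes) < 2:
        raise DataError("labels must contain both classes 0 and 1")
    if lambdas is None:
        lambdas = default_lambda_path(X, y, n_lambdas, lambda_min_ratio, standardize)
    lambdas = np.asarray(lambdas, dtype=float)
    if L:
        Xs, means, scales = _standardize(X) if standardize else (X, np.zeros(L), np.ones(L))
    else:
        Xs, means, scales = X, np.zeros(0), np.ones(0)
    Xs = np.asfortranarray(Xs)  # column-contiguous for the coordinate loops
    Xs2 = Xs * Xs

    coef = np.zeros(L)
    b = _logit(float(y.mean()))
    null_dev = binomial_deviance(y, np.full(n, y.mean()))
    coefs = np.zeros((L, len(lambdas)))
    intercepts = np.zeros(len(lambdas))
    kkts = np.zeros(len(lambdas))
    dev_ratio = np.zeros(len(lambdas))
    prev_ratio = 0.0
    n_done = 0
    for j, lam in enumerate(lambdas):
        coef, b, kkts[j] = _fit_one_lambda(Xs, Xs2, y, lam, coef, b, tol)
        coefs[:, j] = coef / scales
        intercepts[j] = b - float((coef / scales) @ means)
        p = 1.0 / (1.0 + np.exp(-(Xs @ coef + b)))
        dev_ratio[j] = 1.0 - binomial_deviance(y, p) / null_dev
        n_done = j + 1
        # saturation rules: nearly all deviance explained, or a step that
        # improved the fit by a negligible fraction of what is explained
        if dev_ratio[j] > devmax or (j > 0 and dev_ratio[j] - prev_ratio < fdev * dev_ratio[j]):
            break
        prev_ratio = dev_ratio[j]
    sl = slice(0, n_done)
    return {
        "lambdas": lambdas[sl],
        "coefs": coefs[:, sl],
        "intercepts": intercepts[sl],
        "kkt_residuals": kkts[sl],
        "dev_ratio": dev_ratio[sl],
    }


def kkt_violation(X, y, intercept: float, coef: np.ndarray, lam: float, standardize: bool = True) -> float:
    """Max KKT residual of a solution, per sample, in the solver's standardized space.

    Zero coefficients require |gradient| <= lam; nonzero ones require
    gradient = -lam * sign(coef). Useful as an independent optimality check.
    """
    if isinstance(X, DesignMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, L = X.shape
    Xs, means, scales = _standardize(X) if standardize else (X, np.zeros(L), np.ones(L))
    coef_std = np.asarray(coef) * scales
    b_std = intercept + float(np.asarray(coef) @ means)
    p = 1.0 / (1.0 + np.exp(-(Xs @ coef_std + b_std)))
    grad = Xs.T @ (p - y)
    viol = np.where(coef_std != 0.0, np.abs(grad + lam * np.sign(coef_std)), np.maximum(np.abs(grad) - lam, 0.0))
    return max(float(viol.max(initial=0.0)), abs(float(p.sum() - y.sum()))) / n


# ---------------------------------------------------------------------------
# cross-validation and penalty selection


def binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, -2 * mean log-likelihood."""
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def cross_validate(
    X: np.ndarray | DesignMatrix,
    y: np.ndarray,
    lambdas: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    tol: float = 1e-6,
    max_fold_retries: int = 10,
) -> dict:
    """Per-penalty mean and standard error of held-out binomial deviance.

    Folds are stratified by label and drawn from ``seed``; a degenerate
    single-class fold triggers a re-draw with a derived seed, up to
    ``max_fold_retries`` times.
    """
    if isinstance(X, DesignMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < folds:
        raise DataError(f"need at least {folds} sites for {folds}-fold cross-validation")
    for attempt in range(max_fold_retries):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(seed + 100003 * attempt) % 2**31)
        splits = list(splitter.split(X, y))
        if all(len(np.unique(y[tr])) == 2 and len(y[te]) > 0 for tr, te in splits):
            break
    else:
        raise DataError("could not draw folds with both classes present in every training fold")

    errors = np.zeros((folds, len(lambdas)))
    for f, (tr, te) in enumerate(splits):
        path = fit_l1_logistic_path(X[tr], y[tr], lambdas=lambdas, standardize=standardize, tol=tol)
        coefs, intercepts = path["coefs"], path["intercepts"]
        if coefs.shape[1] < len(lambdas):  # fold path saturated early: carry the last fit forward
            pad = len(lambdas) - coefs.shape[1]
            coefs = np.hstack([coefs, np.repeat(coefs[:, -1:], pad, axis=1)])
            intercepts = np.concatenate([intercepts, np.repeat(intercepts[-1], pad)])
        eta = X[te] @ coefs + intercepts[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        errors[f] = [binomial_deviance(y[te], p[:, j]) for j in range(len(lambdas))]
    return {
        "lambdas": lambdas,
        "cv_mean_error": errors.mean(axis=0),
        "cv_se": errors.std(axis=0, ddof=1) / np.sqrt(folds),
        "fold_errors": errors,
    }


def select_lambda_1se(cv_mean_error: np.ndarray, cv_se: np.ndarray, lambdas: np.ndarray) -> tuple[float, int]:
    """One-standard-error rule: the largest penalty whose CV error is within
    one standard error of the minimum — the most parsimonious model that is
    statistically indistinguishable from the best one.

    Returns (lambda, index into the descending path).
    """
    cv_mean_error = np.asarray(cv_mean_error, dtype=float)
    if not (len(cv_mean_error) == len(cv_se) == len(lambdas)):
        raise DataError("CV arrays must align with the penalty path")
    i_min = int(np.argmin(cv_mean_error))
    threshold = cv_mean_error[i_min] + np.asarray(cv_se)[i_min]
    order = np.argsort(-np.asarray(lambdas))  # largest penalty first
    for i in order:
        if cv_mean_error[i] <= threshold:
            return float(lambdas[i]), int(i)
    return float(lambdas[i_min]), i_min  # unreachable: the minimizer always qualifies


# ---------------------------------------------------------------------------
# the full stacked caller


@dataclass
class StackedFit:
    """A fitted stacked caller: penalty path, CV curve, and the selected model."""

    config: FeatureConfig
    caller_names: list[str]
    columns: list[str]
    column_groups: list[str]
    lambdas: np.ndarray
    coef_path: np.ndarray
    intercept_path: np.ndarray
    cv_mean_error: np.ndarray
    cv_se: np.ndarray
    lambda_selected: float
    selected_index: int
    coefficients: np.ndarray
    intercept: float
    medians: dict[str, float]
    missing_indicator_cols: list[str]
    seed: int

    @property
    def support(self) -> list[str]:
        return [c for c, g in zip(self.columns, self.coefficients) if g != 0.0]

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "caller_names": self.caller_names,
            "columns": self.columns,
            "column_groups": self.column_groups,
            "lambdas": self.lambdas.tolist(),
            "coef_path": self.coef_path.tolist(),
            "intercept_path": self.intercept_path.tolist(),
            "cv_mean_error": self.cv_mean_error.tolist(),
            "cv_se": self.cv_se.tolist(),
            "lambda_selected": self.lambda_selected,
            "selected_index": self.selected_index,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "medians": self.medians,
            "missing_indicator_cols": self.missing_indicator_cols,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StackedFit":
        with open(path) as fh:
            d = json.load(fh)
        d["config"] = FeatureConfig(**d["config"])
        for key in ("lambdas", "coef_path", "intercept_path", "cv_mean_error", "cv_se", "coefficients"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def fit_stacked_caller(
    train: CallDataset,
    config: FeatureConfig = FeatureConfig(),
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float | None = None,
    folds: int = 10,
    tol: float = 1e-7,
    cv_tol: float = 1e-6,
) -> StackedFit:
    """Fit the full stacked caller on labeled training data.

    Pipeline: build the design matrix, fit the penalty path on all training
    sites, estimate per-penalty error by stratified ``folds``-fold CV,
    choose the penalty by the one-standard-error rule, and report the
    whole-training-set coefficients at that penalty.
    """
    if train.labels is None:
        raise DataError("training data must carry validation labels")
    dm = build_design_matrix(train, config)
    y = train.labels.astype(float)
    lambdas = default_lambda_path(dm.values, y, n_lambdas, lambda_min_ratio)
    path = fit_l1_logistic_path(dm.values, y, lambdas=lambdas, tol=tol)
    lambdas = path["lambdas"]  # path may stop early once the fit saturates
    cv = cross_validate(dm.values, y, lambdas, folds=folds, seed=seed, tol=cv_tol)
    lam_sel, idx = select_lambda_1se(cv["cv_mean_error"], cv["cv_se"], lambdas)
    return StackedFit(
        config=config,
        caller_names=list(train.caller_names),
        columns=dm.columns,
        column_groups=dm.column_groups,
        lambdas=lambdas,
        coef_path=path["coefs"],
        intercept_path=path["intercepts"],
        cv_mean_error=cv["cv_mean_error"],
        cv_se=cv["cv_se"],
        lambda_selected=lam_sel,
        selected_index=idx,
        coefficients=path["coefs"][:, idx].copy(),
        intercept=float(path["intercepts"][idx]),
        medians=dm.medians,
        missing_indicator_cols=dm.missing_indicator_cols,
        seed=seed,
    )


def predict_proba(fit: StackedFit, data: CallDataset) -> np.ndarray:
    """Predicted probability that each site is a true somatic mutation."""
    if list(data.caller_names) != list(fit.caller_names):
        raise DataError(
            f"caller names {data.caller_names} do not match the fitted model's {fit.caller_names}"
        )
    dm = build_design_matrix(data, fit.config, medians=fit.medians,
                             missing_indicator_cols=fit.missing_indicator_cols)
    if dm.columns != fit.columns:
        raise DataError("design columns of new data do not align with the fitted model")
    eta = dm.values @ fit.coefficients + fit.intercept
    return 1.0 / (1.0 + np.exp(-eta))
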
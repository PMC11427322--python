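"""Lasso-based restorativeness modeling.

The statistical chain mirrors the study protocol: standardize all predictors
(sample-SD z-scores over the full photo set), iteratively prune
multicollinear indicators by variance inflation factor (VIF < 5, with
√greenery protected from elimination), hold out a random test split
(10 of 60 photos), choose the lasso penalty by 10-fold cross-validation with
the one-standard-error rule, and evaluate train/test RMSE.

The public surface has two layers:

* free functions implementing each step (:func:`standardize`,
  :func:`compute_vif`, :func:`vif_prune`, :func:`split_train_test`,
  :func:`cv_lasso`, :func:`fit_lasso`, :func:`evaluate_rmse`,
  :func:`apply_model`, :func:`sqrt_greenery_correlations`), plus the
  published coefficient tables via :func:`published_models`;
* a Model/Results pair, :class:`RestorativenessLasso` /
  :class:`RestorativenessLassoResults`, that composes the chain end to end.

Objective convention: the lasso minimises (1/2n)·Σ(y − ŷ)² + λ·Σ|β| with an
unpenalised intercept, so λ values are comparable across sample sizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression

from restoview.exceptions import ValidationError
from restoview.psychometrics import correlate

__all__ = [
    "Standardization",
    "VIFReport",
    "SplitSpec",
    "CVResult",
    "LassoModelSpec",
    "standardize",
    "compute_vif",
    "vif_prune",
    "split_train_test",
    "lambda_grid_from_data",
    "cv_lasso",
    "fit_lasso",
    "evaluate_rmse",
    "apply_model",
    "published_models",
    "sqrt_greenery_correlations",
    "RestorativenessLasso",
    "RestorativenessLassoResults",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Standardization:
    """Per-column means and sample SDs used to map raw features to z-scores."""

    means: pd.Series
    sds: pd.Series

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.means.index)
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValidationError(f"feature matrix missing columns {missing}")
        return (X[cols] - self.means) / self.sds

    def to_dict(self) -> dict:
        return {"means": self.means.to_dict(), "sds": self.sds.to_dict()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Standardization":
        return cls(pd.Series(d["means"], dtype=float), pd.Series(d["sds"], dtype=float))


@dataclass
class VIFReport:
    """Final VIFs, the ordered removal trace, and the retained feature set."""

    vifs: pd.Series
    removal_trace: list  # [(feature, vif at removal), ...]
    retained: list

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removal_trace, columns=["removed", "vif"])


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValidationError("train and test ids overlap")


@dataclass
class CVResult:
    """Cross-validation curve and the two canonical penalty choices."""

    lambda_grid: np.ndarray  # decreasing
    mean_rmse: np.ndarray
    se_rmse: np.ndarray
    lambda_min: float
    lambda_1se: float
    n_folds: int
    seed: int

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambda_grid, "mean_rmse": self.mean_rmse, "se_rmse": self.se_rmse}
        )


@dataclass
class LassoModelSpec:
    """A fitted or published lasso model on the standardized feature scale."""

    outcome: str
    intercept: float
    coefficients: dict  # feature -> coefficient (standardized scale)
    lam: float | None = None
    standardization: Standardization | None = None
    provenance: str = "fitted"  # or "published"

    @property
    def nonzero_coefficients(self) -> dict:
        return {k: v for k, v in self.coefficients.items() if v != 0.0}

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "lambda": self.lam,
            "standardization": None
            if self.standardization is None
            else self.standardization.to_dict(),
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "LassoModelSpec":
        std = d.get("standardization")
        return cls(
            outcome=d["outcome"],
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            lam=None if d.get("lambda") is None else float(d["lambda"]),
            standardization=None if std is None else Standardization.from_dict(std),
            provenance=d.get("provenance", "fitted"),
        )

    @classmethod
    def from_json(cls, path) -> "LassoModelSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# steps


def standardize(X: pd.DataFrame):
    """Column z-scores with the sample-SD (n-1) convention.

    Returns ``(Z, Standardization)``; the stored parameters are reused to map
    new raw features onto the training scale.
    """
    X = X.astype(float)
    if X.isna().any().any():
        raise ValidationError("feature matrix contains missing cells")
    sds = X.std(ddof=1)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValidationError(f"zero-variance columns cannot be standardized: {zero}")
    means = X.mean()
    std = Standardization(means, sds)
    return std.apply(X), std


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R²) of column j
    regressed (with intercept) on all other columns.  Perfect collinearity
    reports +inf rather than raising."""
    X = X.astype(float)
    n, p = X.shape
    if p < 2:
        raise ValidationError("VIF needs at least two columns")
    if n <= p + 1:
        raise ValidationError(f"VIF needs more rows ({n}) than columns + 1 ({p + 1})")
    arr = X.to_numpy()
    if np.any(arr.std(axis=0) == 0):
        raise ValidationError("constant columns have undefined VIF")
    vifs = {}
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vifs[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def vif_prune(
    X: pd.DataFrame, threshold: float = 5.0, protected: Iterable[str] = ()
) -> VIFReport:
    """Iteratively drop the highest-VIF non-protected column until all
    retained columns have VIF < threshold.

    Protected columns are never removed (even above threshold) but still count
    as regressors.  Ties on the maximum VIF break by column order.
    """
    protected = set(protected)
    unknown = protected - set(X.columns)
    if unknown:
        raise ValidationError(f"protected features not in matrix: {sorted(unknown)}")
    current = X.copy()
    trace: list = []
    while True:
        if current.shape[1] < 2:
            # a lone column is trivially free of collinearity
            vifs = pd.Series(1.0, index=current.columns)
            break
        vifs = compute_vif(current)
        candidates = [c for c in current.columns if c not in protected]
        if not candidates:
            break
        cand_vifs = vifs[candidates]
        worst = cand_vifs.idxmax()  # first occurrence wins ties
        if cand_vifs[worst] < threshold:
            break
        trace.append((worst, float(cand_vifs[worst])))
        current = current.drop(columns=[worst])
    return VIFReport(vifs=vifs, removal_trace=trace, retained=list(current.columns))


def split_train_test(ids: Sequence, n_test: int = 10, seed: int = 0) -> SplitSpec:
    """Uniform random test holdout without replacement; deterministic per seed."""
    ids = list(ids)
    if n_test >= len(ids):
        raise ValidationError(f"n_test={n_test} must be smaller than the number of ids ({len(ids)})")
    rng = np.random.default_rng(seed)
    test_pos = set(rng.choice(len(ids), size=n_test, replace=False).tolist())
    train = tuple(x for i, x in enumerate(ids) if i not in test_pos)
    test = tuple(x for i, x in enumerate(ids) if i in test_pos)
    return SplitSpec(train_ids=train, test_ids=test, seed=seed)


def lambda_grid_from_data(
    X: pd.DataFrame, y: Sequence[float], n_lambdas: int = 100, eps: float = 1e-4
) -> np.ndarray:
    """Decreasing log-spaced grid from λ_max (all coefficients zero) down to
    eps·λ_max; λ_max = max_j |x_jᵀ(y - ȳ)| / n under the (1/2n) objective."""
    arr = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    lam_max = float(np.max(np.abs(arr.T @ (yv - yv.mean())))) / n
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, eps * lam_max, n_lambdas)


def fit_lasso(X: pd.DataFrame, y: Sequence[float], lam: float,
              outcome: str = "y", standardization: Standardization | None = None) -> LassoModelSpec:
    """Lasso fit at a fixed penalty under the (1/2n) objective.

    λ = 0 reduces to ordinary least squares.  Coefficients are stored for all
    columns of X (zeros included) on the scale X was supplied in.
    """
    arr = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(arr)) and np.all(np.isfinite(yv))):
        raise ValidationError("non-finite values in the design or outcome")
    if lam < 0:
        raise ValidationError("lambda must be nonnegative")
    if lam == 0:
        est = LinearRegression().fit(arr, yv)
    else:
        est = Lasso(alpha=lam, fit_intercept=True, tol=1e-10, max_iter=200000).fit(arr, yv)
    coefs = {c: float(b) for c, b in zip(X.columns, np.atleast_1d(est.coef_))}
    return LassoModelSpec(
        outcome=outcome,
        intercept=float(est.intercept_),
        coefficients=coefs,
        lam=float(lam),
        standardization=standardization,
    )


def _fold_indices(n: int, k: int, seed: int) -> list:
    """Seeded shuffle then contiguous blocks."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, k)]


def cv_lasso(
    X: pd.DataFrame,
    y: Sequence[float],
    lambda_grid: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """K-fold cross-validated lasso curve with the one-standard-error rule.

    For each λ the model is fitted on k-1 folds and scored by RMSE on the
    held-out fold; the curve reports the across-fold mean and standard error
    (SD/√k).  ``lambda_min`` minimises the mean RMSE; ``lambda_1se`` is the
    largest λ whose mean RMSE is within one standard error of that minimum.
    """
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < k:
        raise ValidationError(f"need at least k={k} rows, got {n}")
    if lambda_grid is None:
        lambda_grid = lambda_grid_from_data(X, yv)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(lambda_grid) >= 0):
        raise ValidationError("lambda grid must be strictly decreasing")
    arr = X.to_numpy(dtype=float)
    folds = _fold_indices(n, k, seed)
    rmse = np.empty((k, len(lambda_grid)))
    for fi, val_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        Xtr, ytr = arr[mask], yv[mask]
        Xva, yva = arr[~mask], yv[~mask]
        est = Lasso(alpha=lambda_grid[0], fit_intercept=True, tol=1e-10,
                    max_iter=200000, warm_start=True)
        for li, lam in enumerate(lambda_grid):
            est.set_params(alpha=lam)
            est.fit(Xtr, ytr)
            pred = est.predict(Xva)
            rmse[fi, li] = math.sqrt(float(np.mean((yva - pred) ** 2)))
    mean_rmse = rmse.mean(axis=0)
    se_rmse = rmse.std(axis=0, ddof=1) / math.sqrt(k)
    i_min = int(np.argmin(mean_rmse))
    bound = mean_rmse[i_min] + se_rmse[i_min]
    i_1se = int(np.nonzero(mean_rmse <= bound)[0][0])  # grid decreasing: first = largest λ
    return CVResult(
        lambda_grid=lambda_grid,
        mean_rmse=mean_rmse,
        se_rmse=se_rmse,
        lambda_min=float(lambda_grid[i_min]),
        lambda_1se=float(lambda_grid[i_1se]),
        n_folds=k,
        seed=seed,
    )


def apply_model(model: LassoModelSpec, z: Mapping) -> float:
    """Predict from standardized feature values: intercept + Σ βⱼ·zⱼ."""
    total = model.intercept
    for name, beta in model.coefficients.items():
        if name not in z:
            raise ValidationError(f"feature {name!r} missing from input vector")
        total += beta * float(z[name])
    return float(total)


def evaluate_rmse(model: LassoModelSpec, X: pd.DataFrame, y: Sequence[float]) -> float:
    """Root-mean-square prediction error.

    If the model carries standardization parameters, raw features are mapped
    to z-scores first; otherwise X is taken to be standardized already.
    """
    missing = [c for c in model.coefficients if c not in X.columns]
    if missing:
        raise ValidationError(f"feature matrix missing model columns {missing}")
    Z = model.standardization.apply(X) if model.standardization is not None else X
    yv = np.asarray(y, dtype=float)
    names = list(model.coefficients)
    betas = np.array([model.coefficients[c] for c in names])
    if names:
        pred = model.intercept + Z[names].to_numpy(dtype=float) @ betas
    else:
        pred = np.full(len(yv), model.intercept)
    return math.sqrt(float(np.mean((yv - pred) ** 2)))


def published_models() -> dict:
    """The four published coefficient tables (standardized scale).

    Overall restorativeness has four nonzero coefficients, Being Away three,
    Fascination four, Extent none (intercept-only at 2.928); the color-fractal
    coefficient is negative in every model that includes it.
    """
    payload = json.loads(
        resources.files("restoview.data").joinpath("published_models.json").read_text("utf-8")
    )
    out = {}
    for name, d in payload.items():
        out[name] = LassoModelSpec(
            outcome=d["outcome"],
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            lam=None,
            provenance="published",
        )
    return out


def published_rmse() -> pd.DataFrame:
    """Published train/test RMSE per outcome, for reference alongside the models."""
    payload = json.loads(
        resources.files("restoview.data").joinpath("published_models.json").read_text("utf-8")
    )
    return pd.DataFrame(
        {
            name: {"rmse_train": d["rmse_train"], "rmse_test": d["rmse_test"]}
            for name, d in payload.items()
        }
    ).T


def sqrt_greenery_correlations(
    features: pd.DataFrame, photo_scores: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between (√greenery, raw greenery) and each photo-mean score.

    ``features`` is indexed by photo id with a ``sqrt_greenery`` column;
    ``photo_scores`` is the per-photo summary with ``*_mean`` columns.  Both
    transforms are reported so the improvement from the square root is
    inspectable.
    """
    scores = photo_scores.set_index("photo_id") if "photo_id" in photo_scores.columns else photo_scores
    common = features.index.intersection(scores.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 matched photos")
    g_sqrt = features.loc[common, "sqrt_greenery"]
    g_raw = g_sqrt**2
    rows = {}
    for score in ("overall", "being_away", "fascination", "extent"):
        col = f"{score}_mean"
        if col not in scores.columns:
            continue
        y = scores.loc[common, col]
        rows[score] = {
            "r_sqrt_greenery": correlate(g_sqrt, y),
            "r_raw_greenery": correlate(g_raw, y),
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Model / Results


class RestorativenessLasso:
    """Cross-validated lasso linking visual properties to photo-level scores.

    Parameters
    ----------
    features : DataFrame indexed by photo id, one column per indicator.
    photo_scores : per-photo summary (``photo_id`` column plus ``*_mean``
        columns) or a Series of outcomes indexed by photo id.
    outcome : which score to model (``overall``, ``being_away``,
        ``fascination`` or ``extent``).
    protected : features exempt from VIF elimination (default: √greenery).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        photo_scores,
        outcome: str = "overall",
        protected: Iterable[str] = ("sqrt_greenery",),
        vif_threshold: float = 5.0,
        n_test: int = 10,
        n_folds: int = 10,
        lambda_grid: np.ndarray | None = None,
    ) -> None:
        if isinstance(photo_scores, pd.Series):
            y = photo_scores.astype(float)
        else:
            tbl = (
                photo_scores.set_index("photo_id")
                if "photo_id" in photo_scores.columns
                else photo_scores
            )
            col = f"{outcome}_mean" if f"{outcome}_mean" in tbl.columns else outcome
            if col not in tbl.columns:
                raise ValidationError(f"photo_scores has no column for outcome {outcome!r}")
            y = tbl[col].astype(float)
        common = features.index.intersection(y.index)
        if len(common) < max(3, n_folds):
            raise ValidationError("too few matched photos for modeling")
        missing = set(features.index).symmetric_difference(y.index)
        if missing:
            raise ValidationError(f"unmatched photo ids between features and scores: {sorted(missing)[:5]}")
        self.features = features.loc[common].astype(float)
        self.y = y.loc[common]
        self.outcome = outcome
        self.protected = tuple(protected)
        self.vif_threshold = float(vif_threshold)
        self.n_test = int(n_test)
        self.n_folds = int(n_folds)
        self.lambda_grid = lambda_grid

    @classmethod
    def from_dataframes(cls, features, photo_scores, **kwargs) -> "RestorativenessLasso":
        return cls(features, photo_scores, **kwargs)

    def fit(self, seed: int) -> "RestorativenessLassoResults":
        """Run the full chain; ``seed`` drives the split and fold assignment."""
        Z, std = standardize(self.features)
        vif_report = vif_prune(Z, threshold=self.vif_threshold, protected=self.protected)
        Zr = Z[vif_report.retained]
        split = split_train_test(list(Zr.index), n_test=self.n_test, seed=seed)
        Ztr = Zr.loc[list(split.train_ids)]
        ytr = self.y.loc[list(split.train_ids)]
        grid = self.lambda_grid
        if grid is None:
            grid = lambda_grid_from_data(Ztr, ytr)
        cv = cv_lasso(Ztr, ytr, lambda_grid=grid, k=self.n_folds, seed=seed)
        model = fit_lasso(Ztr, ytr, cv.lambda_1se, outcome=self.outcome, standardization=std)
        rmse_train = evaluate_rmse(model, self.features.loc[list(split.train_ids)], ytr)
        rmse_test = (
            evaluate_rmse(
                model,
                self.features.loc[list(split.test_ids)],
                self.y.loc[list(split.test_ids)],
            )
            if split.test_ids
            else float("nan")
        )
        return RestorativenessLassoResults(
            model=self,
            model_spec=model,
            vif_report=vif_report,
            split=split,
            cv_result=cv,
            rmse_train=rmse_train,
            rmse_test=rmse_test,
        )


@dataclass
class RestorativenessLassoResults:
    """Fitted-chain results: selected model, CV curve, VIF trace, RMSEs."""

    model: RestorativenessLasso
    model_spec: LassoModelSpec
    vif_report: VIFReport
    split: SplitSpec
    cv_result: CVResult
    rmse_train: float
    rmse_test: float

    @property
    def params(self) -> pd.Series:
        """Intercept and coefficients on the standardized scale."""
        return pd.Series({"intercept": self.model_spec.intercept, **self.model_spec.coefficients})

    @property
    def selected_features(self) -> list:
        return sorted(self.model_spec.nonzero_coefficients)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        Z = self.model_spec.standardization.apply(features)
        names = list(self.model_spec.coefficients)
        betas = np.array([self.model_spec.coefficients[c] for c in names])
        pred = self.model_spec.intercept + Z[names].to_numpy(dtype=float) @ betas
        return pd.Series(pred, index=features.index, name=f"{self.model.outcome}_pred")

    def summary(self) -> str:
        spec = self.model_spec
        lines = [
            f"Restorativeness lasso — outcome: {self.model.outcome}",
            "=" * 52,
            f"photos: {len(self.model.y)}  (train {len(self.split.train_ids)}, "
            f"test {len(self.split.test_ids)}; split seed {self.split.seed})",
            f"VIF pruning: threshold {self.model.vif_threshold}, "
            f"removed {len(self.vif_report.removal_trace)}, "
            f"retained {len(self.vif_report.retained)} "
            f"(protected: {', '.join(self.model.protected)})",
            f"CV: {self.cv_result.n_folds}-fold, lambda_min = {self.cv_result.lambda_min:.5f}, "
            f"lambda_1se = {self.cv_result.lambda_1se:.5f}",
            "",
            f"{'term':<34}{'coef (std. scale)':>18}",
            "-" * 52,
            f"{'intercept':<34}{spec.intercept:>18.3f}",
        ]
        for name, beta in spec.coefficients.items():
            if beta != 0.0:
                lines.append(f"{name:<34}{beta:>18.3f}")
        n_zero = sum(1 for b in spec.coefficients.values() if b == 0.0)
        if n_zero:
            lines.append(f"({n_zero} coefficients shrunk to zero)")
        lines += [
            "-" * 52,
            f"RMSE (train) {self.rmse_train:.3f}   RMSE (test) {self.rmse_test:.3f}",
        ]
        return "\n".join(lines)

    def plot_cv_curve(self, ax=None):
        """CV RMSE versus λ with the min and 1-SE choices marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cv = self.cv_result
        ax.errorbar(cv.lambda_grid, cv.mean_rmse, yerr=cv.se_rmse, fmt="o-", ms=2, lw=0.8)
        ax.axvline(cv.lambda_min, ls="--", color="gray", label="lambda_min")
        ax.axvline(cv.lambda_1se, ls=":", color="black", label="lambda_1se")
        ax.set_xscale("log")
        ax.set_xlabel("lambda")
        ax.set_ylabel("CV RMSE")
        ax.legend()
        return ax
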
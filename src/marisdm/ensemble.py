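"""Ten-algorithm ensemble habitat-suitability modelling.

Presence / pseudo-absence training data are fit with ten algorithms spanning
the model families commonly combined in ecological niche modelling — linear
(GLM), additive (GAM), spline (MARS), entropy/background (MAXNET),
discriminant (FDA), single tree (CTA), bagged trees (RF), boosted trees
(GBM, XGBOOST) and neural network (ANN). Model quality is judged per run on
a held-out fold using the true skill statistic (TSS = sensitivity +
specificity - 1), the critical success index (CSI = TP/(TP+FP+FN)) and the
rank-based AUC. Runs with TSS above 0.6 enter the ensemble, which reports
the unweighted mean suitability, the committee average (fraction of retained
runs voting presence at each run's own TSS-maximizing threshold) and the
per-cell coefficient of variation.

Cross-validation is blocked in environmental space: with more than 1000
unique environments, each modelling variable in turn defines five quantile
strata (computed per class, so presences and absences stay balanced), giving
``n_variables x 5`` runs per algorithm; smaller problems fall back to
repeated random 5-fold CV (3 repeats). Presences carry 70% of the total
case weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import FeatureUnion, Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

ALGORITHMS = ("glm", "gam", "rf", "ann", "fda", "cta", "gbm", "maxnet", "xgboost", "mars")

DEFAULT_PREVALENCE = 0.7
TSS_GATE = 0.6
N_FOLDS = 5
N_REPEATS = 3
ENV_CV_MIN_UNIQUE = 1000

#: algorithms whose ``fit`` does not accept sample_weight; the prevalence
#: weighting is applied through seeded weighted resampling instead
_RESAMPLE_WEIGHTED = frozenset({"ann", "fda"})


class EvaluationError(ValueError):
    pass


class EnsembleError(RuntimeError):
    pass


@dataclass
class TrainingSet:
    """Environment matrix + presence/pseudo-absence labels + case weights."""

    X: pd.DataFrame
    y: np.ndarray  # 1 presence, 0 pseudo-absence
    prevalence: float = DEFAULT_PREVALENCE
    weights: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.X.isna().any().any():
            raise ValueError("training environments contain missing values")
        if self.weights is None:
            self.weights = self._prevalence_weights()

    def _prevalence_weights(self) -> np.ndarray:
        n_pres = int(self.y.sum())
        n_abs = len(self.y) - n_pres
        w = np.empty(len(self.y))
        if n_pres:
            w[self.y == 1] = self.prevalence / n_pres
        if n_abs:
            w[self.y == 0] = (1 - self.prevalence) / n_abs
        return w * len(self.y)  # scale to mean ~1 for solver comfort

    @property
    def variables(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class FoldAssignment:
    """One train/test split: ``label`` names the stratifying variable (env CV)
    or the repeat (random CV); ``test_mask`` marks held-out rows."""

    label: str
    fold_id: int
    test_mask: np.ndarray = field(repr=False)


@dataclass
class ModelRun:
    algorithm_id: str
    label: str
    fold_id: int
    estimator: object = field(repr=False, default=None)
    tss: float = np.nan
    auc: float = np.nan
    csi: float = np.nan
    threshold: float = np.nan
    failed: bool = False

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Suitability in [0, 1] for each row."""
        p = self.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]
        return np.clip(p, 0.0, 1.0)


def _quantile_folds(values: np.ndarray, n_folds: int) -> np.ndarray:
    """Fold id by quantile block of ``values`` (near-equal block sizes)."""
    order = np.argsort(values, kind="stable")
    folds = np.empty(len(values), dtype=int)
    folds[order] = (np.arange(len(values)) * n_folds) // len(values)
    return folds


def make_folds(training: TrainingSet, n_unique_env: int) -> list[FoldAssignment]:
    """Build the cross-validation plan.

    With > 1000 unique environments, each variable defines 5 quantile-block
    folds (stratified within class, so every fold holds both presences and
    absences); otherwise random stratified 5-fold CV repeated 3 times.
    """
    if len(training.y) == 0:
        raise ValueError("empty training set")
    y = training.y
    plan: list[FoldAssignment] = []
    if n_unique_env > ENV_CV_MIN_UNIQUE:
        for var in training.variables:
            v = training.X[var].to_numpy(float)
            folds = np.empty(len(y), dtype=int)
            for cls in (0, 1):
                idx = np.flatnonzero(y == cls)
                if idx.size < N_FOLDS:
                    raise EnsembleError(
                        f"class {cls} has fewer rows than folds; cannot stratify"
                    )
                folds[idx] = _quantile_folds(v[idx], N_FOLDS)
            for k in range(N_FOLDS):
                plan.append(FoldAssignment(var, k, folds == k))
    else:
        rng = np.random.default_rng(0)
        for rep in range(N_REPEATS):
            folds = np.empty(len(y), dtype=int)
            for cls in (0, 1):
                idx = np.flatnonzero(y == cls)
                if idx.size < N_FOLDS:
                    raise EnsembleError(
                        f"class {cls} has fewer rows than folds; cannot stratify"
                    )
                folds[idx] = _quantile_folds(rng.random(idx.size), N_FOLDS)
            for k in range(N_FOLDS):
                plan.append(FoldAssignment(f"rep{rep + 1}", k, folds == k))
    for fa in plan:
        for mask in (fa.test_mask, ~fa.test_mask):
            if len(np.unique(y[mask])) < 2:
                raise EnsembleError(
                    f"fold ({fa.label}, {fa.fold_id}) lacks one of the classes"
                )
    return plan


def _spline_hinges(n_knots=5):
    # degree-1 splines on quantile knots = piecewise-linear hinge basis
    return SplineTransformer(
        n_knots=n_knots, degree=1, knots="quantile", include_bias=False
    )


def build_estimator(algorithm_id: str, seed: int = 0):
    """A fresh estimator pipeline for the given algorithm id.

    Each pipeline exposes ``predict_proba`` and (except where noted in the
    methods note) accepts per-row case weights at fit time.
    """
    if algorithm_id == "glm":
        # logistic GLM with linear + quadratic terms
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                ("clf", LogisticRegression(max_iter=2000)),
            ]
        )
    if algorithm_id == "gam":
        # additive model: per-variable cubic spline basis, no interactions
        return Pipeline(
            [
                ("spline", SplineTransformer(n_knots=6, degree=3, knots="quantile")),
                ("clf", LogisticRegression(max_iter=2000)),
            ]
        )
    if algorithm_id == "rf":
        return RandomForestClassifier(
            n_estimators=100, min_samples_leaf=2, random_state=seed, n_jobs=1
        )
    if algorithm_id == "ann":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    MLPClassifier(
                        hidden_layer_sizes=(8,),
                        max_iter=600,
                        random_state=seed,
                        early_stopping=False,
                    ),
                ),
            ]
        )
    if algorithm_id == "fda":
        # discriminant-analysis family on an expanded basis
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                ("clf", LinearDiscriminantAnalysis()),
            ]
        )
    if algorithm_id == "cta":
        return DecisionTreeClassifier(
            max_depth=6, min_samples_leaf=5, random_state=seed
        )
    if algorithm_id == "gbm":
        return GradientBoostingClassifier(
            n_estimators=100, learning_rate=0.1, max_depth=3, random_state=seed
        )
    if algorithm_id == "maxnet":
        # maxent-style: L1-penalized logistic over linear, quadratic and
        # hinge features
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "feats",
                    FeatureUnion(
                        [
                            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                            ("hinge", _spline_hinges()),
                        ]
                    ),
                ),
                (
                    "clf",
                    LogisticRegression(
                        l1_ratio=1.0, solver="liblinear", C=1.0, max_iter=2000
                    ),
                ),
            ]
        )
    if algorithm_id == "xgboost":
        return XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            verbosity=0,
            n_jobs=1,
            eval_metric="logloss",
        )
    if algorithm_id == "mars":
        # adaptive-spline family: hinge basis with L1 term selection
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("hinge", _spline_hinges(n_knots=7)),
                (
                    "clf",
                    LogisticRegression(
                        l1_ratio=1.0, solver="liblinear", C=1.0, max_iter=2000
                    ),
                ),
            ]
        )
    raise KeyError(f"unknown algorithm id {algorithm_id!r}")


def _fit_with_weights(estimator, algorithm_id, X, y, w, seed):
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    X = np.asarray(X, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if algorithm_id in _RESAMPLE_WEIGHTED:
            rng = np.random.default_rng(seed)
            p = w / w.sum()
            idx = rng.choice(len(y), size=len(y), replace=True, p=p)
            # guarantee both classes survive the resample
            if len(np.unique(y[idx])) < 2:
                idx[0] = int(np.flatnonzero(y == 1)[0])
                idx[1] = int(np.flatnonzero(y == 0)[0])
            estimator.fit(X[idx], y[idx])
        elif isinstance(estimator, Pipeline):
            final = estimator.steps[-1][0]
            estimator.fit(X, y, **{f"{final}__sample_weight": w})
        else:
            estimator.fit(X, y, sample_weight=w)
    return estimator


def evaluate(predicted: np.ndarray, truth: np.ndarray) -> dict:
    """TSS/CSI at the TSS-maximizing threshold, plus rank AUC.

    Thresholds are swept over the distinct predicted values (presence
    declared where prediction >= threshold).
    """
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise EvaluationError("truth labels contain a single class")
    candidates = np.unique(predicted)
    pos = truth == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    best = (-np.inf, np.nan, np.nan)  # tss, csi, threshold
    for t in candidates:
        pred_pos = predicted >= t
        tp = int(np.sum(pred_pos & pos))
        fp = int(np.sum(pred_pos & ~pos))
        fn = n_pos - tp
        tn = n_neg - fp
        tss = tp / n_pos + tn / n_neg - 1.0
        if tss > best[0]:
            csi = tp / (tp + fp + fn) if (tp + fp + fn) else 0.0
            best = (tss, csi, float(t))
    auc = float(roc_auc_score(truth, predicted))
    eps = 1e-9
    threshold = float(np.clip(best[2], eps, 1 - eps))
    return {"tss": best[0], "csi": best[1], "auc": auc, "threshold": threshold}


def fit_predict_run(
    algorithm_id: str,
    training: TrainingSet,
    assignment: FoldAssignment,
    seed: int = 0,
    tuning_hook=None,
) -> ModelRun:
    """Fit one algorithm on the training folds, evaluate on the held-out fold.

    ``tuning_hook(algorithm_id, estimator) -> estimator`` may replace or
    re-parameterize the default estimator before fitting.
    """
    test = assignment.test_mask
    train = ~test
    run = ModelRun(algorithm_id, assignment.label, assignment.fold_id)
    estimator = build_estimator(algorithm_id, seed=seed)
    if tuning_hook is not None:
        estimator = tuning_hook(algorithm_id, estimator)
    try:
        _fit_with_weights(
            estimator,
            algorithm_id,
            training.X[train],
            training.y[train],
            training.weights[train],
            seed,
        )
        run.estimator = estimator
        predicted = run.predict(training.X[test])
        metrics = evaluate(predicted, training.y[test])
        run.tss, run.csi = metrics["tss"], metrics["csi"]
        run.auc, run.threshold = metrics["auc"], metrics["threshold"]
    except Exception:  # noqa: BLE001 - a failed fit is excluded, not fatal
        logger.exception("model run failed: %s (%s fold %d)", algorithm_id,
                         assignment.label, assignment.fold_id)
        run.failed = True
    return run


@dataclass
class EnsembleResult:
    """Retained runs plus the calibration ranges needed for projection."""

    runs: list[ModelRun]
    tss_gate: float
    calibration_ranges: pd.DataFrame  # rows: variable; cols: min, max
    variables: list[str]

    @property
    def retained(self) -> list[ModelRun]:
        return [r for r in self.runs if not r.failed and r.tss > self.tss_gate]

    def predict_table(self, X: pd.DataFrame) -> pd.DataFrame:
        """Mean HSI, committee average and coefficient of variation per row."""
        runs = self.retained
        preds = np.stack([r.predict(X[self.variables]) for r in runs])
        votes = np.stack(
            [(r.predict(X[self.variables]) >= r.threshold) for r in runs]
        ).astype(float)
        mean = preds.mean(axis=0)
        std = preds.std(axis=0, ddof=0)
        std[std < 1e-12] = 0.0  # identical runs give exactly zero dispersion
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > 0, std / mean, 0.0)
        return pd.DataFrame(
            {
                "hsi": mean,
                "committee": votes.mean(axis=0),
                "cv": cv,
            }
        )

    def ensemble_threshold(self, training: TrainingSet) -> float:
        """TSS-maximizing threshold of the ensemble-mean prediction."""
        mean = self.predict_table(training.X)["hsi"].to_numpy()
        return evaluate(mean, training.y)["threshold"]

    def run_ledger(self) -> pd.DataFrame:
        rows = [
            {
                "algorithm": r.algorithm_id,
                "label": r.label,
                "fold": r.fold_id,
                "tss": r.tss,
                "auc": r.auc,
                "csi": r.csi,
                "threshold": r.threshold,
                "failed": r.failed,
                "retained": (not r.failed) and r.tss > self.tss_gate,
            }
            for r in self.runs
        ]
        return pd.DataFrame(rows)


def build_ensemble(
    runs: list[ModelRun],
    training: TrainingSet,
    tss_gate: float = TSS_GATE,
) -> EnsembleResult:
    """Gate runs on TSS and assemble the ensemble products."""
    ok = [r for r in runs if not r.failed]
    retained = [r for r in ok if r.tss > tss_gate]
    if not retained:
        best = max((r.tss for r in ok), default=np.nan)
        raise EnsembleError(
            f"no run exceeds the TSS gate {tss_gate}; best TSS = {best:.3f}"
        )
    calib = pd.DataFrame(
        {"min": training.X.min(), "max": training.X.max()}
    )
    return EnsembleResult(
        runs=list(runs),
        tss_gate=tss_gate,
        calibration_ranges=calib,
        variables=training.variables,
    )


def fit_ensemble(
    training: TrainingSet,
    n_unique_env: int,
    seed: int = 0,
    algorithms: tuple[str, ...] = ALGORITHMS,
    tss_gate: float = TSS_GATE,
    tuning_hook=None,
) -> EnsembleResult:
    """Full driver: fold plan -> per-algorithm runs -> gated ensemble."""
    plan = make_folds(training, n_unique_env)
    runs = []
    for ai, alg in enumerate(algorithms):
        for fi, assignment in enumerate(plan):
            runs.append(
                fit_predict_run(
                    alg, training, assignment, seed=seed + 1000 * ai + fi,
                    tuning_hook=tuning_hook,
                )
            )
    return build_ensemble(runs, training, tss_gate=tss_gate)
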
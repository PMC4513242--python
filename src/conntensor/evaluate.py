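"""Experiment design: splits, undersampling-bagging, CV, metrics, group stats.

The classification protocol for an imbalanced two-class contrast (e.g. AD
vs. NC):

1. stratified 85/15 train/test split;
2. feature columns standardized by the training mean and SD;
3. the Lasso parameter selected by 5-fold cross-validation on the training
   data alone (mean fold accuracy, ties toward the larger, sparser lambda);
4. an undersampling-bagging ensemble fit on the whole training set — each
   bag keeps all minority-class samples plus an equal-size random draw of
   the majority class, and predicted probabilities are averaged;
5. accuracy, sensitivity, specificity and AUC measured on the test set;
6. steps 1-5 repeated (20 times by default) and summarized as mean +/- SD.

The module also houses the group-level statistics: element-wise two-sample
t-test maps with Bonferroni correction over all p(p-1)/2 edges, global
network-measure comparisons (Bonferroni over 5 tests), paired one-sided
t-tests comparing feature-extraction methods across repeats, and McNemar's
test on paired predictions.

Everything is driven by one master seed: splits, folds, undersamples and
bags all derive their seeds from it, so a run is bitwise reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from conntensor.data import CohortTensor, matrix_from_upper_triangle, vectorize_upper_triangle
from conntensor.logreg import SparseLogRegModel, fit_sparse_logreg, lambda_path
from conntensor.tensor import FeatureMatrix

#: Clinical severity used to pick the positive class of a contrast: the
#: worse diagnosis is "positive", so sensitivity means disease detection.
SEVERITY = {"NC": 0, "MCI": 1, "AD": 2}


@dataclass(frozen=True)
class ExperimentConfig:
    comparison: tuple[str, str] = ("AD", "NC")
    train_fraction: float = 0.85
    n_repeats: int = 20
    cv_folds: int = 5
    n_bags: int = 21
    lambda_grid_size: int = 20
    master_seed: int = 0
    solver_tol: float = 1e-7
    solver_max_iter: int = 5000

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_bags % 2 == 0:
            raise ValueError("n_bags must be odd so majority voting is defined")
        if len(set(self.comparison)) != 2 or any(c not in SEVERITY for c in self.comparison):
            raise ValueError("comparison must be two distinct labels from {AD, MCI, NC}")

    @property
    def positive_label(self) -> str:
        a, b = self.comparison
        return a if SEVERITY[a] > SEVERITY[b] else b


@dataclass
class EvaluationResult:
    """Per-repeat and aggregate classification performance."""

    per_repeat: pd.DataFrame  # columns accuracy, sensitivity, specificity, auc
    predictions: pd.DataFrame  # repeat, subject_id, prob, predicted, truth
    config: ExperimentConfig
    chosen_lambdas: list[float] = field(default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat.mean()

    @property
    def std(self) -> pd.Series:
        return self.per_repeat.std(ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.std})

    def to_json(self) -> str:
        payload = {
            "comparison": list(self.config.comparison),
            "positive_label": self.config.positive_label,
            "n_repeats": int(self.config.n_repeats),
            "master_seed": int(self.config.master_seed),
            "per_repeat": {
                col: [float(v) for v in self.per_repeat[col]] for col in self.per_repeat
            },
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: float(v) for k, v in self.std.items()},
            "chosen_lambdas": [float(v) for v in self.chosen_lambdas],
            "predictions": {
                col: self.predictions[col].tolist() for col in self.predictions
            },
        }
        return json.dumps(payload, sort_keys=True)


def standardize_columns(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Z-score columns by the *training* mean/SD; constant columns become 0."""
    train = np.asarray(train, dtype=float)
    if train.shape[0] == 0:
        raise ValueError("empty training matrix")
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=0)
    safe = np.where(sds > 0, sds, 1.0)
    train_std = (train - means) / safe
    train_std[:, sds == 0] = 0.0
    test_std = None
    if test is not None:
        test_std = (np.asarray(test, dtype=float) - means) / safe
        test_std[:, sds == 0] = 0.0
    return train_std, test_std, means, sds


def undersample(y: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """All minority indices plus an equal-size draw of the majority class."""
    y = np.asarray(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("undersampling needs both classes present")
    minority = classes[np.argmin(counts)]
    keep = np.flatnonzero(y == minority)
    majority_idx = np.flatnonzero(y != minority)
    drawn = rng.choice(majority_idx, size=keep.size, replace=False)
    return np.sort(np.concatenate([keep, drawn]))


def bagged_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    n_bags: int = 21,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> list[SparseLogRegModel]:
    """Fit ``n_bags`` models, each on an independent undersample of (X, y)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    models = []
    for _ in range(n_bags):
        idx = undersample(y, rng)
        models.append(fit_sparse_logreg(X[idx], y[idx], lam, tol=tol, max_iter=max_iter))
    return models


def ensemble_predict_proba(models: list[SparseLogRegModel], X: np.ndarray) -> np.ndarray:
    """Average of the bag members' predicted positive-class probabilities."""
    return np.mean([m.predict_proba(X) for m in models], axis=0)


def performance_metrics(
    probs: np.ndarray, predicted: np.ndarray, truth: np.ndarray
) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, AUC) for +1/-1 labels.

    Sensitivity is the true-positive rate on the +1 (disease) class; AUC is
    the Mann-Whitney rank statistic with midranks for ties, so constant
    probabilities give exactly 0.5.  With single-class truth only accuracy
    is defined; the other three are returned as NaN.
    """
    probs = np.asarray(probs, dtype=float)
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ValueError("empty truth vector")
    acc = float(np.mean(predicted == truth))
    pos, neg = truth > 0, truth < 0
    if not (pos.any() and neg.any()):
        warnings.warn("single-class truth: sensitivity/specificity/AUC undefined")
        return acc, float("nan"), float("nan"), float("nan")
    sens = float(np.mean(predicted[pos] == truth[pos]))
    spec = float(np.mean(predicted[neg] == truth[neg]))
    ranks = stats.rankdata(probs)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    auc = float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return acc, sens, spec, auc


def _select_lambda_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    cv_folds: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> float:
    """Mean fold accuracy per lambda; ties resolved toward the larger lambda.

    Within each fold the model is a single undersampled fit, warm-started
    along the descending lambda path (the bagged ensemble is reserved for
    the final refit on the whole training set).
    """
    for _attempt in range(10):
        skf = StratifiedKFold(
            n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        folds = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
    else:
        raise ValueError("could not build folds containing both classes")
    acc = np.zeros((cv_folds, grid.size))
    for f, (tr, va) in enumerate(folds):
        Xtr, Xva, _, _ = standardize_columns(X[tr], X[va])
        ytr, yva = y[tr], y[va]
        idx = undersample(ytr, rng)
        Xu, yu = Xtr[idx], ytr[idx]
        w_prev, c_prev = None, None
        for g, lam in enumerate(grid):
            model = fit_sparse_logreg(
                Xu, yu, lam, tol=tol, max_iter=max_iter, w0=w_prev, c0=c_prev
            )
            w_prev, c_prev = model.w, model.c
            pred = np.where(model.predict_proba(Xva) >= 0.5, 1.0, -1.0)
            acc[f, g] = np.mean(pred == yva)
    mean_acc = acc.mean(axis=0)
    return float(grid[int(np.argmax(mean_acc))])  # grid descends: first max = largest lambda


def run_experiment(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    config: ExperimentConfig,
) -> EvaluationResult:
    """Run the full repeated train/test protocol for one two-class contrast."""
    if isinstance(features, FeatureMatrix):
        X_all = features.values
        subject_ids = np.array(features.subject_ids)
    else:
        X_all = np.asarray(features, dtype=float)
        subject_ids = np.array([f"S{i:04d}" for i in range(X_all.shape[0])])
    labels = np.asarray(labels)
    mask = np.isin(labels, list(config.comparison))
    X_all, labels, subject_ids = X_all[mask], labels[mask], subject_ids[mask]
    if np.unique(labels).size != 2:
        raise ValueError("need samples from both comparison groups")
    y_all = np.where(labels == config.positive_label, 1.0, -1.0)

    ss = np.random.SeedSequence(config.master_seed)
    repeat_seeds = ss.generate_state(config.n_repeats * 3).reshape(config.n_repeats, 3)

    rows, pred_frames, chosen = [], [], []
    for rep in range(config.n_repeats):
        split_seed, cv_seed, bag_seed = (int(s % 2**31) for s in repeat_seeds[rep])
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=config.train_fraction, random_state=split_seed
        )
        (tr, te), = splitter.split(X_all, y_all)
        Xtr_std, Xte_std, _, _ = standardize_columns(X_all[tr], X_all[te])
        ytr, yte = y_all[tr], y_all[te]

        grid = lambda_path(Xtr_std, ytr, config.lambda_grid_size)
        lam = _select_lambda_cv(
            X_all[tr], ytr, grid, config.cv_folds, np.random.default_rng(cv_seed),
            config.solver_tol, config.solver_max_iter,
        )
        chosen.append(lam)

        models = bagged_fit(
            Xtr_std, ytr, lam, n_bags=config.n_bags,
            seed=np.random.default_rng(bag_seed),
            tol=config.solver_tol, max_iter=config.solver_max_iter,
        )
        probs = ensemble_predict_proba(models, Xte_std)
        predicted = np.where(probs >= 0.5, 1.0, -1.0)
        rows.append(performance_metrics(probs, predicted, yte))
        pred_frames.append(
            pd.DataFrame(
                {
                    "repeat": rep,
                    "subject_id": subject_ids[te],
                    "prob": probs,
                    "predicted": predicted,
                    "truth": yte,
                }
            )
        )

    per_repeat = pd.DataFrame(rows, columns=["accuracy", "sensitivity", "specificity", "auc"])
    predictions = pd.concat(pred_frames, ignore_index=True)
    return EvaluationResult(per_repeat, predictions, config, chosen)


# ---------------------------------------------------------------------------
# Group-level statistics


def _group_arrays(t: CohortTensor, group_a: str, group_b: str) -> tuple[np.ndarray, np.ndarray]:
    labels = t.labels
    a = np.flatnonzero(labels == group_a)
    b = np.flatnonzero(labels == group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 subjects per group for a t-test")
    edges = np.stack([vectorize_upper_triangle(t.data[i]) for i in range(t.n_subjects)])
    return edges[a], edges[b]


def elementwise_ttest_map(
    t: CohortTensor, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Edge-wise two-sample Student's t-tests with Bonferroni correction.

    Returns symmetric p x p matrices of t statistics and p-values, a boolean
    mask of edges significant after Bonferroni correction over all
    p(p-1)/2 edges (threshold 0.05/6328 ~ 7.9e-6 for p=113), and the
    threshold itself.  Degenerate edges (zero variance in both groups) get
    t = 0, p = 1 with a warning.
    """
    ea, eb = _group_arrays(t, group_a, group_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, pval = stats.ttest_ind(ea, eb, axis=0, equal_var=True)
    bad = ~np.isfinite(tstat)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} degenerate edges (zero variance); p set to 1")
        tstat = np.where(bad, 0.0, tstat)
        pval = np.where(bad, 1.0, pval)
    p = t.node_count
    n_tests = p * (p - 1) // 2
    threshold = 0.05 / n_tests
    t_map = matrix_from_upper_triangle(tstat, p)
    # diagonal carries no test; give it p = 1 so the mask stays clean
    p_map = matrix_from_upper_triangle(pval, p) + np.diag(np.ones(p))
    mask = p_map < threshold
    return t_map, p_map, mask, threshold


def metric_group_tests(
    adjusted_metrics: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    comparison: tuple[str, str],
) -> pd.DataFrame:
    """Two-sample t-tests on the five global measures, Bonferroni over 5.

    Returns a table with t, p, -log10(p) and significance at the adjusted
    threshold 0.05/5 = 0.01 (i.e. -log10 p above 2).
    """
    if isinstance(adjusted_metrics, pd.DataFrame):
        names = list(adjusted_metrics.columns)
        table = adjusted_metrics.to_numpy(dtype=float)
    else:
        table = np.atleast_2d(np.asarray(adjusted_metrics, dtype=float))
        names = [f"metric_{i}" for i in range(table.shape[1])]
    labels = np.asarray(labels)
    a, b = comparison
    ta, tb = table[labels == a], table[labels == b]
    if ta.shape[0] < 2 or tb.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, pval = stats.ttest_ind(ta, tb, axis=0, equal_var=True)
    bad = ~np.isfinite(tstat)
    if bad.any():
        warnings.warn("degenerate metric columns (zero variance); p set to 1")
        tstat = np.where(bad, 0.0, tstat)
        pval = np.where(bad, 1.0, pval)
    threshold = 0.05 / table.shape[1]
    out = pd.DataFrame(
        {
            "t": tstat,
            "p": pval,
            "neg_log10_p": -np.log10(np.maximum(pval, np.finfo(float).tiny)),
            "significant": pval < threshold,
        },
        index=names,
    )
    out.attrs["threshold"] = threshold
    return out


def compare_methods_ttest(perf_a: np.ndarray, perf_b: np.ndarray) -> float:
    """Paired one-sided t-test of H1: method A outperforms method B.

    Per-repeat performances are paired by repeat.  Degenerate all-equal
    differences return 0.5; zero-variance nonzero differences return 0 or 1
    according to the sign.
    """
    a = np.asarray(perf_a, dtype=float)
    b = np.asarray(perf_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 repeats")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.5
        return 0.0 if d.mean() > 0 else 1.0
    return float(stats.ttest_rel(a, b, alternative="greater").pvalue)


def mcnemar_test(
    preds_a: np.ndarray, preds_b: np.ndarray, truth: np.ndarray
) -> float:
    """McNemar's test on two classifiers' paired correct/incorrect outcomes.

    Uses the exact binomial test when the discordant count b + c < 25, else
    the chi-square approximation with continuity correction.  If the two
    classifiers never disagree on correctness, p = 1.
    """
    preds_a, preds_b, truth = map(np.asarray, (preds_a, preds_b, truth))
    if not preds_a.shape == preds_b.shape == truth.shape:
        raise ValueError("prediction and truth vectors must be aligned")
    ok_a = preds_a == truth
    ok_b = preds_b == truth
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    if b + c == 0:
        return 1.0
    table = np.array([[int(np.sum(ok_a & ok_b)), b], [c, int(np.sum(~ok_a & ~ok_b))]])
    exact = (b + c) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.pvalue)
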
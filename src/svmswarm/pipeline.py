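"""End-to-end experiment: load -> PCA -> Z-score -> split -> optimize -> evaluate.

The chain mirrors the standard hyperparameter-tuning protocol for an RBF
SVM: a stratified holdout split (default 20%), preprocessing fitted on the
training rows only, a swarm optimizer maximizing the mean stratified k-fold
cross-validated accuracy over ``(log2 C, log2 gamma)``, a final refit on the
whole training split at the best point, and a nine-metric holdout report.

Everything downstream of the config is a pure function of ``(config, seed)``:
rerunning an experiment reproduces its report byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import ClassTooSmall, FeatureMatrix, InvalidConfig, SingleClassInput
from .metrics import (
    ConfusionMatrix,
    MetricsReport,
    compute_metrics,
    confusion_matrix,
)
from .optimizers import (
    DEFAULT_SVM_BOUNDS,
    OptimizerConfig,
    SearchBounds,
    optimize,
)
from .preprocess import preprocess_apply, preprocess_fit
from .svm_core import (
    KernelSpec,
    SVMModel,
    kernel_matrix,
    svm_train,
    svm_train_from_kernel,
    model_to_json,
)
from .synthetic_data import SyntheticConfig, generate_voice_like
from .data import read_voice_csv

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "stratified_split",
    "CVFitness",
    "run_experiment",
    "report_to_json",
    "history_to_csv",
]


def stratified_split(
    X: FeatureMatrix,
    test_fraction: float,
    mode: str = "row-stratified",
    seed: int = 0,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Deterministic stratified holdout split.

    ``row-stratified`` draws ``round(test_fraction * n_c)`` rows per class
    (class proportions preserved within one row); ``subject-grouped``
    assigns whole subjects to one side, accumulating test subjects per class
    until the class's test-row quota is reached, so no subject straddles the
    split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise InvalidConfig("test_fraction must lie in (0, 1)")
    labels = X.labels
    classes = np.unique(labels)
    if classes.size < 2:
        raise SingleClassInput("both classes must be present to split")
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(X.n, dtype=bool)
    if mode == "row-stratified":
        for c in classes:
            idx = np.flatnonzero(labels == c)
            k = int(round(test_fraction * idx.size))
            if k < 1 or k >= idx.size:
                raise ClassTooSmall(f"class {c} too small for this split")
            test_mask[rng.permutation(idx)[:k]] = True
    elif mode == "subject-grouped":
        if X.subject_ids is None:
            raise InvalidConfig("subject-grouped split needs subject_ids")
        for c in classes:
            idx = np.flatnonzero(labels == c)
            subjects = rng.permutation(np.unique(X.subject_ids[idx]))
            quota = test_fraction * idx.size
            taken = 0
            for s in subjects:
                if taken >= quota:
                    break
                rows = idx[X.subject_ids[idx] == s]
                test_mask[rows] = True
                taken += rows.size
            if taken == 0 or taken == idx.size:
                raise ClassTooSmall(f"class {c} has too few subjects to split")
    else:
        raise InvalidConfig("mode must be row-stratified | subject-grouped")
    return X.take(~test_mask), X.take(test_mask)


def _stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """k disjoint validation index sets, each with near-proportional classes."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        for pos, row in enumerate(idx):
            folds[pos % k].append(int(row))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


class CVFitness:
    """Mean stratified k-fold CV accuracy of an RBF SVM at ``(log2 C, log2 gamma)``.

    The fold layout and the per-fold squared-distance matrices are
    precomputed once, so each evaluation only re-exponentiates the kernel
    and solves the duals. Evaluations are cached by exact position, making
    the fitness deterministic within a run.
    """

    def __init__(self, train: FeatureMatrix, cv_folds: int = 5, seed: int = 0):
        if cv_folds < 2:
            raise InvalidConfig("cv_folds must be >= 2")
        counts = [np.sum(train.labels == c) for c in (-1, 1)]
        if min(counts) < cv_folds:
            raise ClassTooSmall("each class needs at least cv_folds rows")
        self.train = train
        self.cv_folds = cv_folds
        self.seed = seed
        self.n_evaluations = 0
        self._cache: dict[bytes, float] = {}
        self._folds = _stratified_folds(train.labels, cv_folds, seed)
        V = train.values
        self._splits = []
        for val_idx in self._folds:
            tr_mask = np.ones(train.n, dtype=bool)
            tr_mask[val_idx] = False
            tr_idx = np.flatnonzero(tr_mask)
            Vt, Vv = V[tr_idx], V[val_idx]
            sq_tt = (
                np.sum(Vt * Vt, 1)[:, None] + np.sum(Vt * Vt, 1)[None, :]
                - 2.0 * (Vt @ Vt.T)
            )
            sq_vt = (
                np.sum(Vv * Vv, 1)[:, None] + np.sum(Vt * Vt, 1)[None, :]
                - 2.0 * (Vv @ Vt.T)
            )
            np.clip(sq_tt, 0.0, None, out=sq_tt)
            np.clip(sq_vt, 0.0, None, out=sq_vt)
            self._splits.append(
                (train.labels[tr_idx].astype(float), train.labels[val_idx],
                 sq_tt, sq_vt)
            )

    def __call__(self, position: np.ndarray) -> float:
        key = np.asarray(position, dtype=float).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        log2c, log2g = float(position[0]), float(position[1])
        C, gamma = 2.0 ** log2c, 2.0 ** log2g
        correct = 0
        total = 0
        for y_tr, y_val, sq_tt, sq_vt in self._splits:
            K = np.exp(-gamma * sq_tt)
            alpha, bias, _, _ = svm_train_from_kernel(K, y_tr, C)
            f = np.exp(-gamma * sq_vt) @ (alpha * y_tr) + bias
            pred = np.where(f >= 0.0, 1, -1)
            correct += int(np.sum(pred == y_val))
            total += y_val.size
        acc = correct / total
        self._cache[key] = acc
        self.n_evaluations += 1
        return acc


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully resolved settings of one experiment run."""

    synthetic: SyntheticConfig | None = None
    input_path: str | None = None
    method: str = "cspso"
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    kernel_family: str = "gaussian"
    variance_threshold: float = 0.95
    n_components: int | None = None
    test_fraction: float = 0.2
    split_mode: str = "row-stratified"
    cv_folds: int = 5
    seed: int = 0
    bounds: SearchBounds = DEFAULT_SVM_BOUNDS

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_path is None):
            raise InvalidConfig("provide exactly one of synthetic | input_path")
        if self.kernel_family != "gaussian":
            raise InvalidConfig(
                "the tuned pipeline currently optimizes the gaussian kernel only"
            )


@dataclass
class ExperimentReport:
    """Everything one run produced, recomputable from config + seed."""

    best_log2_C: float
    best_log2_gamma: float
    best_C: float
    best_gamma: float
    cv_fitness: float
    holdout_confusion: ConfusionMatrix
    holdout_metrics: MetricsReport
    train_rows: int
    test_rows: int
    n_components: int
    variance_retained: float
    history: list[dict]
    model: SVMModel
    config_summary: dict


def _config_summary(cfg: ExperimentConfig) -> dict:
    d = {
        "method": cfg.method,
        "kernel_family": cfg.kernel_family,
        "variance_threshold": cfg.variance_threshold,
        "n_components": cfg.n_components,
        "test_fraction": cfg.test_fraction,
        "split_mode": cfg.split_mode,
        "cv_folds": cfg.cv_folds,
        "seed": cfg.seed,
        "input_path": cfg.input_path,
        "bounds_lower": cfg.bounds.lower.tolist(),
        "bounds_upper": cfg.bounds.upper.tolist(),
        "optimizer": asdict(cfg.optimizer),
    }
    if cfg.synthetic is not None:
        d["synthetic"] = asdict(cfg.synthetic)
    return d


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Execute the full chain and return a reproducible report.

    Stages: data (synthetic or CSV) -> stratified split -> PCA + Z-score
    fitted on the training rows -> swarm search of ``(log2 C, log2 gamma)``
    maximizing CV accuracy -> final SVM refit on the whole training split ->
    holdout confusion matrix and metrics.
    """
    data = (
        generate_voice_like(cfg.synthetic)
        if cfg.synthetic is not None
        else read_voice_csv(cfg.input_path)
    )
    train, test = stratified_split(data, cfg.test_fraction, cfg.split_mode, cfg.seed)
    pca, std = preprocess_fit(train, cfg.variance_threshold, cfg.n_components)
    train_p = preprocess_apply(train, pca, std)
    test_p = preprocess_apply(test, pca, std)

    fitness = CVFitness(train_p, cv_folds=cfg.cv_folds, seed=cfg.seed)
    opt_cfg = cfg.optimizer if cfg.optimizer.seed == cfg.seed else OptimizerConfig(
        **{**asdict(cfg.optimizer), "seed": cfg.seed}
    )
    result = optimize(cfg.method, fitness, cfg.bounds, opt_cfg)
    log2c, log2g = (float(v) for v in result.best_position)
    C, gamma = 2.0 ** log2c, 2.0 ** log2g

    kernel = KernelSpec.gaussian_from_gamma(gamma)
    model = svm_train(train_p, C, kernel)
    pred = np.where(
        kernel_matrix(kernel, test_p.values, model.support_vectors)
        @ (model.alphas * model.sv_labels) + model.bias >= 0.0, 1, -1,
    )
    cm = confusion_matrix(test_p.labels, pred)
    return ExperimentReport(
        best_log2_C=log2c,
        best_log2_gamma=log2g,
        best_C=C,
        best_gamma=gamma,
        cv_fitness=float(result.best_fitness),
        holdout_confusion=cm,
        holdout_metrics=compute_metrics(cm),
        train_rows=train.n,
        test_rows=test.n,
        n_components=pca.k,
        variance_retained=pca.variance_retained,
        history=result.history,
        model=model,
        config_summary=_config_summary(cfg),
    )


def report_to_json(report: ExperimentReport) -> str:
    """Deterministic JSON rendering of a report (model serialized separately)."""
    doc = {
        "best_log2_C": report.best_log2_C,
        "best_log2_gamma": report.best_log2_gamma,
        "best_C": report.best_C,
        "best_gamma": report.best_gamma,
        "cv_fitness": report.cv_fitness,
        "holdout_confusion": {
            "tp": report.holdout_confusion.tp,
            "fp": report.holdout_confusion.fp,
            "fn": report.holdout_confusion.fn,
            "tn": report.holdout_confusion.tn,
        },
        "holdout_metrics": report.holdout_metrics.as_dict(),
        "train_rows": report.train_rows,
        "test_rows": report.test_rows,
        "n_components": report.n_components,
        "variance_retained": report.variance_retained,
        "history": report.history,
        "config": report.config_summary,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def history_to_csv(history: list[dict], path) -> None:
    """Write the convergence trace as ``iteration,best_fitness,mean_fitness``."""
    import pandas as pd

    pd.DataFrame(history)[["iteration", "best_fitness", "mean_fitness"]].to_csv(
        path, index=False
    )


def save_report(report: ExperimentReport, out_dir) -> None:
    """Write ``report.json``, ``history.csv`` and ``model.json`` to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_to_json(report))
    history_to_csv(report.history, out / "history.csv")
    (out / "model.json").write_text(model_to_json(report.model))
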
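"""Multi-label stratified cross-validated MLP regression of carotenoid
composition, with the repeated-training evaluation harness.

The regressor is a feed-forward network N_f x N_h1 x N_h2 x N_o
(default 412-100-10-3) with tanh hidden activations, trained by L-BFGS
(full-batch quasi-Newton) or ADAM. Continuous 3-component targets are
discretized into quantile bins per output and split by iterative
stratification (Sechidis et al.) so every fold sees a similar distribution
of label combinations. Performance is scored by MSE, MAE and R^2
(1 - SS_res / SS_tot, computable below zero and reported unclipped),
each computed per output and uniformly averaged over the three outputs.
The evaluation harness repeats the whole split-train-test cycle ``n_runs``
times and reports mean, standard deviation and best of each measure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .preprocess import FeatureScaler
from .representative import Dataset


@dataclass
class MLPConfig:
    """Architecture and training configuration of the regressor."""

    n_features: int = 412
    hidden: tuple = (100, 10)
    n_outputs: int = 3
    activation: str = "tanh"
    optimizer: str = "lbfgs"
    max_iter: int | None = None  # None -> 1000 for lbfgs, 2000 for adam
    alpha: float = 0.1  # L2 weight penalty; ~42k weights vs ~10^2 spectra
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("lbfgs", "adam"):
            raise ValueError("optimizer must be 'lbfgs' or 'adam'")
        if min(self.n_features, self.n_outputs, *self.hidden) < 1:
            raise ValueError("all layer sizes must be >= 1")

    @property
    def effective_max_iter(self) -> int:
        if self.max_iter is not None:
            return self.max_iter
        return 1000 if self.optimizer == "lbfgs" else 2000

    def summary(self) -> str:
        """Architecture string, e.g. '412-100-10-3'."""
        return "-".join(str(s) for s in (self.n_features, *self.hidden, self.n_outputs))


def _quantile_bins(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize one output into (at most) n_bins quantile bins."""
    edges = np.quantile(column, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(edges)
    return np.searchsorted(edges, column, side="left")


def multilabel_stratified_kfold(
    targets: np.ndarray, k_folds: int = 5, n_bins: int = 4, seed=0
) -> np.ndarray:
    """Assign samples to k folds by iterative multi-label stratification.

    Each continuous output is discretized into ``n_bins`` quantile bins and
    every (output, bin) pair becomes a binary label; samples are then
    distributed by the Sechidis et al. greedy scheme: repeatedly take the
    rarest unassigned label and hand its samples to the folds with the
    greatest remaining demand for it (ties: largest remaining capacity,
    then seeded random choice). Fold sizes differ by at most one and every
    sample lands in exactly one fold.
    """
    y = np.asarray(targets, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    if n < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} samples, got {n}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    binary: list[np.ndarray] = []
    for col in y.T:
        bins = _quantile_bins(col, n_bins)
        for b in np.unique(bins):
            binary.append(bins == b)
    labels = np.array(binary).T if binary else np.zeros((n, 0), dtype=bool)

    base = n // k_folds
    capacity = np.array([base + (1 if j < n % k_folds else 0) for j in range(k_folds)],
                        dtype=float)
    # desired per-fold share of each label, proportional to fold size
    desired = labels.sum(axis=0)[None, :] * capacity[:, None] / n
    fold_of = np.full(n, -1, dtype=int)

    def _assign(sample: int, fold: int) -> None:
        fold_of[sample] = fold
        capacity[fold] -= 1
        desired[fold, labels[sample]] -= 1

    while np.any(fold_of < 0):
        remaining = fold_of < 0
        counts = labels[remaining].sum(axis=0)
        open_labels = np.nonzero(counts > 0)[0]
        if open_labels.size == 0:
            for sample in np.nonzero(remaining)[0]:
                best = np.nonzero(capacity == capacity.max())[0]
                _assign(int(sample), int(rng.choice(best)))
            break
        lab = int(open_labels[np.argmin(counts[open_labels])])
        for sample in np.nonzero(remaining & labels[:, lab])[0]:
            open_folds = np.nonzero(capacity > 0)[0]
            demand = desired[open_folds, lab]
            cand = open_folds[demand == demand.max()]
            if cand.size > 1:
                caps = capacity[cand]
                cand = cand[caps == caps.max()]
            _assign(int(sample), int(cand[0] if cand.size == 1 else rng.choice(cand)))
    return fold_of


def train_mlp(features: np.ndarray, targets: np.ndarray, cfg: MLPConfig) -> MLPRegressor:
    """Fit the MLP regressor on (already scaled) training data.

    Non-convergence within the iteration cap returns the trained model with
    a logged warning rather than raising; the iteration count is available
    as ``model.n_iter_``.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if features.shape[1] != cfg.n_features:
        raise ValueError(
            f"feature matrix has {features.shape[1]} columns, config expects "
            f"{cfg.n_features}"
        )
    model = MLPRegressor(
        hidden_layer_sizes=cfg.hidden,
        activation=cfg.activation,
        solver=cfg.optimizer,
        max_iter=cfg.effective_max_iter,
        alpha=cfg.alpha,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("always", category=ConvergenceWarning)
        model.fit(features, targets)
    return model


@dataclass
class EvalMetrics:
    """MSE, MAE and R^2, each uniformly averaged over the outputs."""

    mse: float
    mae: float
    r2: float
    per_output: dict = field(default_factory=dict)
    excluded_outputs: list = field(default_factory=list)


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    """Mean squared error, mean absolute error and coefficient of
    determination R^2 = 1 - SS_res / SS_tot, per output and uniformly
    averaged; R^2 of a zero-variance output is undefined and excluded from
    the average with a warning. R^2 is never clipped: arbitrarily negative
    values are carried through.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("yTrue and yPred must have equal shapes")
    if y_true.ndim == 1:
        y_true, y_pred = y_true[:, None], y_pred[:, None]
    if y_true.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    residual = y_true - y_pred
    mse_cols = np.mean(residual**2, axis=0)
    mae_cols = np.mean(np.abs(residual), axis=0)
    ss_res = np.sum(residual**2, axis=0)
    ss_tot = np.sum((y_true - y_true.mean(axis=0)) ** 2, axis=0)
    per_output: dict[int, dict] = {}
    r2_cols: list[float] = []
    excluded: list[int] = []
    for j in range(y_true.shape[1]):
        entry = {"mse": float(mse_cols[j]), "mae": float(mae_cols[j])}
        if ss_tot[j] == 0:
            entry["r2"] = None
            excluded.append(j)
        else:
            entry["r2"] = float(1.0 - ss_res[j] / ss_tot[j])
            r2_cols.append(entry["r2"])
        per_output[j] = entry
    if excluded:
        warnings.warn(
            f"R^2 undefined for zero-variance output(s) {excluded}; "
            "excluded from the average",
            stacklevel=2,
        )
    if not r2_cols:
        raise ValueError("R^2 undefined for every output (all zero-variance)")
    return EvalMetrics(
        mse=float(np.mean(mse_cols)),
        mae=float(np.mean(mae_cols)),
        r2=float(np.mean(r2_cols)),
        per_output=per_output,
        excluded_outputs=excluded,
    )


@dataclass
class RunResult:
    """One repetition of the split-train-test cycle."""

    test: EvalMetrics
    train: EvalMetrics
    n_iterations: float  # mean over folds
    y_true: np.ndarray  # pooled held-out targets
    y_pred: np.ndarray  # pooled held-out predictions


@dataclass
class EvalReport:
    """Per-run results plus mean / SD / best aggregates over runs."""

    runs: list
    config: MLPConfig
    k_folds: int
    n_bins: int
    seed: int

    def _series(self, split: str, measure: str) -> np.ndarray:
        return np.array([getattr(getattr(r, split), measure) for r in self.runs])

    def aggregate(self, split: str = "test") -> dict:
        out: dict[str, dict] = {}
        for measure, best_fn in (("r2", np.max), ("mse", np.min), ("mae", np.min)):
            vals = self._series(split, measure)
            out[measure] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=0)),
                "best": float(best_fn(vals)),
            }
        iters = np.array([r.n_iterations for r in self.runs])
        out["n_iterations"] = {"mean": float(iters.mean()), "sd": float(iters.std(ddof=0))}
        return out

    def to_dict(self) -> dict:
        return {
            "optimizer": self.config.optimizer,
            "architecture": self.config.summary(),
            "n_runs": len(self.runs),
            "k_folds": self.k_folds,
            "n_bins": self.n_bins,
            "seed": self.seed,
            "test": self.aggregate("test"),
            "train": self.aggregate("train"),
            "per_run_test_r2": [float(r.test.r2) for r in self.runs],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def repeated_training(
    dataset: Dataset,
    cfg: MLPConfig | None = None,
    n_runs: int = 50,
    k_folds: int = 5,
    n_bins: int = 4,
    seed: int = 0,
) -> EvalReport:
    """Repeat the full cross-validated evaluation ``n_runs`` times.

    Each run draws a fresh multi-label stratified k-fold split; per fold,
    min-max scaling is fitted on the training portion only, the MLP is
    trained and the held-out fold predicted. A run's test metrics are
    computed on the pooled held-out predictions (every sample held out
    exactly once); train metrics on the pooled in-fold predictions.
    """
    cfg = cfg or MLPConfig(n_features=dataset.features.shape[1])
    x_all, y_all = dataset.features, dataset.targets
    root = np.random.SeedSequence(seed)
    runs: list[RunResult] = []
    for run_ss in root.spawn(n_runs):
        seeds = run_ss.generate_state(2) % (2**31 - 1)
        folds = multilabel_stratified_kfold(
            y_all, k_folds=k_folds, n_bins=n_bins, seed=np.random.default_rng(seeds[0])
        )
        y_pred = np.empty_like(y_all)
        train_true, train_pred = [], []
        iters = []
        for j in range(k_folds):
            test_mask = folds == j
            scaler = FeatureScaler().fit(x_all[~test_mask])
            fold_cfg = MLPConfig(
                n_features=cfg.n_features,
                hidden=cfg.hidden,
                n_outputs=cfg.n_outputs,
                activation=cfg.activation,
                optimizer=cfg.optimizer,
                max_iter=cfg.max_iter,
                alpha=cfg.alpha,
                seed=int((seeds[1] + j) % (2**31 - 1)),
            )
            model = train_mlp(scaler.transform(x_all[~test_mask]), y_all[~test_mask],
                              fold_cfg)
            y_pred[test_mask] = model.predict(scaler.transform(x_all[test_mask]))
            train_true.append(y_all[~test_mask])
            train_pred.append(model.predict(scaler.transform(x_all[~test_mask])))
            iters.append(model.n_iter_)
        runs.append(
            RunResult(
                test=evaluate(y_all, y_pred),
                train=evaluate(np.vstack(train_true), np.vstack(train_pred)),
                n_iterations=float(np.mean(iters)),
                y_true=y_all.copy(),
                y_pred=y_pred,
            )
        )
    return EvalReport(runs=runs, config=cfg, k_folds=k_folds, n_bins=n_bins, seed=seed)


# ---------------------------------------------------------------------------
# Portable model persistence


def save_model(model: MLPRegressor, scaler: FeatureScaler, cfg: MLPConfig, path) -> None:
    """Serialize weights + scaler statistics + config to portable JSON."""
    doc = {
        "config": {
            "n_features": cfg.n_features,
            "hidden": list(cfg.hidden),
            "n_outputs": cfg.n_outputs,
            "activation": cfg.activation,
            "optimizer": cfg.optimizer,
            "max_iter": cfg.max_iter,
            "alpha": cfg.alpha,
            "seed": cfg.seed,
        },
        "coefs": [w.tolist() for w in model.coefs_],
        "intercepts": [b.tolist() for b in model.intercepts_],
        "scaler": {
            "data_min": scaler.data_min_.tolist(),
            "data_max": scaler.data_max_.tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> tuple[MLPRegressor, FeatureScaler, MLPConfig]:
    """Rebuild a saved model; predictions match the saved one exactly."""
    doc = json.loads(Path(path).read_text())
    c = doc["config"]
    cfg = MLPConfig(
        n_features=c["n_features"],
        hidden=tuple(c["hidden"]),
        n_outputs=c["n_outputs"],
        activation=c["activation"],
        optimizer=c["optimizer"],
        max_iter=c["max_iter"],
        alpha=c.get("alpha", 0.1),
        seed=c["seed"],
    )
    model = MLPRegressor(
        hidden_layer_sizes=cfg.hidden,
        activation=cfg.activation,
        solver=cfg.optimizer,
    )
    model.coefs_ = [np.asarray(w, dtype=float) for w in doc["coefs"]]
    model.intercepts_ = [np.asarray(b, dtype=float) for b in doc["intercepts"]]
    model.n_layers_ = len(model.coefs_) + 1
    model.n_outputs_ = cfg.n_outputs
    model.n_features_in_ = cfg.n_features
    model.out_activation_ = "identity"
    scaler = FeatureScaler()
    n = cfg.n_features
    scaler._scaler.fit(np.vstack([doc["scaler"]["data_min"], doc["scaler"]["data_max"]]))
    assert scaler._scaler.n_features_in_ == n
    scaler._fitted = True
    return model, scaler, cfg
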
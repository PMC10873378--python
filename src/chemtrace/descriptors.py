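"""Molecule descriptors pooled from encoder memory, baselines, and the
fold-based downstream property-prediction harness.

The encoder memory is one hidden vector per source token (non-padding
positions, including the start/end tokens). Four pooling methods map it to
a fixed width: at d_model = 512 they give 512 (mean), 512 (first token),
2048 (mean | max | first | last) and 3072 (mean | max | min | std | first
| last). The standard deviation is the population form, so a single-token
memory pools to zeros in those columns.

Downstream prediction uses gradient-boosted trees with a seeded, bounded
random hyperparameter search on a validation split, reporting RMSE
(regression) or AUROC (classification) per fold with mean and unbiased
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mean_squared_error, roc_auc_score
from sklearn.model_selection import ParameterSampler

from .similarity import FingerprintConfig, fingerprint, mol_from_smiles

POOLING_METHODS = ("mean", "first_token", "concat4", "concat6")

#: descriptor width as a multiple of d_model
POOLING_WIDTH_FACTOR = {"mean": 1, "first_token": 1, "concat4": 4, "concat6": 6}


@dataclass
class PooledDescriptor:
    vector: np.ndarray
    method: str
    source_step: int | None = None


def pool_memory(memory: np.ndarray, method: str,
                source_step: int | None = None) -> PooledDescriptor:
    """Pool an (L, d_model) encoder memory into one fixed-width vector."""
    memory = np.asarray(memory)
    if memory.ndim != 2 or memory.shape[0] < 1:
        raise ValueError("memory must be a non-empty (L, d_model) matrix")
    if method == "mean":
        vec = memory.mean(axis=0)
    elif method == "first_token":
        vec = memory[0].copy()
    elif method == "concat4":
        vec = np.concatenate([memory.mean(axis=0), memory.max(axis=0),
                              memory[0], memory[-1]])
    elif method == "concat6":
        vec = np.concatenate([memory.mean(axis=0), memory.max(axis=0),
                              memory.min(axis=0), memory.std(axis=0),
                              memory[0], memory[-1]])
    else:
        raise ValueError(f"unknown pooling method {method!r}; "
                         f"expected one of {POOLING_METHODS}")
    return PooledDescriptor(vector=vec, method=method, source_step=source_step)


def encoder_descriptors(model, smiles_list: list[str], vocab, method: str,
                        rng: np.random.Generator | None = None,
                        randomized: bool = True,
                        source_step: int | None = None) -> np.ndarray:
    """Descriptor matrix for a list of molecules from a trained (or
    untrained) model's encoder; inputs are randomized SMILES by default."""
    from . import autodiff as ad
    from .corpus import randomize_smiles

    if randomized and rng is None:
        raise ValueError("randomized inputs need an rng")
    was_training = model.training
    model.train(False)
    rows = []
    try:
        for smi in smiles_list:
            s = randomize_smiles(smi, rng) if randomized else smi
            ids = vocab.encode(s)[None, :]
            with ad.no_grad():
                memory = model.encode(ids).data[0]
            rows.append(pool_memory(memory, method, source_step).vector)
    finally:
        model.train(was_training)
    return np.array(rows)


def baseline_descriptor(kind: str, smiles: str | None = None,
                        rng: np.random.Generator | None = None,
                        n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Baselines: uniform-[0,1] noise of width 2048, or a folded Morgan
    (ECFP-like) fingerprint of the molecule (R=2, 2048 bits by default)."""
    if kind == "random_uniform":
        if rng is None:
            raise ValueError("random_uniform needs an rng")
        return rng.random(n_bits)
    if kind == "ecfp":
        mol = mol_from_smiles(smiles or "")
        if mol is None:
            raise ValueError(f"invalid SMILES for ECFP baseline: {smiles!r}")
        return fingerprint(mol, FingerprintConfig("ecfp", radius, n_bits)).astype(float)
    raise ValueError(f"unknown baseline kind {kind!r}")


_SEARCH_SPACE = {
    "max_depth": [2, 3, 4, 5, 6, 8],
    "learning_rate": [0.01, 0.03, 0.1, 0.2, 0.3],
    "n_estimators": [50, 100, 200, 300],
    "subsample": [0.6, 0.8, 1.0],
    "colsample_bytree": [0.6, 0.8, 1.0],
    "min_child_weight": [1, 2, 4, 8],
}


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator):
    """Disjoint covering folds; fold i tests, fold (i+1) validates,
    the rest train."""
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    for i in range(n_folds):
        test = folds[i]
        val = folds[(i + 1) % n_folds]
        train = np.concatenate([folds[j] for j in range(n_folds)
                                if j not in (i, (i + 1) % n_folds)])
        yield train, val, test


def _make_estimator(task: str, params: dict, seed: int):
    import xgboost as xgb

    common = dict(n_jobs=1, random_state=seed, tree_method="hist",
                  verbosity=0, **params)
    if task == "regression":
        return xgb.XGBRegressor(**common)
    return xgb.XGBClassifier(eval_metric="logloss", **common)


def _score(task: str, est, X, y) -> float:
    if task == "regression":
        return float(np.sqrt(mean_squared_error(y, est.predict(X))))
    return float(roc_auc_score(y, est.predict_proba(X)[:, 1]))


def downstream_eval(descriptors: np.ndarray, labels: np.ndarray, task: str,
                    n_folds: int = 5, rng: np.random.Generator | None = None,
                    n_trials: int = 20) -> pd.DataFrame:
    """Fold-based property prediction from descriptors.

    Per fold, a bounded random hyperparameter search is scored on the
    validation split, the best configuration is refit on train+validation
    and scored on the test split. Returns per-fold rows plus a summary row
    (mean, unbiased std). Regression reports RMSE; classification AUROC.
    """
    if task not in ("regression", "classification"):
        raise ValueError("task must be regression or classification")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X = np.asarray(descriptors)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("descriptor rows must align with labels")
    if task == "classification" and len(np.unique(y)) < 2:
        raise ValueError("classification labels are degenerate (single class)")
    rng = rng or np.random.default_rng(0)
    seed = int(rng.integers(2**31 - 1))
    metric = "rmse" if task == "regression" else "auroc"
    better = min if task == "regression" else max

    rows = []
    for fold, (tr, va, te) in enumerate(_fold_indices(len(y), n_folds, rng)):
        candidates = list(ParameterSampler(_SEARCH_SPACE, n_iter=n_trials,
                                           random_state=seed + fold))
        best_params, best_val = None, None
        for params in candidates:
            est = _make_estimator(task, params, seed)
            est.fit(X[tr], y[tr])
            val = _score(task, est, X[va], y[va])
            if best_val is None or better(val, best_val) == val:
                best_val, best_params = val, params
        est = _make_estimator(task, best_params, seed)
        refit = np.concatenate([tr, va])
        est.fit(X[refit], y[refit])
        rows.append({"fold": fold, "metric": metric,
                     "value": _score(task, est, X[te], y[te])})
    df = pd.DataFrame(rows)
    values = df["value"].to_numpy()
    summary = pd.DataFrame([{"fold": "mean", "metric": metric, "value": values.mean()},
                            {"fold": "std", "metric": metric,
                             "value": values.std(ddof=1)}])
    return pd.concat([df, summary], ignore_index=True)
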
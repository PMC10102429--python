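"""Cross-validated LAI regression with four model families.

Families: RBF-kernel support vector regression (``SVM``, C = 1.00,
gamma = 3.03 on standardized features), random forest (``RF``, 200 trees,
``mtry`` tuned per input set by inner cross-validation), a single-hidden-
layer backpropagation network (``BPNN``, 10 hidden units, learning rate
0.01, standardized features), and partial least squares regression
(``PLSR``, latent-variable count chosen by inner cross-validation).

Evaluation uses ten-fold cross-validation: each fold fits on 9/10 of the
samples (the calibration set) and predicts the held-out tenth (validation).
Per-fold metrics are

    R^2  = 1 - sum (y - yhat)^2 / sum (y - ybar)^2
    RMSE = sqrt(mean (y - yhat)^2)
    RPD  = sd(y) / RMSE          (population sd, divisor n)

and the reported calibration/validation numbers are across-fold means.  All
data-dependent choices — feature standardization, ``mtry``, the PLSR latent
count — are made inside the training fold only, so the validation metrics
are leakage-free.
"""
from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .errors import DomainError, TexlaiError

log = logging.getLogger(__name__)

FAMILIES: tuple[str, ...] = ("SVM", "RF", "BPNN", "PLSR")

#: Families whose optimizers need z-scored inputs.
_NEEDS_SCALING = {"SVM", "BPNN"}

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "SVM": {"c": 1.00, "g": 3.03},
    "RF": {"ntrees": 200, "mtry": "auto", "tuning_folds": 5, "tuning_ntrees": 50},
    "BPNN": {
        "learning_rate": 0.01,
        "hidden_units": 10,
        "hidden_layers": 1,
        "max_epochs": 2000,
    },
    "PLSR": {"n_latent": "auto", "tuning_folds": 5, "max_latent": 8},
}


@dataclass
class ModelSpec:
    """One model family plus its hyperparameters and RNG seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; known: {FAMILIES}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.family])
        unknown = set(self.hyperparameters) - set(merged)
        if unknown:
            raise ValueError(f"unknown {self.family} hyperparameters: {unknown}")
        merged.update(self.hyperparameters)
        self.hyperparameters = merged
        if self.family in ("RF", "BPNN") and self.seed is None:
            raise ValueError(f"{self.family} requires an explicit seed")


@dataclass
class FoldMetrics:
    fold: int
    cal_R2: float
    cal_RMSE: float
    cal_RPD: float
    val_R2: float
    val_RMSE: float
    val_RPD: float


@dataclass
class CVResult:
    family: str
    input_set: str
    folds: list[FoldMetrics]
    oof_prediction: np.ndarray  # out-of-fold prediction per sample
    y: np.ndarray
    n_dropped: int = 0
    flagged_folds: list[int] = field(default_factory=list)

    def _mean(self, attr: str) -> float:
        vals = [getattr(f, attr) for f in self.folds
                if f.fold not in self.flagged_folds]
        return float(np.mean(vals))

    @property
    def summary(self) -> dict[str, float]:
        return {
            f"{split}_{m}": self._mean(f"{split}_{m}")
            for split in ("cal", "val")
            for m in ("R2", "RMSE", "RPD")
        }


def tenfold_split(n: int, seed: int, n_folds: int = 10) -> np.ndarray:
    """Random balanced fold assignment: fold sizes differ by at most one.

    For n = 700 every training set holds exactly 630 samples and every
    validation set 70.
    """
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % n_folds
    return folds


def metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(R2, RMSE, RPD) with the population-sd RPD convention.

    A perfect fit gives RPD = +inf; a constant mean predictor gives exactly
    R2 = 0 and RPD = 1.
    """
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("y_true and y_pred must be equal-length 1-D, n >= 2")
    sd = y.std(ddof=0)
    if sd == 0:
        raise DomainError("metrics undefined: y_true has zero variance")
    sse = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    rmse = float(np.sqrt(sse / y.size))
    rpd = float(sd / rmse) if rmse > 0 else float("inf")
    return r2, rmse, rpd


def standardize_features(
    X_train: np.ndarray, X_apply: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-score with training mean/sd only (the apply set reuses them)."""
    X_train = np.asarray(X_train, dtype=float)
    X_apply = np.asarray(X_apply, dtype=float)
    mean = X_train.mean(axis=0)
    sd = X_train.std(ddof=0, axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DomainError(f"zero-variance training column(s) at index {dead.tolist()}")
    return (X_train - mean) / sd, (X_apply - mean) / sd, (mean, sd)


def unstandardize(X_scaled: np.ndarray, params) -> np.ndarray:
    mean, sd = params
    return X_scaled * sd + mean


def _inner_folds(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % k
    return folds


def _tune_mtry(X, y, hp, seed: int) -> int:
    """Inner-CV grid over mtry in {1..p}, maximizing mean validation R2.

    The grid search ranks candidates with a reduced forest
    (``tuning_ntrees``); the winning mtry is then fit with the full
    ``ntrees``.  mtry rankings stabilize quickly with tree count, so this
    keeps the search affordable without changing the selection rule.
    """
    p = X.shape[1]
    if p == 1:
        return 1
    k = min(hp["tuning_folds"], len(y))
    folds = _inner_folds(len(y), k, seed)
    best_mtry, best_score = 1, -np.inf
    for mtry in range(1, p + 1):
        scores = []
        for f in range(k):
            tr, va = folds != f, folds == f
            est = RandomForestRegressor(
                n_estimators=min(hp["ntrees"], hp["tuning_ntrees"]),
                max_features=mtry,
                random_state=seed + 7 * mtry + f,
            )
            est.fit(X[tr], y[tr])
            r2, _, _ = metrics(y[va], est.predict(X[va]))
            scores.append(r2)
        score = float(np.mean(scores))
        if score > best_score:  # ties keep the smaller, cheaper mtry
            best_mtry, best_score = mtry, score
    return best_mtry


def _tune_plsr_components(X, y, hp, seed: int) -> int:
    """Inner-CV over 1..min(p, max_latent) latent variables, minimizing RMSE."""
    p = X.shape[1]
    max_lv = min(p, hp["max_latent"])
    if max_lv == 1:
        return 1
    k = min(hp["tuning_folds"], len(y))
    folds = _inner_folds(len(y), k, seed)
    best_lv, best_rmse = 1, np.inf
    for lv in range(1, max_lv + 1):
        errors = []
        for f in range(k):
            tr, va = folds != f, folds == f
            est = PLSRegression(n_components=lv, scale=True)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[va]).ravel()
            errors.append(float(np.sqrt(np.mean((y[va] - pred) ** 2))))
        rmse = float(np.mean(errors))
        if rmse < best_rmse:
            best_lv, best_rmse = lv, rmse
    return best_lv


def _fit_family(spec: ModelSpec, X_train, y_train, X_val, fold_seed: int):
    """Fit one family on a training fold; return (cal_pred, val_pred)."""
    hp = spec.hyperparameters
    family = spec.family
    if family in _NEEDS_SCALING:
        X_train, X_val, _ = standardize_features(X_train, X_val)
    if family == "SVM":
        est = SVR(kernel="rbf", C=hp["c"], gamma=hp["g"])
    elif family == "RF":
        mtry = hp["mtry"]
        if mtry == "auto":
            mtry = _tune_mtry(X_train, y_train, hp, fold_seed)
        est = RandomForestRegressor(
            n_estimators=hp["ntrees"], max_features=mtry, random_state=fold_seed
        )
    elif family == "BPNN":
        est = MLPRegressor(
            hidden_layer_sizes=(hp["hidden_units"],) * hp["hidden_layers"],
            learning_rate_init=hp["learning_rate"],
            max_iter=hp["max_epochs"],
            solver="adam",
            random_state=fold_seed,
        )
    else:  # PLSR
        lv = hp["n_latent"]
        if lv == "auto":
            lv = _tune_plsr_components(X_train, y_train, hp, fold_seed)
        est = PLSRegression(n_components=lv, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X_train, y_train)
    cal = np.asarray(est.predict(X_train)).ravel()
    val = np.asarray(est.predict(X_val)).ravel()
    return cal, val


def fit_predict(
    spec: ModelSpec,
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    folds: np.ndarray,
    input_set: str = "features",
) -> CVResult:
    """Run one family through the cross-validation folds.

    Rows with any missing feature (or missing y) are dropped with a logged
    count before splitting.  A fold whose fit fails or predicts non-finite
    values is flagged and excluded from the aggregated means; if every fold
    fails the run errors out.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    folds = np.asarray(folds)
    if Xa.ndim != 2 or len(Xa) != len(ya) or len(folds) != len(ya):
        raise ValueError("X, y and folds must align on the sample axis")
    if Xa.shape[1] == 0:
        raise TexlaiError(f"empty feature set for {spec.family}/{input_set}")
    keep = np.isfinite(Xa).all(axis=1) & np.isfinite(ya)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info(
            "%s/%s: dropped %d incomplete rows of %d",
            spec.family, input_set, n_dropped, len(ya),
        )
    Xa, ya, folds = Xa[keep], ya[keep], folds[keep]
    if np.any(ya < 0):
        raise ValueError("LAI response must be non-negative")

    fold_ids = np.unique(folds)
    base_seed = 0 if spec.seed is None else int(spec.seed)
    fold_rows: list[FoldMetrics] = []
    flagged: list[int] = []
    oof = np.full(len(ya), np.nan)
    for f in fold_ids:
        tr, va = folds != f, folds == f
        try:
            cal_pred, val_pred = _fit_family(
                spec, Xa[tr], ya[tr], Xa[va], base_seed + int(f)
            )
            if not (np.isfinite(cal_pred).all() and np.isfinite(val_pred).all()):
                raise DomainError("non-finite predictions")
            cal = metrics(ya[tr], cal_pred)
            val = metrics(ya[va], val_pred)
        except (DomainError, ValueError) as exc:
            log.warning("%s/%s fold %s failed: %s", spec.family, input_set, f, exc)
            flagged.append(int(f))
            continue
        oof[va] = val_pred
        fold_rows.append(FoldMetrics(int(f), *cal, *val))
    if not fold_rows:
        raise TexlaiError(f"every fold failed for {spec.family}/{input_set}")
    return CVResult(
        family=spec.family,
        input_set=input_set,
        folds=fold_rows,
        oof_prediction=oof,
        y=ya,
        n_dropped=n_dropped,
        flagged_folds=flagged,
    )


def _family_seed(seed: int, family: str, input_set: str) -> int:
    tag = zlib.crc32(input_set.encode())  # stable across processes
    ss = np.random.SeedSequence([seed, FAMILIES.index(family), tag])
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    feature_table: pd.DataFrame,
    feature_sets: Mapping[str, Sequence[str]],
    seed: int,
    families: Sequence[str] = FAMILIES,
    lai_col: str = "lai",
    hyperparameters: Mapping[str, dict] | None = None,
    n_folds: int = 10,
) -> dict:
    """Fit every family on every input set under a shared fold split.

    Returns ``{"results": tidy DataFrame (family x input_set x Cal/Val),
    "cv": {(family, set): CVResult}, "predictions": out-of-fold scatter
    table, "best": (family, input_set) with max validation R2}``.
    """
    for name, cols in feature_sets.items():
        if not cols:
            raise TexlaiError(
                f"feature set {name!r} is empty; nothing to model "
                "(screening threshold too strict?)"
            )
        missing = [c for c in cols if c not in feature_table.columns]
        if missing:
            raise TexlaiError(f"feature set {name!r} misses columns {missing}")
    hyperparameters = dict(hyperparameters or {})
    y = feature_table[lai_col].to_numpy(dtype=float)
    folds = tenfold_split(len(y), seed, n_folds)

    rows, cv, preds = [], {}, []
    for set_name, cols in feature_sets.items():
        X = feature_table[list(cols)]
        for family in families:
            spec = ModelSpec(
                family,
                hyperparameters.get(family, {}),
                seed=_family_seed(seed, family, set_name),
            )
            res = fit_predict(spec, X, y, folds, input_set=set_name)
            cv[(family, set_name)] = res
            s = res.summary
            for split_key, split_name in (("cal", "Cal"), ("val", "Val")):
                rows.append(
                    {
                        "family": family,
                        "input_set": set_name,
                        "split": split_name,
                        "R2": s[f"{split_key}_R2"],
                        "RMSE": s[f"{split_key}_RMSE"],
                        "RPD": s[f"{split_key}_RPD"],
                    }
                )
            ok = np.isfinite(res.oof_prediction)
            preds.append(
                pd.DataFrame(
                    {
                        "family": family,
                        "input_set": set_name,
                        "y_true": res.y[ok],
                        "y_pred": res.oof_prediction[ok],
                    }
                )
            )
    results = pd.DataFrame(rows)
    val = results[results["split"] == "Val"]
    best_row = val.loc[val["R2"].idxmax()]
    return {
        "results": results,
        "cv": cv,
        "predictions": pd.concat(preds, ignore_index=True),
        "folds": folds,
        "best": (best_row["family"], best_row["input_set"]),
    }
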
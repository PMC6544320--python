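"""Drug-combination featurization (bitwise OR of drug-level binary
profiles), SEA prediction filtering, and the per-cell-line 70/30 + 10-fold
cross-validation harness for CSS prediction.

Learners are injected, not implemented: anything with scikit-learn's
``fit``/``predict`` contract works. The bundled default is a small ridge
grid so the harness runs dependency-light.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, train_test_split

from ._exceptions import ConfigError


@dataclass(frozen=True)
class SeaPrediction:
    """One drug-target prediction with its confidence statistics."""

    drug: str
    target: str
    z_score: float
    tanimoto: float
    p_value: float


#: strict acceptance thresholds for predicted targets
SEA_Z_MIN = 20.0
SEA_TANIMOTO_MIN = 0.4
SEA_P_MAX = 0.01


def filter_sea(predictions) -> list[tuple[str, str]]:
    """Accepted (drug, target) pairs: z > 20, Tanimoto > 0.4, p < 0.01,
    all comparisons strict."""
    kept = []
    for p in predictions:
        if p.z_score > SEA_Z_MIN and p.tanimoto > SEA_TANIMOTO_MIN \
                and p.p_value < SEA_P_MAX:
            kept.append((p.drug, p.target))
    return kept


def sea_frame_to_predictions(df: pd.DataFrame) -> list[SeaPrediction]:
    """Rows of a (drug, target, z, tanimoto, p) CSV as prediction objects."""
    required = {"drug", "target", "z", "tanimoto", "p"}
    if not required.issubset(df.columns):
        raise ConfigError(f"SEA table needs columns {sorted(required)}")
    return [SeaPrediction(str(r.drug), str(r.target), float(r.z),
                          float(r.tanimoto), float(r.p))
            for r in df.itertuples()]


def combine_features(f1, f2) -> np.ndarray:
    """Elementwise OR of two equal-length binary feature vectors."""
    a = np.asarray(f1)
    b = np.asarray(f2)
    if a.shape != b.shape:
        raise ValueError(f"feature length mismatch: {a.shape} vs {b.shape}")
    return np.logical_or(a, b).astype(np.int8)


@dataclass(frozen=True)
class DrugFeatureTable:
    """Binary drug x feature matrix (targets then fingerprint bits)."""

    drugs: tuple[str, ...]
    feature_names: tuple[str, ...]
    bits: np.ndarray

    def __post_init__(self):
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("drug names must be unique")
        if self.bits.shape != (len(self.drugs), len(self.feature_names)):
            raise ValueError("bits shape does not match drugs x features")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("feature bits must be 0/1")

    def vector(self, drug: str) -> np.ndarray:
        try:
            return self.bits[self.drugs.index(drug)]
        except ValueError:
            raise KeyError(f"unknown drug {drug!r}") from None

    def combination_vector(self, drug1: str, drug2: str) -> np.ndarray:
        return combine_features(self.vector(drug1), self.vector(drug2))

    def combination_matrix(self, pairs) -> np.ndarray:
        return np.stack([self.combination_vector(d1, d2) for d1, d2 in pairs])

    @classmethod
    def from_wide_frame(cls, df: pd.DataFrame, drug_column: str = "drug"):
        """Wide binary CSV: one row per drug, one column per feature."""
        if drug_column not in df.columns:
            raise ConfigError(f"wide feature table needs a {drug_column!r} column")
        drugs = tuple(str(d) for d in df[drug_column])
        features = tuple(c for c in df.columns if c != drug_column)
        bits = df[list(features)].to_numpy()
        return cls(drugs=drugs, feature_names=features,
                   bits=np.asarray(bits, dtype=np.int8))

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame):
        """Long CSV with columns drug, feature, value in {0, 1}."""
        required = {"drug", "feature", "value"}
        if not required.issubset(df.columns):
            raise ConfigError(f"long feature table needs columns {sorted(required)}")
        wide = (df.pivot_table(index="drug", columns="feature", values="value",
                               aggfunc="max", fill_value=0)
                .astype(np.int8))
        return cls(drugs=tuple(str(d) for d in wide.index),
                   feature_names=tuple(str(f) for f in wide.columns),
                   bits=wide.to_numpy())


# ---------------------------------------------------------------------------
# CV harness
# ---------------------------------------------------------------------------

METRICS = ("rmse", "r2", "cor", "mae")


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """RMSE, R2 (= 1 - SS_res/SS_tot, 0 when SS_tot = 0), Pearson
    correlation (0 when either side is constant) and MAE."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else float(1.0 - np.sum(err ** 2) / ss_tot)
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        cor = 0.0
    else:
        cor = float(np.corrcoef(y_true, y_pred)[0, 1])
    return {"rmse": rmse, "r2": r2, "cor": cor, "mae": mae}


def default_learners() -> list[tuple[str, object]]:
    """A small ridge-regularization grid as the bundled learner family."""
    return [(f"ridge_alpha={a}", Ridge(alpha=a)) for a in (0.1, 1.0, 10.0)]


@dataclass(frozen=True)
class CvReport:
    """Mean +/- sd of the test metrics over repeats, plus per-repeat detail."""

    mean: dict[str, float]
    sd: dict[str, float]
    per_repeat: pd.DataFrame
    n_repeats: int

    def summary(self) -> dict:
        return {m: {"mean": self.mean[m], "sd": self.sd[m]} for m in METRICS}


def _cv_rmse(learner, X, y, folds) -> float:
    errs = []
    for train_idx, val_idx in folds:
        model = clone(learner)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[val_idx])
        errs.append(np.mean((pred - y[val_idx]) ** 2))
    return float(np.sqrt(np.mean(errs)))


def cv_harness(X, y, learners=None, test_size: float = 0.3,
               n_folds: int = 10, n_repeats: int = 20, seed: int = 0) -> CvReport:
    """Repeated 70/30 evaluation with inner 10-fold model selection.

    Each repeat draws a random train/test split (test combinations never
    appear in training), selects the learner with the lowest 10-fold CV RMSE
    on the training part, refits it there and evaluates on the held-out 30%.
    Metrics are reported as mean +/- sd over repeats; identical seeds give
    identical splits and metrics. A learner failure skips the repeat with a
    warning; if every repeat fails a ``RuntimeError`` is raised.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(y) < 20:
        raise ValueError("need at least 20 combinations for the harness")
    if learners is None:
        learners = default_learners()

    rng = np.random.default_rng(seed)
    rows = []
    for repeat in range(n_repeats):
        rs = int(rng.integers(0, 2 ** 31 - 1))
        try:
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=test_size, random_state=rs)
            folds = list(KFold(n_splits=n_folds, shuffle=True,
                               random_state=rs).split(X_tr))
            cv_scores = [(_cv_rmse(est, X_tr, y_tr, folds), name, est)
                         for name, est in learners]
            _, best_name, best_est = min(cv_scores, key=lambda t: t[0])
            model = clone(best_est)
            model.fit(X_tr, y_tr)
            metrics = regression_metrics(y_te, model.predict(X_te))
        except Exception as exc:  # noqa: BLE001 - learner contract violation
            warnings.warn(f"repeat {repeat}: learner failed ({exc}); skipped")
            continue
        rows.append({"repeat": repeat, "learner": best_name, **metrics})

    if not rows:
        raise RuntimeError("all CV repeats failed")
    per_repeat = pd.DataFrame(rows)
    mean = {m: float(per_repeat[m].mean()) for m in METRICS}
    sd = {m: float(per_repeat[m].std(ddof=1)) if len(rows) > 1 else 0.0
          for m in METRICS}
    return CvReport(mean=mean, sd=sd, per_repeat=per_repeat, n_repeats=len(rows))
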
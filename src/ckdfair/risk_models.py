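"""Pooled and race-specific (modular) risk models.

A small fully connected network (two hidden layers, 64 and 32 rectifier
units, sigmoid output) trained with class-weighted binary cross-entropy plus
an L2 penalty, optimized by Adam with mini-batches of 32, early stopping on a
held-out validation slice, and minority-class duplication oversampling.  The
implementation is plain numpy: forward/backward passes are exact and the
whole fit is deterministic given the seed under single-threaded BLAS.

Two training strategies are exposed: ``pooled`` (one race-blind model per
cross-validation fold, race never a feature) and ``modular`` (per fold, one
model per race trained only on that race's training rows; each patient is
scored by their own group's model).  All evaluation downstream uses
out-of-fold predictions only.

Because the training loss up-weights the positive class (class weight x
duplication factor), the raw sigmoid outputs sit on an inflated probability
scale.  Predictions are mapped back to the natural five-year risk scale by a
prior correction: a single logit shift solved on the fold's training portion
so that the mean corrected prediction equals the training-portion event rate
(recalibration-in-the-large; for a fully converged well-specified logistic
model the solved shift equals ``ln(effective positive weight)``).  The shift
uses training rows only, so out-of-fold purity is preserved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .harmonize import (
    BIOMARKER_FEATURES,
    CLINICAL_FEATURES,
    apply_preprocessor,
    fit_preprocessor,
)

__all__ = [
    "MlpConfig",
    "FittedModel",
    "make_cv_folds",
    "oversample_duplicate",
    "train_mlp",
    "predict_risk",
    "run_strategy",
    "run_biomarker_variant",
    "write_predictions_csv",
    "read_predictions_csv",
]

STRATEGIES = ("pooled", "modular")


@dataclass
class MlpConfig:
    """Training hyperparameters for the progression classifier."""

    hidden_sizes: tuple = (64, 32)
    l2_penalty: float = 0.001
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    early_stopping_patience: int = 10
    validation_fraction: float = 0.2
    class_weight: float = 3.0
    oversample_factor: int = 2
    prior_correction: bool = True
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 42

    def validate(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be positive")
        for name in ("l2_penalty", "learning_rate", "batch_size", "max_epochs",
                     "early_stopping_patience", "class_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.early_stopping_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0,1)")
        if self.oversample_factor < 1 or int(self.oversample_factor) != self.oversample_factor:
            raise ValueError("oversample_factor must be an integer >= 1")


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------

def make_cv_folds(cohort: pd.DataFrame, k: int = 5, seed: int = 42) -> np.ndarray:
    """Assign each row to one of ``k`` folds, stratified on (outcome x race).

    Every fold then carries a comparable race composition and event rate.
    Deterministic given the seed; raises if any joint stratum is smaller
    than ``k``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    for col in ("progression", "race"):
        if col not in cohort.columns:
            raise ValueError(f"cohort must have a {col!r} column")
    strata = (
        cohort["race"].astype(str) + "|" + cohort["progression"].astype(int).astype(str)
    )
    small = strata.value_counts()
    if (small < k).any():
        worst = small.idxmin()
        raise ValueError(
            f"stratum {worst!r} has {small.min()} rows, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(cohort), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(cohort)), strata)):
        folds[test_idx] = f
    return folds


def oversample_duplicate(training_indices, labels, factor: int) -> np.ndarray:
    """Duplicate minority-class rows ``factor`` times (majority stays once).

    Returns the expanded index list: original order first, then the extra
    minority copies appended in original order, once per extra round.  Ties
    in class size count the positive class as the minority.  Never applied to
    validation or test rows by the callers in this module.
    """
    idx = np.asarray(training_indices)
    y = np.asarray(labels).astype(int)
    if idx.shape != y.shape:
        raise ValueError("training_indices and labels must align")
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be an integer >= 1")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    minority = 1 if n_pos <= n_neg else 0
    if (y == minority).sum() == 0:
        raise ValueError("no minority-class examples to oversample")
    if factor == 1:
        return idx.copy()
    extra = np.tile(idx[y == minority], int(factor) - 1)
    return np.concatenate([idx, extra])


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A trained network plus everything needed to reproduce its predictions."""

    weights: list               # [(W, b), ...] per layer, output last
    feature_names: list
    strategy: str = "pooled"    # "pooled" or "modular:<race>"
    effective_pos_weight: float = 1.0
    prior_correction: bool = True
    logit_shift: float = 0.0    # subtracted from raw logits at predict time
    epochs_run: int = 0
    final_val_loss: float = math.nan

    def to_json(self) -> str:
        """Serialize to a portable JSON weight format (shapes + row-major)."""
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "strategy": self.strategy,
                "effective_pos_weight": self.effective_pos_weight,
                "prior_correction": self.prior_correction,
                "logit_shift": self.logit_shift,
                "epochs_run": self.epochs_run,
                "final_val_loss": self.final_val_loss,
                "layers": [
                    {
                        "shape": list(W.shape),
                        "weights": W.ravel().tolist(),
                        "bias": b.tolist(),
                    }
                    for W, b in self.weights
                ],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        weights = [
            (
                np.array(layer["weights"], dtype=float).reshape(layer["shape"]),
                np.array(layer["bias"], dtype=float),
            )
            for layer in d["layers"]
        ]
        return cls(
            weights=weights,
            feature_names=d["feature_names"],
            strategy=d["strategy"],
            effective_pos_weight=d["effective_pos_weight"],
            prior_correction=d["prior_correction"],
            logit_shift=d["logit_shift"],
            epochs_run=d["epochs_run"],
            final_val_loss=d["final_val_loss"],
        )


def _forward(weights, x):
    """Forward pass; returns activations of every layer (input first)."""
    acts = [x]
    h = x
    for i, (W, b) in enumerate(weights):
        z = h @ W + b
        if i < len(weights) - 1:
            h = np.maximum(z, 0.0)       # rectifier
        else:
            h = 1.0 / (1.0 + np.exp(-z))  # sigmoid probability
        acts.append(h)
    return acts

def _weighted_bce(p, y, w):
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    ll = w * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(-ll.sum() / w.sum())


def _stratified_split(y, fraction, rng):
    """Deterministic stratified holdout; returns (train_idx, val_idx)."""
    train_idx, val_idx = [], []
    for cls in (0, 1):
        cls_idx = np.nonzero(y == cls)[0]
        perm = rng.permutation(cls_idx)
        n_val = max(1, int(round(fraction * cls_idx.size)))
        val_idx.append(perm[:n_val])
        train_idx.append(perm[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train_mlp(
    features,
    labels,
    config: MlpConfig,
    seed: int | None = None,
    strategy: str = "pooled",
) -> FittedModel:
    """Train the network on a fold's training portion.

    A stratified ``validation_fraction`` slice is carved out first and used
    only for early stopping (weighted cross-entropy, patience on consecutive
    non-improving epochs, best weights restored).  Minority-class duplication
    oversampling is applied to the remaining rows only.  Deterministic given
    the seed and a fixed thread count.
    """
    config.validate()
    X = np.asarray(features, dtype=float)
    feature_names = (
        list(features.columns) if isinstance(features, pd.DataFrame)
        else [f"x{i}" for i in range(X.shape[1])]
    )
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features and labels must align")
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class; cannot train")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    fit_idx, val_idx = _stratified_split(y.astype(int), config.validation_fraction, rng)
    expanded = oversample_duplicate(
        fit_idx, y[fit_idx].astype(int), config.oversample_factor
    )
    Xtr, ytr = X[expanded], y[expanded]
    Xval, yval = X[val_idx], y[val_idx]
    wtr = np.where(ytr == 1, config.class_weight, 1.0)
    wval = np.where(yval == 1, config.class_weight, 1.0)

    # Effective positive-class weight in the training loss: explicit class
    # weight times the duplication multiplicity of the minority class.
    n_pos = int((y[fit_idx] == 1).sum())
    n_neg = fit_idx.size - n_pos
    dup_pos = config.oversample_factor if n_pos <= n_neg else 1
    dup_neg = config.oversample_factor if n_neg < n_pos else 1
    effective_pos_weight = config.class_weight * dup_pos / dup_neg

    # He-style initialization for rectifier layers.
    sizes = [X.shape[1], *config.hidden_sizes, 1]
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        weights.append((W, np.zeros(fan_out)))

    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    b1, b2, eps = config.adam_beta1, config.adam_beta2, config.adam_eps
    step = 0

    best_loss, best_weights, since_best, epochs_run = math.inf, None, 0, 0
    n = Xtr.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            xb, yb, wb = Xtr[batch], ytr[batch], wtr[batch]
            acts = _forward(weights, xb)
            p = acts[-1][:, 0]
            if np.isnan(p).any():
                raise RuntimeError(
                    f"NaN loss at epoch {epoch}, step {step}: diverged "
                    f"(lr={config.learning_rate}, l2={config.l2_penalty})"
                )
            # Gradient of mean weighted BCE wrt output pre-activation.
            delta = (wb * (p - yb) / wb.sum())[:, None]
            grads = []
            for li in range(len(weights) - 1, -1, -1):
                W, _ = weights[li]
                h_prev = acts[li]
                gW = h_prev.T @ delta + 2.0 * config.l2_penalty * W
                gb = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ W.T) * (acts[li] > 0)
                grads.append((gW, gb))
            grads.reverse()
            step += 1
            new_weights = []
            for li, ((W, b), (gW, gb)) in enumerate(zip(weights, grads)):
                mW = b1 * m[li][0] + (1 - b1) * gW
                mb = b1 * m[li][1] + (1 - b1) * gb
                vW = b2 * v[li][0] + (1 - b2) * gW**2
                vb = b2 * v[li][1] + (1 - b2) * gb**2
                m[li], v[li] = (mW, mb), (vW, vb)
                mhW, mhb = mW / (1 - b1**step), mb / (1 - b1**step)
                vhW, vhb = vW / (1 - b2**step), vb / (1 - b2**step)
                new_weights.append((
                    W - config.learning_rate * mhW / (np.sqrt(vhW) + eps),
                    b - config.learning_rate * mhb / (np.sqrt(vhb) + eps),
                ))
            weights = new_weights
        epochs_run = epoch + 1
        val_p = _forward(weights, Xval)[-1][:, 0]
        val_loss = _weighted_bce(val_p, yval, wval)
        if math.isnan(val_loss):
            raise RuntimeError(f"NaN validation loss at epoch {epoch}")
        if val_loss < best_loss - 1e-9:
            best_loss, since_best = val_loss, 0
            best_weights = [(W.copy(), b.copy()) for W, b in weights]
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                break
    if best_weights is None:
        best_weights = weights

    # Prior correction: one logit shift, solved on the training portion so
    # the mean corrected prediction matches the (unweighted) event rate.
    logit_shift = 0.0
    if config.prior_correction and effective_pos_weight != 1.0:
        from scipy.optimize import brentq

        raw = np.clip(_forward(best_weights, X)[-1][:, 0], 1e-12, 1 - 1e-12)
        raw_logits = np.log(raw / (1.0 - raw))
        target = float(y.mean())

        def gap(delta):
            return float(np.mean(1.0 / (1.0 + np.exp(-(raw_logits - delta))))) - target

        lo, hi = -20.0, 20.0
        if gap(lo) > 0 and gap(hi) < 0:
            logit_shift = float(brentq(gap, lo, hi, xtol=1e-10))
        else:  # extreme degenerate outputs: fall back to the analytic shift
            logit_shift = math.log(effective_pos_weight)

    return FittedModel(
        weights=best_weights,
        feature_names=feature_names,
        strategy=strategy,
        effective_pos_weight=effective_pos_weight,
        prior_correction=config.prior_correction,
        logit_shift=logit_shift,
        epochs_run=epochs_run,
        final_val_loss=best_loss,
    )


def predict_risk(model: FittedModel, features) -> np.ndarray:
    """Predicted five-year progression probability on the natural scale.

    Row-wise (batch-size invariant).  When the model was trained with an
    up-weighted positive class and prior correction is enabled, the raw
    sigmoid output is shifted on the logit scale by the training-portion
    recalibration constant to undo the sampling/weighting bias.
    """
    if isinstance(features, pd.DataFrame):
        if list(features.columns) != list(model.feature_names):
            raise ValueError(
                f"feature columns {list(features.columns)} do not match the "
                f"training schema {list(model.feature_names)}"
            )
        X = features.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {X.shape[1]}"
            )
    p = _forward(model.weights, X)[-1][:, 0]
    if model.prior_correction and model.logit_shift != 0.0:
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        logits = np.log(p / (1.0 - p)) - model.logit_shift
        p = 1.0 / (1.0 + np.exp(-logits))
    return p


# ---------------------------------------------------------------------------
# Cross-validated strategies
# ---------------------------------------------------------------------------

def _derive_seed(seed: int, fold: int, group_index: int) -> int:
    return (seed * 1009 + fold * 13 + group_index) % (2**31 - 1)


def run_strategy(
    cohort: pd.DataFrame,
    strategy: str,
    config: MlpConfig,
    k: int = 5,
    feature_names=CLINICAL_FEATURES,
    seed: int | None = None,
    variant: str = "clinical",
    return_models: bool = False,
):
    """Cross-validated out-of-fold predictions for one training strategy.

    ``pooled`` trains one race-blind model per fold on all training rows;
    ``modular`` trains one model per race per fold on that race's training
    rows only and scores each test patient with their own group's model.
    Preprocessing is fit on each model's training rows only.  Returns a tidy
    predictions frame (id, race, outcome, fold, strategy, variant, risk) with
    exactly one out-of-fold prediction per patient.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    seed = config.seed if seed is None else seed
    folds = make_cv_folds(cohort, k=k, seed=seed)
    races = sorted(cohort["race"].unique())
    records = []
    models = {}
    for f in range(k):
        train_rows = cohort.loc[folds != f]
        test_rows = cohort.loc[folds == f]
        if strategy == "pooled":
            groups = [("all", train_rows, test_rows)]
        else:
            groups = []
            for race in races:
                tr = train_rows.loc[train_rows["race"] == race]
                te = test_rows.loc[test_rows["race"] == race]
                if len(tr) == 0:
                    raise ValueError(
                        f"race stratum {race!r} absent from training fold {f}"
                    )
                groups.append((race, tr, te))
        for gi, (gname, tr, te) in enumerate(groups):
            state = fit_preprocessor(tr, feature_names=feature_names)
            Xtr = apply_preprocessor(state, tr)
            tag = "pooled" if strategy == "pooled" else f"modular:{gname}"
            model = train_mlp(
                Xtr,
                tr["progression"].to_numpy(),
                config,
                seed=_derive_seed(seed, f, gi),
                strategy=tag,
            )
            models[(f, gname)] = (model, state)
            if len(te) == 0:
                continue
            Xte = apply_preprocessor(state, te)
            risk = predict_risk(model, Xte)
            records.append(pd.DataFrame({
                "id": te["id"].to_numpy(),
                "race": te["race"].to_numpy(),
                "outcome": te["progression"].to_numpy().astype(int),
                "fold": f,
                "strategy": strategy,
                "variant": variant,
                "risk": risk,
            }))
    preds = pd.concat(records, ignore_index=True).sort_values("id").reset_index(drop=True)
    if preds["id"].duplicated().any() or len(preds) != len(cohort):
        raise AssertionError("out-of-fold predictions must cover each patient once")
    if return_models:
        return preds, models
    return preds


def run_biomarker_variant(
    cohort_subset: pd.DataFrame,
    strategy: str,
    config: MlpConfig,
    k: int = 5,
    seed: int | None = None,
):
    """Cross-validated predictions for the biomarker-augmented (18-feature) model.

    Trained and evaluated strictly within the sub-cohort in which TNFR1,
    TNFR2 and KIM-1 were measured.  Biomarkers are never imputed: any row
    with a missing biomarker is an error.
    """
    biomarkers = ["tnfr1", "tnfr2", "kim1"]
    missing_cols = [c for c in biomarkers if c not in cohort_subset.columns]
    if missing_cols:
        raise ValueError(f"missing biomarker columns: {missing_cols}")
    if cohort_subset[biomarkers].isna().any().any():
        n_bad = int(cohort_subset[biomarkers].isna().any(axis=1).sum())
        raise ValueError(
            f"{n_bad} rows lack biomarker measurements; biomarkers are never "
            "imputed -- restrict to the measured sub-cohort"
        )
    return run_strategy(
        cohort_subset,
        strategy,
        config,
        k=k,
        feature_names=BIOMARKER_FEATURES,
        seed=seed,
        variant="biomarker",
    )


# ---------------------------------------------------------------------------
# Predictions CSV
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ["id", "race", "outcome", "fold", "strategy", "variant", "risk"]


def write_predictions_csv(preds: pd.DataFrame, path) -> None:
    preds[PREDICTION_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_predictions_csv(path) -> pd.DataFrame:
    preds = pd.read_csv(path)
    missing = [c for c in PREDICTION_COLUMNS if c not in preds.columns]
    if missing:
        raise ValueError(f"predictions CSV missing columns: {missing}")
    return preds[PREDICTION_COLUMNS]
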
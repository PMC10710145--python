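"""Train/test protocol, scaling, MVAE training loop, regression head, metrics.

The protocol follows the study design: 20% of subjects are randomly held out
as the test set; features are min-max scaled per view on the training
subjects only (the Bernoulli cross-entropy reconstruction requires inputs in
[0, 1]); the MVAE is trained by mini-batch Adam on the negative ELBO; the
fused posterior mean is the extracted latent representation; an ordinary
least-squares linear head predicts the phenotype from the latents; and
performance is reported as MAE, MAPE, RMSE and the R^2 score.  A grid search
over MLP depth, hidden width and latent dimension selects the configuration
with the highest R^2 on a validation split carved from the training data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .mvae import (
    MVAEParams,
    ViewSpec,
    encode,
    init_params,
    loss_and_grads,
    poe_fuse,
)

__all__ = [
    "TrainConfig",
    "Scaler",
    "LinearHead",
    "PredictionReport",
    "split_train_test",
    "fit_scaler",
    "apply_scaler",
    "train_mvae",
    "extract_latents",
    "fit_head",
    "predict",
    "evaluate",
    "grid_search",
    "DEFAULT_SEARCH_SPACE",
]

logger = logging.getLogger(__name__)

#: Grid-search space: MLP layers 1-3; hidden units and latent dimension
#: each from {32, 48, 64, 128, 256}.
DEFAULT_SEARCH_SPACE = {
    "n_layers": (1, 2, 3),
    "hidden_units": (32, 48, 64, 128, 256),
    "latent_dim": (32, 48, 64, 128, 256),
}


@dataclass
class TrainConfig:
    test_fraction: float = 0.20
    latent_dim: int = 32
    n_layers: int = 2
    hidden_units: int = 64
    epochs: int = 500
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 50  # early stop on validation-loss plateau, if val data given
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        for name in ("latent_dim", "n_layers", "hidden_units", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class Scaler:
    """Per-view, per-feature training min/max for [0, 1] scaling."""

    mins: list
    maxs: list


@dataclass
class LinearHead:
    coef: np.ndarray
    intercept: float
    ridge: bool = False


@dataclass
class PredictionReport:
    mae: float
    mape: float | None  # percent; None when some y == 0
    rmse: float
    r2: float
    pairs: np.ndarray = field(repr=False)  # (N, 2) columns y, yhat


def split_train_test(n_subjects: int, test_fraction: float = 0.20, seed: int = 0):
    """Disjoint, exhaustive train/test index split; |test| = round(n * frac)."""
    if n_subjects < 5:
        raise ValueError("need at least 5 subjects to split")
    n_test = int(round(n_subjects * test_fraction))
    if n_test == 0 or n_test == n_subjects:
        raise ValueError(f"test_fraction={test_fraction} yields an empty split")
    perm = np.random.default_rng(seed).permutation(n_subjects)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def fit_scaler(train_views) -> Scaler:
    """Per-feature min/max on training subjects only."""
    mins, maxs = [], []
    for v in train_views:
        v = np.asarray(v, dtype=float)
        mins.append(v.min(axis=0))
        maxs.append(v.max(axis=0))
    return Scaler(mins=mins, maxs=maxs)


def apply_scaler(scaler: Scaler, views) -> list:
    """(x - min) / (max - min), constant features mapped to 0.5, results
    clipped to [0, 1] (test values may fall outside the training range)."""
    out = []
    for v, lo, hi in zip(views, scaler.mins, scaler.maxs, strict=True):
        v = np.asarray(v, dtype=float)
        span = hi - lo
        safe = np.where(span > 0, span, 1.0)
        scaled = np.where(span > 0, (v - lo) / safe, 0.5)
        out.append(np.clip(scaled, 0.0, 1.0))
    return out


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _adam_state(weights):
    def zeros(tree):
        return {
            k: [(np.zeros_like(W), np.zeros_like(b)) for W, b in v]
            if isinstance(v, list) else (np.zeros_like(v[0]), np.zeros_like(v[1]))
            for k, v in tree.items()
        }
    return {m: zeros(t) for m, t in weights.items()}, {m: zeros(t) for m, t in weights.items()}


def _adam_step(weights, grads, m1, m2, lr, t, b1=0.9, b2=0.999, eps=1e-8):
    c1 = 1.0 - b1**t
    c2 = 1.0 - b2**t
    for view, tree in weights.items():
        for key, val in tree.items():
            entries = enumerate(val) if isinstance(val, list) else [(None, val)]
            for i, (W, b) in entries:
                gW, gb = (grads[view][key][i] if i is not None else grads[view][key])
                sW, sb = (m1[view][key][i] if i is not None else m1[view][key])
                vW, vb = (m2[view][key][i] if i is not None else m2[view][key])
                sW += (1 - b1) * (gW - sW)
                sb += (1 - b1) * (gb - sb)
                vW += (1 - b2) * (gW * gW - vW)
                vb += (1 - b2) * (gb * gb - vb)
                W -= lr * (sW / c1) / (np.sqrt(vW / c2) + eps)
                b -= lr * (sb / c1) / (np.sqrt(vb / c2) + eps)


def _epoch_loss(params, views_dict, rng_eval):
    n = next(iter(views_dict.values())).shape[0]
    noise = rng_eval.standard_normal((n, params.latent_dim))
    parts, _ = loss_and_grads(params, views_dict, noise)
    return parts.total / n


def train_mvae(train_views, config: TrainConfig, view_names=None, val_views=None):
    """Mini-batch Adam on the negative ELBO.

    ``train_views`` is a list of row-aligned (N x P_m) matrices already
    scaled to [0, 1].  Returns (MVAEParams, per-epoch mean-loss trace).
    Fully reproducible under ``config.seed`` (initialization, batch order,
    reparameterization noise).  If ``val_views`` is given, training stops
    early when the validation loss has not improved for ``config.patience``
    epochs.
    """
    train_views = [np.asarray(v, dtype=float) for v in train_views]
    n = train_views[0].shape[0]
    if any(v.shape[0] != n for v in train_views):
        raise ValueError("views must be row-aligned")
    names = view_names or [f"view{i}" for i in range(len(train_views))]
    specs = [
        ViewSpec(name=nm, input_dim=v.shape[1],
                 n_layers=config.n_layers, hidden_units=config.hidden_units)
        for nm, v in zip(names, train_views)
    ]
    params = init_params(specs, config.latent_dim, seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))

    m1, m2 = _adam_state(params.weights)
    trace = []
    best_val, since_best = np.inf, 0
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = {nm: v[idx] for nm, v in zip(names, train_views)}
            noise = rng.standard_normal((idx.size, config.latent_dim))
            parts, grads = loss_and_grads(params, batch, noise)
            if not np.isfinite(parts.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            step += 1
            _adam_step(params.weights, grads, m1, m2, config.learning_rate, step)
            epoch_total += parts.total
        trace.append(epoch_total / n)
        if val_views is not None:
            val = {nm: np.asarray(v, dtype=float) for nm, v in zip(names, val_views)}
            noise = rng.standard_normal((val[names[0]].shape[0], config.latent_dim))
            vparts, _ = loss_and_grads(params, val, noise)
            vloss = vparts.total / val[names[0]].shape[0]
            if vloss < best_val - 1e-9:
                best_val, since_best = vloss, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    logger.info("early stop at epoch %d (val plateau)", epoch)
                    break
    return params, np.asarray(trace)


def extract_latents(params: MVAEParams, views, view_names=None) -> np.ndarray:
    """Fused posterior mean per subject (noise-free), N x D."""
    names = view_names or params.views()
    if len(names) != len(views):
        raise ValueError("view count does not match the trained architecture")
    posts = [encode(v, params, nm) for nm, v in zip(names, views)]
    return poe_fuse(posts).mean


# ---------------------------------------------------------------------------
# Regression head and metrics
# ---------------------------------------------------------------------------

def fit_head(latents_train: np.ndarray, y_train: np.ndarray) -> LinearHead:
    """OLS with intercept; falls back to a tiny-penalty ridge when the
    latent design is rank-deficient or underdetermined."""
    Z = np.atleast_2d(np.asarray(latents_train, dtype=float))
    y = np.asarray(y_train, dtype=float)
    n, d = Z.shape
    X = np.column_stack([np.ones(n), Z])
    if n > d and np.linalg.matrix_rank(X) == d + 1:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return LinearHead(coef=beta[1:], intercept=float(beta[0]))
    logger.warning("degenerate latent design (n=%d, D=%d): ridge fallback", n, d)
    model = Ridge(alpha=1e-6).fit(Z, y)
    return LinearHead(coef=model.coef_, intercept=float(model.intercept_), ridge=True)


def predict(head: LinearHead, latents: np.ndarray) -> np.ndarray:
    Z = np.atleast_2d(np.asarray(latents, dtype=float))
    return Z @ head.coef + head.intercept


def evaluate(y: np.ndarray, yhat: np.ndarray) -> PredictionReport:
    """MAE, MAPE (percent, denominator y_i as defined), RMSE and R^2.

    MAPE is undefined (None) when any y equals zero; other metrics are
    still returned.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat lengths differ")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / ss_tot) if ss_tot > 0 else float("nan")
    if np.any(y == 0.0):
        logger.warning("MAPE undefined: phenotype contains zeros")
        mape = None
    else:
        mape = float(np.mean(np.abs(err) / y) * 100.0)
    return PredictionReport(mae=mae, mape=mape, rmse=rmse, r2=r2,
                            pairs=np.column_stack([y, yhat]))


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def grid_search(train_views, y_train, base_config: TrainConfig,
                space: dict | None = None, val_fraction: float = 0.20):
    """Train one model per (n_layers, hidden_units, latent_dim) grid point
    and select the highest validation R^2.

    A validation split is carved from the training subjects (selection on
    the held-out test set would leak).  Failed grid points are recorded and
    skipped.  Returns (best TrainConfig, results DataFrame sorted by R^2).
    """
    space = dict(DEFAULT_SEARCH_SPACE, **(space or {}))
    if not all(space.values()):
        raise ValueError("search space must be nonempty")
    y_train = np.asarray(y_train, dtype=float)
    n = train_views[0].shape[0]
    fit_idx, val_idx = split_train_test(n, val_fraction, seed=base_config.seed)
    rows = []
    best = None
    for n_layers, hidden, latent in itertools.product(
        space["n_layers"], space["hidden_units"], space["latent_dim"]
    ):
        cfg = replace(base_config, n_layers=n_layers, hidden_units=hidden,
                      latent_dim=latent)
        row = {"n_layers": n_layers, "hidden_units": hidden, "latent_dim": latent}
        try:
            inner = [v[fit_idx] for v in train_views]
            outer = [v[val_idx] for v in train_views]
            scaler = fit_scaler(inner)
            inner_s = apply_scaler(scaler, inner)
            outer_s = apply_scaler(scaler, outer)
            params, _ = train_mvae(inner_s, cfg, val_views=outer_s)
            head = fit_head(extract_latents(params, inner_s), y_train[fit_idx])
            rep = evaluate(y_train[val_idx], predict(head, extract_latents(params, outer_s)))
            row.update(r2=rep.r2, rmse=rep.rmse, mae=rep.mae, mape=rep.mape, failed=False)
            if best is None or rep.r2 > best[0]:
                best = (rep.r2, cfg)
        except Exception as exc:  # grid point failure must not kill the search
            logger.warning("grid point %s failed: %s", row, exc)
            row.update(r2=np.nan, rmse=np.nan, mae=np.nan, mape=np.nan, failed=True)
        rows.append(row)
    if best is None:
        raise RuntimeError("every grid point failed")
    results = pd.DataFrame(rows).sort_values("r2", ascending=False).reset_index(drop=True)
    return best[1], results
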
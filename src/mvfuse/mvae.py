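"""Multi-view variational autoencoder with product-of-experts fusion.

Each view m has an MLP encoder producing a diagonal-Gaussian posterior
N(mu_m, diag(sigma_m^2)) over a shared D-dimensional latent space (the
log-variance head is exponentiated, so variances are positive by
construction).  The per-view posteriors are fused in closed form by a
product of experts: for Gaussians the product is Gaussian with

    precision_z = sum_m precision_m,
    mu_z = (sum_m mu_m * precision_m) / precision_z,

per latent dimension.  A sample z = mu_z + sigma_z * eps (reparameterization
trick) is decoded by per-view MLP decoders with a logistic-sigmoid output, and
the loss is the negative evidence lower bound: Bernoulli cross-entropy
reconstruction over all views plus the closed-form KL divergence from the
fused posterior to the standard-normal prior,

    KL = (1/2) sum_d (mu_d^2 + sigma_d^2 - log sigma_d^2 - 1).

The networks are small dense MLPs implemented directly in numpy with
analytically derived gradients (validated against finite differences in the
test suite); hidden layers use ReLU, log-variance outputs are clamped to
[-10, 10] for numerical stability, and weights are fan-in-scaled random
draws under the run seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ViewSpec",
    "GaussianPosterior",
    "FusedPosterior",
    "MVAEParams",
    "init_params",
    "encode",
    "poe_fuse",
    "reparameterize",
    "decode",
    "kl_to_standard_normal",
    "negative_elbo",
    "ELBOParts",
    "loss_and_grads",
    "save_params",
    "load_params",
]

_LOGVAR_CLAMP = 10.0
_EPS = 1e-7

LAYER_CHOICES = (1, 2, 3)
HIDDEN_CHOICES = (32, 48, 64, 128, 256)
LATENT_CHOICES = (32, 48, 64, 128, 256)


@dataclass
class ViewSpec:
    """Architecture of one view: input width and encoder/decoder MLP shape.

    ``n_layers`` hidden layers of ``hidden_units`` units each are used in
    both the encoder and the decoder.  The declared grid-search choices are
    {1,2,3} layers and {32,48,64,128,256} units, but any positive values are
    accepted.
    """

    name: str
    input_dim: int
    n_layers: int = 2
    hidden_units: int = 64

    def __post_init__(self):
        if self.input_dim < 1 or self.n_layers < 1 or self.hidden_units < 1:
            raise ValueError("ViewSpec dimensions must be positive")


@dataclass
class GaussianPosterior:
    """Per-subject diagonal-Gaussian posterior: mean and log-variance,
    each of shape (n_subjects, D)."""

    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=float))
        self.log_variance = np.atleast_2d(np.asarray(self.log_variance, dtype=float))
        if self.mean.shape != self.log_variance.shape:
            raise ValueError("mean and log_variance shapes differ")
        if not (np.isfinite(self.mean).all() and np.isfinite(self.log_variance).all()):
            raise ValueError("posterior parameters must be finite")

    @property
    def variance(self) -> np.ndarray:
        return np.exp(self.log_variance)

    @property
    def latent_dim(self) -> int:
        return self.mean.shape[1]


class FusedPosterior(GaussianPosterior):
    """Product-of-experts fusion of per-view posteriors; its variance is
    elementwise no larger than any expert's."""


class ELBOParts(NamedTuple):
    total: float
    reconstruction: float
    kl: float


@dataclass
class MVAEParams:
    """All weights of the model plus the architecture metadata needed to
    rebuild it (view specs, latent dimension, seed).

    ``weights[view]`` holds ``enc_hidden`` (list of (W, b)), ``enc_mu``,
    ``enc_logvar``, ``dec_hidden`` (list of (W, b)) and ``dec_out``.
    """

    view_specs: dict
    latent_dim: int
    seed: int
    weights: dict

    def views(self):
        return list(self.view_specs)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _init_layer(rng, fan_in, fan_out, relu=True):
    scale = np.sqrt((2.0 if relu else 1.0) / fan_in)
    return rng.normal(0.0, scale, (fan_in, fan_out)), np.zeros(fan_out)


def init_params(view_specs, latent_dim: int, seed: int = 0) -> MVAEParams:
    """Fan-in-scaled random initialization of every view's encoder/decoder."""
    if latent_dim < 1:
        raise ValueError("latent_dim must be positive")
    rng = np.random.default_rng(seed)
    specs = {s.name: s for s in view_specs}
    weights = {}
    for name, spec in specs.items():
        enc_hidden = []
        fan = spec.input_dim
        for _ in range(spec.n_layers):
            enc_hidden.append(_init_layer(rng, fan, spec.hidden_units))
            fan = spec.hidden_units
        enc_mu = _init_layer(rng, fan, latent_dim, relu=False)
        enc_logvar = _init_layer(rng, fan, latent_dim, relu=False)
        dec_hidden = []
        fan = latent_dim
        for _ in range(spec.n_layers):
            dec_hidden.append(_init_layer(rng, fan, spec.hidden_units))
            fan = spec.hidden_units
        dec_out = _init_layer(rng, fan, spec.input_dim, relu=False)
        weights[name] = {
            "enc_hidden": enc_hidden,
            "enc_mu": enc_mu,
            "enc_logvar": enc_logvar,
            "dec_hidden": dec_hidden,
            "dec_out": dec_out,
        }
    return MVAEParams(view_specs=specs, latent_dim=latent_dim, seed=seed, weights=weights)


# ---------------------------------------------------------------------------
# Forward operations
# ---------------------------------------------------------------------------

def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _check_view(params: MVAEParams, view: str):
    if view not in params.view_specs:
        raise ValueError(f"unknown view '{view}'")
    return params.view_specs[view]


def _encode_cached(x, w):
    acts = [x]
    h = x
    for W, b in w["enc_hidden"]:
        h = np.maximum(h @ W + b, 0.0)
        acts.append(h)
    W, b = w["enc_mu"]
    mu = h @ W + b
    W, b = w["enc_logvar"]
    s_raw = h @ W + b
    s = np.clip(s_raw, -_LOGVAR_CLAMP, _LOGVAR_CLAMP)
    return mu, s, s_raw, acts


def encode(view_features: np.ndarray, params: MVAEParams, view: str) -> GaussianPosterior:
    """Per-view Gaussian posterior: mean head and exponentiated
    log-variance head of the view's encoder MLP."""
    spec = _check_view(params, view)
    x = np.atleast_2d(np.asarray(view_features, dtype=float))
    if x.shape[1] != spec.input_dim:
        raise ValueError(
            f"view '{view}' expects width {spec.input_dim}, got {x.shape[1]}"
        )
    mu, s, _, _ = _encode_cached(x, params.weights[view])
    return GaussianPosterior(mean=mu, log_variance=s)


def poe_fuse(posteriors) -> FusedPosterior:
    """Closed-form product-of-experts fusion of diagonal Gaussians.

    Precisions add; the fused mean is the precision-weighted mean of the
    expert means.  With a single expert the fusion is the identity.
    """
    posteriors = list(posteriors)
    if not posteriors:
        raise ValueError("poe_fuse requires at least one posterior")
    d = posteriors[0].mean.shape
    if any(p.mean.shape != d for p in posteriors):
        raise ValueError("experts disagree on latent dimension or batch size")
    prec = np.stack([np.exp(-p.log_variance) for p in posteriors])
    prec_z = prec.sum(axis=0)
    mean_z = np.einsum("mnd,mnd->nd", prec, np.stack([p.mean for p in posteriors])) / prec_z
    return FusedPosterior(mean=mean_z, log_variance=-np.log(prec_z))


def reparameterize(posterior: GaussianPosterior, noise: np.ndarray) -> np.ndarray:
    """z = mean + sqrt(variance) * noise, elementwise."""
    noise = np.asarray(noise, dtype=float)
    if noise.shape != posterior.mean.shape:
        raise ValueError("noise shape must match the posterior")
    return posterior.mean + np.exp(0.5 * posterior.log_variance) * noise


def _decode_cached(z, w):
    acts = [z]
    h = z
    for W, b in w["dec_hidden"]:
        h = np.maximum(h @ W + b, 0.0)
        acts.append(h)
    W, b = w["dec_out"]
    pre = h @ W + b
    return _sigmoid(pre), acts


def decode(z: np.ndarray, params: MVAEParams, view: str) -> np.ndarray:
    """Reconstruct a view from latent codes; sigmoid output in (0, 1)."""
    spec = _check_view(params, view)
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != params.latent_dim:
        raise ValueError(f"latent width {z.shape[1]} != model D {params.latent_dim}")
    if not np.isfinite(z).all():
        raise ValueError("latent codes must be finite")
    xhat, _ = _decode_cached(z, params.weights[view])
    assert xhat.shape[1] == spec.input_dim
    return xhat


def kl_to_standard_normal(posterior: GaussianPosterior) -> np.ndarray:
    """Closed-form KL(q || N(0, I)) per subject:
    (1/2) sum_d (mu_d^2 + sigma_d^2 - log sigma_d^2 - 1)."""
    var = posterior.variance
    return 0.5 * np.sum(
        posterior.mean**2 + var - posterior.log_variance - 1.0, axis=1
    )


def _bce(x, xhat):
    xc = np.clip(xhat, _EPS, 1.0 - _EPS)
    return -(x * np.log(xc) + (1.0 - x) * np.log(1.0 - xc))


def negative_elbo(views, reconstructions, fused: FusedPosterior) -> ELBOParts:
    """Negative ELBO: summed Bernoulli cross-entropy over all views and
    features plus the summed KL to the standard-normal prior.

    Reconstructions are clipped to [eps, 1-eps] before the logs; values
    outside [0, 1] are rejected.
    """
    recon = 0.0
    for x, xhat in zip(views, reconstructions, strict=True):
        x = np.asarray(x, dtype=float)
        xhat = np.asarray(xhat, dtype=float)
        if x.shape != xhat.shape:
            raise ValueError("view and reconstruction shapes differ")
        if np.any(xhat < 0.0) or np.any(xhat > 1.0):
            raise ValueError("reconstruction outside [0, 1]")
        recon += float(_bce(x, xhat).sum())
    kl = float(kl_to_standard_normal(fused).sum())
    return ELBOParts(total=recon + kl, reconstruction=recon, kl=kl)


# ---------------------------------------------------------------------------
# Loss + analytic gradients (for training)
# ---------------------------------------------------------------------------

def _zeros_like_tree(w):
    return {
        k: [(np.zeros_like(W), np.zeros_like(b)) for W, b in v] if isinstance(v, list)
        else (np.zeros_like(v[0]), np.zeros_like(v[1]))
        for k, v in w.items()
    }


def loss_and_grads(params: MVAEParams, views: dict, noise: np.ndarray):
    """Negative-ELBO value and analytic gradients for one mini-batch.

    ``views`` maps view name -> (B x P_m) scaled features; ``noise`` is a
    (B x D) standard-normal draw shared across views through the fused
    sample.  Returns (ELBOParts, grads) with ``grads`` mirroring
    ``params.weights``.
    """
    names = params.views()
    w = params.weights
    enc_cache = {}
    mus, ss, precs = {}, {}, {}
    for m in names:
        x = np.asarray(views[m], dtype=float)
        mu, s, s_raw, acts = _encode_cached(x, w[m])
        enc_cache[m] = (x, s_raw, acts)
        mus[m], ss[m] = mu, s
        precs[m] = np.exp(-s)

    prec_z = sum(precs[m] for m in names)
    v_z = 1.0 / prec_z
    mu_z = sum(mus[m] * precs[m] for m in names) * v_z
    sd_z = np.sqrt(v_z)
    z = mu_z + sd_z * noise

    recon = 0.0
    dz = np.zeros_like(z)
    grads = {m: _zeros_like_tree(w[m]) for m in names}
    for m in names:
        x = enc_cache[m][0]
        xhat, dacts = _decode_cached(z, w[m])
        recon += float(_bce(x, xhat).sum())
        delta = xhat - x  # d(sum BCE)/d(pre-sigmoid)
        W_out, _ = w[m]["dec_out"]
        grads[m]["dec_out"] = (dacts[-1].T @ delta, delta.sum(axis=0))
        back = delta @ W_out.T
        for li in range(len(w[m]["dec_hidden"]) - 1, -1, -1):
            W, _ = w[m]["dec_hidden"][li]
            back = back * (dacts[li + 1] > 0)
            grads[m]["dec_hidden"][li] = (dacts[li].T @ back, back.sum(axis=0))
            back = back @ W.T
        dz += back

    kl = float(0.5 * np.sum(mu_z**2 + v_z + np.log(prec_z) - 1.0))

    # gradients into the fused parameters
    dmu_z = dz + mu_z
    dv_z = dz * noise / (2.0 * sd_z) + 0.5 * (1.0 - prec_z)

    for m in names:
        x, s_raw, acts = enc_cache[m]
        t_m = precs[m]
        dmu_m = dmu_z * t_m * v_z
        dt_m = dmu_z * v_z * (mus[m] - mu_z) - dv_z * v_z * v_z
        ds_m = -dt_m * t_m
        ds_m = np.where(np.abs(s_raw) < _LOGVAR_CLAMP, ds_m, 0.0)

        h = acts[-1]
        W_mu, _ = w[m]["enc_mu"]
        W_s, _ = w[m]["enc_logvar"]
        grads[m]["enc_mu"] = (h.T @ dmu_m, dmu_m.sum(axis=0))
        grads[m]["enc_logvar"] = (h.T @ ds_m, ds_m.sum(axis=0))
        back = dmu_m @ W_mu.T + ds_m @ W_s.T
        for li in range(len(w[m]["enc_hidden"]) - 1, -1, -1):
            W, _ = w[m]["enc_hidden"][li]
            back = back * (acts[li + 1] > 0)
            grads[m]["enc_hidden"][li] = (acts[li].T @ back, back.sum(axis=0))
            back = back @ W.T
    parts = ELBOParts(total=recon + kl, reconstruction=recon, kl=kl)
    return parts, grads


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_params(params: MVAEParams, path):
    """Serialize weights + architecture metadata to a single npz archive."""
    arrays = {}
    for m, tree in params.weights.items():
        for key, val in tree.items():
            if isinstance(val, list):
                for i, (W, b) in enumerate(val):
                    arrays[f"{m}::{key}::{i}::W"] = W
                    arrays[f"{m}::{key}::{i}::b"] = b
            else:
                arrays[f"{m}::{key}::W"] = val[0]
                arrays[f"{m}::{key}::b"] = val[1]
    meta = {
        "latent_dim": params.latent_dim,
        "seed": params.seed,
        "view_specs": {
            m: {"input_dim": s.input_dim, "n_layers": s.n_layers, "hidden_units": s.hidden_units}
            for m, s in params.view_specs.items()
        },
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_params(path) -> MVAEParams:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        specs = {
            m: ViewSpec(name=m, **cfg) for m, cfg in meta["view_specs"].items()
        }
        weights = {}
        for m, spec in specs.items():
            tree = {}
            for key in ("enc_hidden", "dec_hidden"):
                layers = []
                i = 0
                while f"{m}::{key}::{i}::W" in npz:
                    layers.append((npz[f"{m}::{key}::{i}::W"], npz[f"{m}::{key}::{i}::b"]))
                    i += 1
                tree[key] = layers
            for key in ("enc_mu", "enc_logvar", "dec_out"):
                tree[key] = (npz[f"{m}::{key}::W"], npz[f"{m}::{key}::b"])
            weights[m] = tree
    return MVAEParams(
        view_specs=specs,
        latent_dim=meta["latent_dim"],
        seed=meta["seed"],
        weights=weights,
    )
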
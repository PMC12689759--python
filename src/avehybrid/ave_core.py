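"""Core AVE network: dual encoders, reparameterized sampling, latent fusion,
shared decoder.

The AVE (autoencoder + variational-autoencoder ensemble) couples a
deterministic encoder branch with a stochastic, KL-regularized branch.  Both
branches map an input row ``x`` of ``d`` features to a latent vector of
length ``L``; the two latents are fused (averaged by default) and a single
shared decoder reconstructs ``x`` from the fused latent.  Anomalies are the
rows the trained network reconstructs poorly.

Everything here is plain numpy.  The forward pass caches enough intermediate
state for :func:`backward_batch` to return exact analytic gradients of the
training objective with respect to every parameter array, so the trainer can
run any first-order optimizer on top.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelConfig",
    "Affine",
    "ModelParams",
    "LatentState",
    "init_params",
    "ae_encode",
    "vae_encode",
    "reparameterize",
    "fuse_latents",
    "decode",
    "forward",
    "forward_batch",
    "backward_batch",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_FORMAT",
]

CHECKPOINT_FORMAT = "ave-checkpoint-1"

_FUSION_MODES = ("averaged", "weighted", "concatenated")
_BRANCHES = ("hybrid", "ae_only", "vae_only")
_REPARAM_VARIANTS = ("paper", "std")
_OUTPUT_ACTS = ("sigmoid", "linear")


def default_latent_dim(input_dim: int) -> int:
    """Default latent width: d/4, clamped to [2, 32]."""
    return max(2, min(32, math.ceil(input_dim / 4)))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Parameters
    ----------
    input_dim : int
        Number of input features ``d``.
    hidden_dims : list of int
        Encoder hidden-layer widths; the decoder mirrors them in reverse.
    latent_dim : int
        Latent width ``L``, shared by both branches (required for averaging).
    fusion_mode : {"averaged", "weighted", "concatenated"}
        How the deterministic latent z1 and sampled latent z2 are combined.
    kl_weight : float
        Weight of the KL regularizer in the total loss (default 0.1).
    reparam_variant : {"paper", "std"}
        ``paper``: z2 = mu + e^{sigma} * eps (sigma read as log-variance but
        exponentiated whole in the sampler); ``std``: z2 = mu + e^{sigma/2} * eps,
        the conventional reparameterization.
    branch : {"hybrid", "ae_only", "vae_only"}
        Ablation switch; non-hybrid branches drop the other encoder entirely.
    """

    input_dim: int
    hidden_dims: tuple[int, ...] = (64, 32)
    latent_dim: int | None = None
    activation: str = "relu"
    output_activation: str = "sigmoid"
    fusion_mode: str = "averaged"
    kl_weight: float = 0.1
    reparam_variant: str = "paper"
    l2_lambda: float = 0.001
    seed: int = 0
    branch: str = "hybrid"
    allow_large_latent: bool = False

    def __post_init__(self):
        if self.input_dim < 1:
            raise ValueError(f"input_dim must be positive, got {self.input_dim}")
        object.__setattr__(self, "hidden_dims", tuple(int(h) for h in self.hidden_dims))
        if any(h < 1 for h in self.hidden_dims):
            raise ValueError(f"hidden_dims must be positive, got {self.hidden_dims}")
        if self.latent_dim is None:
            object.__setattr__(self, "latent_dim", default_latent_dim(self.input_dim))
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.latent_dim > self.input_dim and not self.allow_large_latent:
            raise ValueError(
                f"latent_dim {self.latent_dim} exceeds input_dim {self.input_dim}; "
                "pass allow_large_latent=True to override"
            )
        if self.activation != "relu":
            raise ValueError("only relu hidden activation is supported")
        if self.output_activation not in _OUTPUT_ACTS:
            raise ValueError(f"output_activation must be one of {_OUTPUT_ACTS}")
        if self.fusion_mode not in _FUSION_MODES:
            raise ValueError(f"fusion_mode must be one of {_FUSION_MODES}")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be nonnegative")
        if self.reparam_variant not in _REPARAM_VARIANTS:
            raise ValueError(f"reparam_variant must be one of {_REPARAM_VARIANTS}")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be nonnegative")
        if self.branch not in _BRANCHES:
            raise ValueError(f"branch must be one of {_BRANCHES}")

    @property
    def fused_dim(self) -> int:
        """Decoder input width: 2L only for hybrid concatenated fusion."""
        if self.branch == "hybrid" and self.fusion_mode == "concatenated":
            return 2 * self.latent_dim
        return self.latent_dim

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Affine:
    """One affine map y = x W^T + b with W of shape (out, in)."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.ndim != 1 or self.W.shape[0] != self.b.shape[0]:
            raise ValueError(
                f"inconsistent affine shapes: W {self.W.shape}, b {self.b.shape}"
            )


@dataclass
class ModelParams:
    """Trained weight/bias collections for both encoders and the shared decoder.

    Branch-specific stacks are ``None`` when the configured ablation drops
    them (``ae_only`` has no VAE stack and vice versa).
    """

    decoder: list[Affine]
    ae_encoder: list[Affine] | None = None
    vae_trunk: list[Affine] | None = None
    vae_mu_head: Affine | None = None
    vae_logvar_head: Affine | None = None
    fusion_weight_logit: np.ndarray = field(default_factory=lambda: np.zeros(()))

    def __post_init__(self):
        self.fusion_weight_logit = np.asarray(self.fusion_weight_logit, dtype=float)
        if (self.vae_mu_head is None) != (self.vae_logvar_head is None):
            raise ValueError("mu and logvar heads must both be present or both absent")
        if self.vae_mu_head is not None:
            if self.vae_mu_head.W.shape != self.vae_logvar_head.W.shape:
                raise ValueError(
                    "mu/logvar heads differ in width: "
                    f"{self.vae_mu_head.W.shape} vs {self.vae_logvar_head.W.shape}"
                )

    def named_arrays(self):
        """Yield (name, array) for every parameter array, in a fixed order."""
        if self.ae_encoder is not None:
            for i, lay in enumerate(self.ae_encoder):
                yield f"ae_encoder.{i}.W", lay.W
                yield f"ae_encoder.{i}.b", lay.b
        if self.vae_trunk is not None:
            for i, lay in enumerate(self.vae_trunk):
                yield f"vae_trunk.{i}.W", lay.W
                yield f"vae_trunk.{i}.b", lay.b
        if self.vae_mu_head is not None:
            yield "vae_mu_head.W", self.vae_mu_head.W
            yield "vae_mu_head.b", self.vae_mu_head.b
            yield "vae_logvar_head.W", self.vae_logvar_head.W
            yield "vae_logvar_head.b", self.vae_logvar_head.b
        for i, lay in enumerate(self.decoder):
            yield f"decoder.{i}.W", lay.W
            yield f"decoder.{i}.b", lay.b
        yield "fusion_weight_logit", self.fusion_weight_logit

    def get_array(self, name: str) -> np.ndarray:
        for n, a in self.named_arrays():
            if n == name:
                return a
        raise KeyError(name)

    def set_array(self, name: str, value: np.ndarray) -> None:
        parts = name.split(".")
        if parts[0] == "fusion_weight_logit":
            self.fusion_weight_logit = np.asarray(value, dtype=float)
            return
        obj = getattr(self, parts[0])
        if parts[0] in ("vae_mu_head", "vae_logvar_head"):
            setattr(obj, parts[1], np.asarray(value, dtype=float))
        else:
            setattr(obj[int(parts[1])], parts[2], np.asarray(value, dtype=float))

    def copy(self) -> "ModelParams":
        def cl(stack):
            if stack is None:
                return None
            return [Affine(l.W.copy(), l.b.copy()) for l in stack]

        def cl1(lay):
            return None if lay is None else Affine(lay.W.copy(), lay.b.copy())

        return ModelParams(
            decoder=cl(self.decoder),
            ae_encoder=cl(self.ae_encoder),
            vae_trunk=cl(self.vae_trunk),
            vae_mu_head=cl1(self.vae_mu_head),
            vae_logvar_head=cl1(self.vae_logvar_head),
            fusion_weight_logit=self.fusion_weight_logit.copy(),
        )

    def weight_matrices(self):
        """All weight matrices (biases and the fusion logit excluded)."""
        for name, arr in self.named_arrays():
            if name.endswith(".W"):
                yield name, arr


@dataclass
class LatentState:
    """Per-batch latent bookkeeping from a forward pass (rows = samples)."""

    z1: np.ndarray | None
    mu_x: np.ndarray | None
    sigma_x: np.ndarray | None  # log-variance
    epsilon: np.ndarray | None
    z2: np.ndarray | None
    z_fused: np.ndarray


# ---------------------------------------------------------------------------
# initialization


def _glorot(rng: np.random.Generator, n_out: int, n_in: int) -> Affine:
    limit = math.sqrt(6.0 / (n_in + n_out))
    return Affine(rng.uniform(-limit, limit, size=(n_out, n_in)), np.zeros(n_out))


def init_params(config: ModelConfig, seed: int | None = None) -> ModelParams:
    """Glorot-uniform weights, zero biases, seeded by ``config.seed``.

    Parameter stacks are drawn in a fixed order (AE encoder, VAE trunk, mu
    head, logvar head, decoder) so equal seeds give identical networks.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    d, L = config.input_dim, config.latent_dim
    hid = list(config.hidden_dims)

    ae = None
    if config.branch != "vae_only":
        dims = [d] + hid + [L]
        ae = [_glorot(rng, dims[i + 1], dims[i]) for i in range(len(dims) - 1)]

    trunk = mu_head = logvar_head = None
    if config.branch != "ae_only":
        dims = [d] + hid
        trunk = [_glorot(rng, dims[i + 1], dims[i]) for i in range(len(dims) - 1)]
        mu_head = _glorot(rng, L, dims[-1])
        logvar_head = _glorot(rng, L, dims[-1])

    dims = [config.fused_dim] + hid[::-1] + [d]
    dec = [_glorot(rng, dims[i + 1], dims[i]) for i in range(len(dims) - 1)]

    return ModelParams(
        decoder=dec,
        ae_encoder=ae,
        vae_trunk=trunk,
        vae_mu_head=mu_head,
        vae_logvar_head=logvar_head,
        fusion_weight_logit=np.zeros(()),
    )


# ---------------------------------------------------------------------------
# forward primitives


def _relu(a):
    return np.maximum(a, 0.0)


def _sigmoid(a):
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def _apply_act(a, act):
    if act == "relu":
        return _relu(a)
    if act == "sigmoid":
        return _sigmoid(a)
    if act == "linear":
        return a
    raise ValueError(f"unknown activation {act!r}")


def _as_batch(x, d, what):
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != d:
        raise ValueError(f"{what}: expected width {d}, got shape {x.shape}")
    return x, squeeze


def _stack_forward(h, layers, final_act, hidden_act="relu"):
    cache = []
    for i, lay in enumerate(layers):
        if h.shape[1] != lay.W.shape[1]:
            raise ValueError(
                f"layer {i}: expected input width {lay.W.shape[1]}, got {h.shape[1]}"
            )
        a = h @ lay.W.T + lay.b
        act = final_act if i == len(layers) - 1 else hidden_act
        cache.append((h, a, act))
        h = _apply_act(a, act)
    return h, cache


def _stack_backward(dout, cache, layers, grads, prefix):
    for i in reversed(range(len(layers))):
        h_in, a, act = cache[i]
        if act == "relu":
            da = dout * (a > 0)
        elif act == "sigmoid":
            s = _sigmoid(a)
            da = dout * s * (1.0 - s)
        else:  # linear
            da = dout
        grads[f"{prefix}.{i}.W"] = grads.get(f"{prefix}.{i}.W", 0.0) + da.T @ cache[i][0]
        grads[f"{prefix}.{i}.b"] = grads.get(f"{prefix}.{i}.b", 0.0) + da.sum(axis=0)
        dout = da @ layers[i].W
    return dout


# ---------------------------------------------------------------------------
# public single-op surface


def ae_encode(x, params: ModelParams, config: ModelConfig | None = None):
    """Deterministic branch: x -> z1 through affine + ReLU layers."""
    if params.ae_encoder is None:
        raise ValueError("this model has no AE encoder branch")
    x, squeeze = _as_batch(x, params.ae_encoder[0].W.shape[1], "ae_encode")
    z1, _ = _stack_forward(x, params.ae_encoder, final_act="relu")
    return z1[0] if squeeze else z1


def vae_encode(x, params: ModelParams, config: ModelConfig | None = None):
    """Stochastic branch heads: x -> (mu, log-variance); no sampling here."""
    if params.vae_mu_head is None:
        raise ValueError("this model has no VAE encoder branch")
    in_dim = (
        params.vae_trunk[0].W.shape[1] if params.vae_trunk else params.vae_mu_head.W.shape[1]
    )
    x, squeeze = _as_batch(x, in_dim, "vae_encode")
    t, _ = _stack_forward(x, params.vae_trunk, final_act="relu") if params.vae_trunk else (x, [])
    mu = t @ params.vae_mu_head.W.T + params.vae_mu_head.b
    lv = t @ params.vae_logvar_head.W.T + params.vae_logvar_head.b
    return (mu[0], lv[0]) if squeeze else (mu, lv)


def reparameterize(mu_x, sigma_x, epsilon, variant: str = "paper"):
    """Sample z2 = mu + e^{sigma} * eps (``paper``) or mu + e^{sigma/2} * eps (``std``)."""
    mu_x = np.asarray(mu_x, dtype=float)
    sigma_x = np.asarray(sigma_x, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    if mu_x.shape != sigma_x.shape or mu_x.shape != epsilon.shape:
        raise ValueError(
            f"shape mismatch: mu {mu_x.shape}, sigma {sigma_x.shape}, eps {epsilon.shape}"
        )
    if variant == "paper":
        return mu_x + np.exp(sigma_x) * epsilon
    if variant == "std":
        return mu_x + np.exp(0.5 * sigma_x) * epsilon
    raise ValueError(f"unknown reparam variant {variant!r}")


def fuse_latents(z1, z2, mode: str = "averaged", fusion_weight: float = 0.5):
    """Combine the two branch latents.

    averaged: (z1+z2)/2; weighted: a*z1 + (1-a)*z2; concatenated: [z1 || z2].
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError(f"latent shape mismatch: {z1.shape} vs {z2.shape}")
    if mode == "averaged":
        return 0.5 * (z1 + z2)
    if mode == "weighted":
        a = float(fusion_weight)
        if not 0.0 < a < 1.0:
            raise ValueError(f"fusion weight must lie in (0,1), got {a}")
        return a * z1 + (1.0 - a) * z2
    if mode == "concatenated":
        return np.concatenate([z1, z2], axis=-1)
    raise ValueError(f"unknown fusion mode {mode!r}")


def decode(z_fused, params: ModelParams, config: ModelConfig):
    """Shared decoder: fused latent -> reconstruction x_hat."""
    z, squeeze = _as_batch(z_fused, params.decoder[0].W.shape[1], "decode")
    xh, _ = _stack_forward(z, params.decoder, final_act=config.output_activation)
    return xh[0] if squeeze else xh


def forward_batch(X, params: ModelParams, config: ModelConfig, epsilon=None):
    """Full forward pass with cache for backprop.

    ``epsilon`` is ``None`` (zero noise, deterministic), an (n, L) array, or a
    numpy Generator to draw a standard-normal batch from.

    Returns (x_hat, LatentState, cache).
    """
    X, _ = _as_batch(X, config.input_dim, "forward")
    n, L = X.shape[0], config.latent_dim
    cache: dict = {}

    z1 = None
    if config.branch != "vae_only":
        z1, cache["ae"] = _stack_forward(X, params.ae_encoder, final_act="relu")

    mu = lv = eps = z2 = None
    if config.branch != "ae_only":
        if params.vae_trunk:
            t, cache["trunk"] = _stack_forward(X, params.vae_trunk, final_act="relu")
        else:
            t, cache["trunk"] = X, []
        cache["t"] = t
        mu = t @ params.vae_mu_head.W.T + params.vae_mu_head.b
        lv = t @ params.vae_logvar_head.W.T + params.vae_logvar_head.b
        if epsilon is None:
            eps = np.zeros((n, L))
        elif isinstance(epsilon, np.random.Generator):
            eps = epsilon.standard_normal((n, L))
        else:
            eps = np.asarray(epsilon, dtype=float)
            if eps.shape != (n, L):
                raise ValueError(f"epsilon shape {eps.shape} != {(n, L)}")
        z2 = reparameterize(mu, lv, eps, config.reparam_variant)

    if config.branch == "ae_only":
        zf = z1
    elif config.branch == "vae_only":
        zf = z2
    else:
        alpha = float(_sigmoid(params.fusion_weight_logit))
        cache["alpha"] = alpha
        zf = fuse_latents(z1, z2, config.fusion_mode, alpha)

    if zf.shape[1] != params.decoder[0].W.shape[1]:
        raise ValueError(
            f"fused latent width {zf.shape[1]} does not match decoder input "
            f"width {params.decoder[0].W.shape[1]}"
        )
    xh, cache["dec"] = _stack_forward(zf, params.decoder, final_act=config.output_activation)
    cache.update(X=X, z1=z1, mu=mu, lv=lv, eps=eps, z2=z2, zf=zf, xh=xh)
    latents = LatentState(z1=z1, mu_x=mu, sigma_x=lv, epsilon=eps, z2=z2, z_fused=zf)
    return xh, latents, cache


def forward(x_batch, params: ModelParams, config: ModelConfig, epsilon_source=None):
    """Forward pass returning (x_hat_batch, LatentState)."""
    xh, latents, _ = forward_batch(x_batch, params, config, epsilon_source)
    return xh, latents


def backward_batch(cache, params: ModelParams, config: ModelConfig, kl_weight: float):
    """Analytic gradients of mse_loss + kl_weight * kl_loss w.r.t. all params.

    ``cache`` is the third output of :func:`forward_batch`.  The l2 penalty is
    not included here; the trainer adds ``2*l2*W`` per weight matrix.
    """
    X, xh = cache["X"], cache["xh"]
    n, d = X.shape
    L = config.latent_dim
    grads: dict[str, np.ndarray] = {}

    dxh = 2.0 * (xh - X) / (n * d)
    dzf = _stack_backward(dxh, cache["dec"], params.decoder, grads, "decoder")

    dz1 = dz2 = None
    if config.branch == "ae_only":
        dz1 = dzf
    elif config.branch == "vae_only":
        dz2 = dzf
    elif config.fusion_mode == "averaged":
        dz1 = 0.5 * dzf
        dz2 = 0.5 * dzf
    elif config.fusion_mode == "weighted":
        a = cache["alpha"]
        dz1 = a * dzf
        dz2 = (1.0 - a) * dzf
        dalpha = float(np.sum(dzf * (cache["z1"] - cache["z2"])))
        grads["fusion_weight_logit"] = np.asarray(dalpha * a * (1.0 - a))
    else:  # concatenated
        dz1 = dzf[:, :L]
        dz2 = dzf[:, L:]
    grads.setdefault("fusion_weight_logit", np.zeros(()))

    if dz1 is not None and config.branch != "vae_only":
        _stack_backward(dz1, cache["ae"], params.ae_encoder, grads, "ae_encoder")

    if dz2 is not None and config.branch != "ae_only":
        mu, lv, eps = cache["mu"], cache["lv"], cache["eps"]
        s = 1.0 if config.reparam_variant == "paper" else 0.5
        dmu = dz2.copy()
        dlv = dz2 * eps * s * np.exp(s * lv)
        if kl_weight != 0.0:
            # KL = -0.5 * mean(lv - mu^2 - e^lv + 1) over n*L entries
            dmu += kl_weight * mu / (n * L)
            dlv += kl_weight * (-0.5) * (1.0 - np.exp(lv)) / (n * L)
        t = cache["t"]
        grads["vae_mu_head.W"] = dmu.T @ t
        grads["vae_mu_head.b"] = dmu.sum(axis=0)
        grads["vae_logvar_head.W"] = dlv.T @ t
        grads["vae_logvar_head.b"] = dlv.sum(axis=0)
        dt = dmu @ params.vae_mu_head.W + dlv @ params.vae_logvar_head.W
        if params.vae_trunk:
            _stack_backward(dt, cache["trunk"], params.vae_trunk, grads, "vae_trunk")

    return grads


# ---------------------------------------------------------------------------
# checkpoint I/O (JSON: text-only, byte-stable for equal inputs)


def save_checkpoint(params: ModelParams, config: ModelConfig, path) -> None:
    def stack(s):
        return None if s is None else [{"W": l.W.tolist(), "b": l.b.tolist()} for l in s]

    def one(l):
        return None if l is None else {"W": l.W.tolist(), "b": l.b.tolist()}

    doc = {
        "format_version": CHECKPOINT_FORMAT,
        "config": dataclasses.asdict(config),
        "params": {
            "ae_encoder": stack(params.ae_encoder),
            "vae_trunk": stack(params.vae_trunk),
            "vae_mu_head": one(params.vae_mu_head),
            "vae_logvar_head": one(params.vae_logvar_head),
            "decoder": stack(params.decoder),
            "fusion_weight_logit": float(params.fusion_weight_logit),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig]:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != CHECKPOINT_FORMAT:
        raise ValueError(
            f"checkpoint format {version!r} not supported (expected {CHECKPOINT_FORMAT!r})"
        )
    cfg = doc["config"]
    cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
    config = ModelConfig(**cfg)
    p = doc["params"]

    def stack(s):
        return None if s is None else [Affine(np.array(l["W"]), np.array(l["b"])) for l in s]

    def one(l):
        return None if l is None else Affine(np.array(l["W"]), np.array(l["b"]))

    params = ModelParams(
        decoder=stack(p["decoder"]),
        ae_encoder=stack(p["ae_encoder"]),
        vae_trunk=stack(p["vae_trunk"]),
        vae_mu_head=one(p["vae_mu_head"]),
        vae_logvar_head=one(p["vae_logvar_head"]),
        fusion_weight_logit=np.asarray(p["fusion_weight_logit"]),
    )
    return params, config
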
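"""Traditional and conditional GAN phase-space generators.

The generator maps a 6-D standard-normal latent vector (for the
conditional model, concatenated with a learned 4-D embedding of the tube
potential label) through three hidden layers of configurable width —
ReLU, ReLU, sigmoid — and a final affine head to the six normalized
particle parameters (x, y, dx, dy, dz, e).  The discriminator mirrors
the hidden stack with ReLU activations and a scalar output; spectral
normalization of its weight matrices is optional.

Two adversarial objectives are supported:

* ``non_saturated_r1`` — softplus-form non-saturating losses with the R1
  gradient penalty (gamma/2) * E[ ||grad_x D(x)||^2 ] on real samples;
* ``wasserstein`` — critic difference of means, with a gradient penalty
  on latent-mixed samples when spectral normalization is off (the critic
  is penalty-free when spectral normalization enforces the Lipschitz
  bound).

Training uses RMSProp at a 1:1 discriminator/generator update ratio,
optionally tracking an exponential moving average (EMA) of the generator
weights, and logs the validation histogram loss once per epoch.  All
randomness flows from one seed through named substreams (init /
shuffling / latent / validation), so identical configurations reproduce
identical weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import evaluation
from .autodiff import (
    Var, grad, vadd, vdiv, vmatmul, vmean, vmul, vneg, vrelu, vsigmoid,
    vsoftplus, vsqrt, vsquare, vsub, vsum,
)
from .phasespace import (
    NormalizationSpec, ParticleBatch, PhaseSpace, denormalize_batch, normalize_batch,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainConfig",
    "TrainedGenerator",
    "ModelQualityError",
    "compute_losses",
    "train_gan",
    "sample_particles",
    "interpolate_energies",
    "spectral_norm_audit",
]

LOSS_MODES = ("wasserstein", "non_saturated_r1")


class ModelQualityError(RuntimeError):
    """Sampling rejection rate too high: the generator is unusable."""


@dataclass
class GeneratorSpec:
    latent_dim: int = 6
    embed_dim: int = 4
    hidden: tuple[int, ...] = (400, 400, 400)
    output_dim: int = 6
    labels: tuple[int, ...] | None = None  # None -> traditional (unconditional)

    def __post_init__(self):
        self.hidden = tuple(int(h) for h in self.hidden)
        if len(self.hidden) != 3 or any(h < 1 for h in self.hidden):
            raise ValueError("generator uses three positive hidden widths")
        if self.latent_dim < 1 or self.output_dim < 1:
            raise ValueError("dimensions must be positive")
        if self.labels is not None:
            self.labels = tuple(int(v) for v in self.labels)

    @property
    def conditional(self) -> bool:
        return self.labels is not None

    @property
    def input_dim(self) -> int:
        return self.latent_dim + (self.embed_dim if self.conditional else 0)


@dataclass
class DiscriminatorSpec:
    hidden: tuple[int, ...] = (400, 400, 400)
    spectral_norm: bool = False
    embed_dim: int = 4

    def __post_init__(self):
        self.hidden = tuple(int(h) for h in self.hidden)
        if len(self.hidden) != 3 or any(h < 1 for h in self.hidden):
            raise ValueError("discriminator uses three positive hidden widths")


@dataclass
class TrainConfig:
    loss: str = "non_saturated_r1"
    r1_gamma: float = 10.0
    gp_lambda: float = 10.0
    lr: float = 2e-5
    batch_size: int = 10_000
    epochs: int = 20
    ema: bool = True
    ema_decay: float = 0.999
    #: discriminator updates per generator update
    d_steps: int = 1
    seed: int = 0
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8
    #: particles per label used for the per-epoch validation histogram loss
    val_particles: int | None = None
    val_bins: int = 100
    #: when validation data is given, keep the weights of the epoch with
    #: the lowest validation histogram loss instead of the last epoch
    keep_best: bool = False

    def __post_init__(self):
        if self.loss not in LOSS_MODES:
            raise ValueError(f"loss must be one of {LOSS_MODES}")
        if self.lr <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("lr, batch size and epochs must be positive")
        if self.r1_gamma < 0:
            raise ValueError("r1_gamma must be nonnegative")
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("ema_decay must be in [0, 1)")


# ---------------------------------------------------------------------------
# parameter initialisation and forward passes
# ---------------------------------------------------------------------------

def _init_mlp(prefix, sizes, rng, params):
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        scale = np.sqrt(2.0 / fan_in)
        params[f"{prefix}.W{i}"] = rng.standard_normal((fan_in, fan_out)) * scale
        params[f"{prefix}.b{i}"] = np.zeros(fan_out)


def init_params(
    gspec: GeneratorSpec, dspec: DiscriminatorSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    _init_mlp("g", (gspec.input_dim, *gspec.hidden, gspec.output_dim), rng, params)
    # start generated samples concentrated around the middle of the unit
    # box so that early models are valid (all parameters inside range)
    params["g.W3"] *= 0.3
    params["g.b3"] = np.full(gspec.output_dim, 0.5)
    d_in = gspec.output_dim + (dspec.embed_dim if gspec.conditional else 0)
    _init_mlp("d", (d_in, *dspec.hidden, 1), rng, params)
    if gspec.conditional:
        n_lab = len(gspec.labels)
        params["g.embed"] = rng.standard_normal((n_lab, gspec.embed_dim))
        params["d.embed"] = rng.standard_normal((n_lab, dspec.embed_dim))
    return params


def _g_forward_np(params, z, label_idx, conditional, split=False):
    x = z
    if conditional:
        x = np.concatenate([z, params["g.embed"][label_idx]], axis=1)
    h1 = np.maximum(x @ params["g.W0"] + params["g.b0"], 0.0)
    if split:
        return h1
    return _g_rest_np(params, h1)


def _g_rest_np(params, h1):
    h2 = np.maximum(h1 @ params["g.W1"] + params["g.b1"], 0.0)
    a3 = h2 @ params["g.W2"] + params["g.b2"]
    h3 = 1.0 / (1.0 + np.exp(-np.clip(a3, -60, 60)))
    return h3 @ params["g.W3"] + params["g.b3"]


def _g_forward_var(pvars, z_const, embed_rows, conditional):
    """Generator forward with Var parameters; z is a constant input."""
    if conditional:
        x = Var(z_const)
        # per-sample embedding rows: gather is realised as one-hot matmul so
        # gradients flow back into the embedding table
        onehot, table = embed_rows
        emb = vmatmul(Var(onehot), table)
        x = _vconcat(x, emb)
    else:
        x = Var(z_const)
    h1 = vrelu(vadd(vmatmul(x, pvars["g.W0"]), pvars["g.b0"]))
    h2 = vrelu(vadd(vmatmul(h1, pvars["g.W1"]), pvars["g.b1"]))
    h3 = vsigmoid(vadd(vmatmul(h2, pvars["g.W2"]), pvars["g.b2"]))
    return vadd(vmatmul(h3, pvars["g.W3"]), pvars["g.b3"])


def _vconcat(a: Var, b: Var) -> Var:
    """Concatenate along axis 1 via padded matmuls (keeps the graph simple)."""
    na, nb = a.shape[1], b.shape[1]
    pa = np.zeros((na, na + nb))
    pa[np.arange(na), np.arange(na)] = 1.0
    pb = np.zeros((nb, na + nb))
    pb[np.arange(nb), na + np.arange(nb)] = 1.0
    return vadd(vmatmul(a, Var(pa)), vmatmul(b, Var(pb)))


def _d_forward_var(weights, x: Var) -> Var:
    """Discriminator forward on a Var input; weights may be Var or ndarray."""
    h = x
    for i in range(3):
        h = vrelu(vadd(vmatmul(h, weights[f"d.W{i}"]), weights[f"d.b{i}"]))
    return vadd(vmatmul(h, weights["d.W3"]), weights["d.b3"])


# ---------------------------------------------------------------------------
# spectral normalization
# ---------------------------------------------------------------------------

def _power_iteration(W: np.ndarray, u: np.ndarray, n_iter: int = 1):
    for _ in range(n_iter):
        v = W.T @ u
        v /= np.linalg.norm(v) + 1e-12
        u = W @ v
        u /= np.linalg.norm(u) + 1e-12
    sigma = float(u @ W @ v)
    return u, v, sigma


def _sn_weight(W_var: Var, u: np.ndarray, v: np.ndarray) -> Var:
    """W / sigma with sigma = u^T W v; u, v treated as constants so the
    gradient flows through both the numerator and sigma."""
    Wv = vmatmul(W_var, Var(v[:, None]))
    sigma = vsum(vmul(Var(u[:, None]), Wv))
    return vdiv(W_var, sigma)


def spectral_norm_audit(weights: dict[str, np.ndarray], sn_state) -> list[float]:
    """Largest singular value of each effective discriminator matrix."""
    out = []
    for i in range(4):
        W = weights[f"d.W{i}"]
        if sn_state is not None:
            u = sn_state[f"d.W{i}"]
            _, _, sigma = _power_iteration(W, u, n_iter=1)
            W = W / sigma
        out.append(float(np.linalg.svd(W, compute_uv=False)[0]))
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def compute_losses(
    d_out_real: Var,
    d_out_fake: Var,
    mode: str,
    r1_gamma: float = 10.0,
    real_batch: Var | None = None,
    *,
    gp_lambda: float = 0.0,
    d_fn=None,
    fake_batch: Var | None = None,
    mix_eps: np.ndarray | None = None,
) -> tuple[Var, Var]:
    """Discriminator and generator losses as differentiable scalars.

    ``non_saturated_r1``: d_loss = E[softplus(-D(real))] + E[softplus(D(fake))]
    plus (gamma/2) * E[||grad_x D(x)||^2] over real samples (``real_batch``
    must be the Var the real outputs were computed from); g_loss =
    E[softplus(-D(fake))].

    ``wasserstein``: d_loss = E[D(fake)] - E[D(real)], plus a gradient
    penalty gp_lambda * E[(||grad D(x_hat)|| - 1)^2] on mixed samples when
    ``d_fn``/``fake_batch``/``mix_eps`` are supplied (omitted when spectral
    normalization already bounds the critic); g_loss = -E[D(fake)].
    """
    if mode not in LOSS_MODES:
        raise ValueError(f"unknown loss mode {mode!r}")
    if r1_gamma < 0:
        raise ValueError("r1_gamma must be nonnegative")

    if mode == "non_saturated_r1":
        d_loss = vadd(
            vmean(vsoftplus(vneg(d_out_real))), vmean(vsoftplus(d_out_fake))
        )
        if r1_gamma > 0 and real_batch is not None:
            gx = grad(vsum(d_out_real), [real_batch])[0]
            r1 = vmul(0.5 * r1_gamma, vmean(vsum(vsquare(gx), axis=1)))
            d_loss = vadd(d_loss, r1)
        g_loss = vmean(vsoftplus(vneg(d_out_fake)))
        return d_loss, g_loss

    d_loss = vsub(vmean(d_out_fake), vmean(d_out_real))
    if gp_lambda > 0 and d_fn is not None and fake_batch is not None:
        if mix_eps is None:
            raise ValueError("wasserstein gradient penalty needs mix_eps")
        x_hat = Var(
            mix_eps * real_batch.value + (1.0 - mix_eps) * fake_batch.value
        )
        gx = grad(vsum(d_fn(x_hat)), [x_hat])[0]
        gnorm = vsqrt(vadd(vsum(vsquare(gx), axis=1), 1e-12))
        gp = vmul(gp_lambda, vmean(vsquare(vsub(gnorm, 1.0))))
        d_loss = vadd(d_loss, gp)
    g_loss = vneg(vmean(d_out_fake))
    return d_loss, g_loss


# ---------------------------------------------------------------------------
# trained model container
# ---------------------------------------------------------------------------

@dataclass
class TrainedGenerator:
    """Generator weights + EMA shadow + normalization + label vocabulary."""

    gspec: GeneratorSpec
    dspec: DiscriminatorSpec
    params: dict[str, np.ndarray]
    ema_params: dict[str, np.ndarray]
    norm: NormalizationSpec
    kvp: int | None = None  # traditional models carry their single potential
    train_log: list[dict] = field(default_factory=list)
    sn_state: dict[str, np.ndarray] | None = None

    @property
    def labels(self) -> tuple[int, ...] | None:
        return self.gspec.labels

    def _label_index(self, label) -> int:
        if not self.gspec.conditional:
            raise ValueError("traditional generator takes no label")
        try:
            return self.gspec.labels.index(int(label))
        except ValueError:
            raise KeyError(
                f"label {label} not in vocabulary {self.gspec.labels}"
            ) from None

    def _weights(self, use_ema: bool) -> dict[str, np.ndarray]:
        return self.ema_params if use_ema else self.params

    def forward(self, z: np.ndarray, label=None, use_ema: bool = True) -> np.ndarray:
        """Normalized 6-parameter output for latent batch z of shape (n, 6)."""
        z = np.asarray(z, float)
        if z.ndim != 2 or z.shape[1] != self.gspec.latent_dim:
            raise ValueError(f"z must have shape (n, {self.gspec.latent_dim})")
        w = self._weights(use_ema)
        if self.gspec.conditional:
            if label is None:
                raise ValueError("conditional generator requires a label")
            idx = np.full(z.shape[0], self._label_index(label))
            return _g_forward_np(w, z, idx, True)
        if label is not None:
            raise ValueError("traditional generator takes no label")
        return _g_forward_np(w, z, None, False)

    def first_layer(self, z: np.ndarray, label=None, use_ema: bool = True,
                    embedding: np.ndarray | None = None) -> np.ndarray:
        """First-hidden-layer activations G1(z, E(y)) (splittable forward)."""
        z = np.asarray(z, float)
        w = self._weights(use_ema)
        if self.gspec.conditional:
            if embedding is None:
                embedding = w["g.embed"][self._label_index(label)]
            x = np.concatenate(
                [z, np.broadcast_to(embedding, (z.shape[0], self.gspec.embed_dim))],
                axis=1,
            )
        else:
            x = z
        return np.maximum(x @ w["g.W0"] + w["g.b0"], 0.0)

    def rest(self, h1: np.ndarray, use_ema: bool = True) -> np.ndarray:
        """Remaining layers G2-3; rest(first_layer(z, y)) == forward(z, y)."""
        return _g_rest_np(self._weights(use_ema), h1)

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "gspec": asdict(self.gspec),
            "dspec": asdict(self.dspec),
            "kvp": self.kvp,
            "train_log": self.train_log,
            "format_version": 1,
        }
        arrays = {f"p__{k}": v for k, v in self.params.items()}
        arrays.update({f"e__{k}": v for k, v in self.ema_params.items()})
        if self.sn_state:
            arrays.update({f"s__{k}": v for k, v in self.sn_state.items()})
        arrays["norm_lo"] = self.norm.lo
        arrays["norm_hi"] = self.norm.hi
        arrays["meta_json"] = np.array(json.dumps(meta))
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedGenerator":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta_json"]))
            gmeta = dict(meta["gspec"])
            if gmeta.get("labels") is not None:
                gmeta["labels"] = tuple(gmeta["labels"])
            gmeta["hidden"] = tuple(gmeta["hidden"])
            dmeta = dict(meta["dspec"])
            dmeta["hidden"] = tuple(dmeta["hidden"])
            params = {
                k[3:]: data[k] for k in data.files if k.startswith("p__")
            }
            ema = {k[3:]: data[k] for k in data.files if k.startswith("e__")}
            sn = {k[3:]: data[k] for k in data.files if k.startswith("s__")}
            return cls(
                gspec=GeneratorSpec(**gmeta),
                dspec=DiscriminatorSpec(**dmeta),
                params=params,
                ema_params=ema,
                norm=NormalizationSpec(data["norm_lo"], data["norm_hi"]),
                kvp=meta["kvp"],
                train_log=meta["train_log"],
                sn_state=sn or None,
            )


def generator_forward(g: TrainedGenerator, z, label=None, use_ema=True):
    """Functional alias of :meth:`TrainedGenerator.forward`."""
    return g.forward(z, label=label, use_ema=use_ema)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _rmsprop_update(params, grads, cache, lr, alpha, eps):
    for k, g in grads.items():
        c = cache.get(k)
        if c is None:
            c = np.zeros_like(g)
            cache[k] = c
        c *= alpha
        c += (1 - alpha) * g * g
        params[k] -= lr * g / (np.sqrt(c) + eps)


def _d_weight_vars(params, dspec, sn_state, update_sn: bool):
    """Var wrappers of D weights, spectrally normalized if configured.

    Returns (weights-for-forward, raw trainable Vars).
    """
    raw = {}
    eff = {}
    for i in range(4):
        for kind in ("W", "b"):
            k = f"d.{kind}{i}"
            raw[k] = Var(params[k])
            eff[k] = raw[k]
        if dspec.spectral_norm:
            k = f"d.W{i}"
            u = sn_state[k]
            if update_sn:
                u, v, _ = _power_iteration(params[k], u)
                sn_state[k] = u
            else:
                v = params[k].T @ u
                v /= np.linalg.norm(v) + 1e-12
            eff[k] = _sn_weight(raw[k], u, v)
    if "d.embed" in params:
        raw["d.embed"] = Var(params["d.embed"])
    return eff, raw


def _d_input(x: Var, onehot: np.ndarray | None, embed_var: Var | None) -> Var:
    if onehot is None:
        return x
    emb = vmatmul(Var(onehot), embed_var)
    return _vconcat(x, emb)


def train_gan(
    data: dict[int, PhaseSpace] | PhaseSpace,
    gspec: GeneratorSpec | None = None,
    dspec: DiscriminatorSpec | None = None,
    tcfg: TrainConfig | None = None,
    val_data: dict[int, PhaseSpace] | PhaseSpace | None = None,
) -> TrainedGenerator:
    """Adversarial training on (already split) training phase spaces.

    ``data`` maps tube-potential labels to training phase spaces for the
    conditional model, or is a single phase space for the traditional
    model.  ``val_data``, when given with the same structure, is used for
    the per-epoch validation histogram-loss log.
    """
    tcfg = tcfg or TrainConfig()
    dspec = dspec or DiscriminatorSpec()

    if isinstance(data, PhaseSpace):
        labels = None
        data_map = {int(data.kvp_label): data}
    else:
        data_map = {int(k): v for k, v in data.items()}
        labels = tuple(sorted(data_map))
    if gspec is None:
        gspec = GeneratorSpec(labels=labels)
    elif gspec.conditional != (labels is not None):
        raise ValueError("generator spec conditionality does not match the data")

    for kvp, ps in data_map.items():
        if ps.n < 2 * tcfg.batch_size and ps.n < 2:
            raise ValueError(f"label {kvp}: too little training data")

    # one seed, named substreams
    ss = np.random.SeedSequence(tcfg.seed)
    init_rng, shuffle_rng, latent_rng, val_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    all_cols = np.concatenate([ps.batch.columns() for ps in data_map.values()])
    norm = NormalizationSpec(all_cols.min(axis=0), all_cols.max(axis=0))

    xs, ys = [], []
    label_list = labels or (next(iter(data_map)),)
    for li, kvp in enumerate(label_list):
        xn, _ = normalize_batch(data_map[kvp].batch, norm)
        xs.append(xn)
        ys.append(np.full(xn.shape[0], li, dtype=np.int64))
    X = np.concatenate(xs)
    Y = np.concatenate(ys)
    n_total = X.shape[0]
    batch = min(tcfg.batch_size, n_total)
    steps_per_epoch = max(n_total // batch, 1)

    params = init_params(gspec, dspec, init_rng)
    # bias-corrected EMA: shadow accumulates from zero and is divided by
    # (1 - decay^t), so short runs are not anchored to the random init
    ema_raw = {
        k: np.zeros_like(v) for k, v in params.items() if k.startswith("g.")
    }
    ema = {k: v.copy() for k, v in params.items() if k.startswith("g.")}
    cache_d: dict[str, np.ndarray] = {}
    cache_g: dict[str, np.ndarray] = {}
    sn_state = None
    if dspec.spectral_norm:
        sn_rng = np.random.default_rng(ss.spawn(1)[0])
        sn_state = {
            f"d.W{i}": sn_rng.standard_normal(params[f"d.W{i}"].shape[0])
            for i in range(4)
        }
        for k, u in sn_state.items():
            sn_state[k] = u / np.linalg.norm(u)

    n_lab = len(label_list)
    g_keys = [k for k in params if k.startswith("g.")]
    d_keys = [k for k in params if k.startswith("d.")]
    train_log: list[dict] = []

    def onehot_of(idx):
        oh = np.zeros((idx.size, n_lab))
        oh[np.arange(idx.size), idx] = 1.0
        return oh

    model = TrainedGenerator(
        gspec=gspec, dspec=dspec, params=params, ema_params=ema, norm=norm,
        kvp=None if gspec.conditional else int(label_list[0]),
        train_log=train_log, sn_state=sn_state,
    )

    g_step = 0
    best = None
    for epoch in range(1, tcfg.epochs + 1):
        perm = shuffle_rng.permutation(n_total)
        d_loss_val = g_loss_val = float("nan")
        for step in range(steps_per_epoch):
            sel = perm[step * batch : (step + 1) * batch]
            xb, yb = X[sel], Y[sel]
            oh = onehot_of(yb) if gspec.conditional else None

            # ---- discriminator update(s)
            for _ in range(tcfg.d_steps):
                z = latent_rng.standard_normal((xb.shape[0], gspec.latent_dim))
                fake = _g_forward_np(params, z, yb, gspec.conditional)
                d_eff, d_raw = _d_weight_vars(params, dspec, sn_state, update_sn=True)
                emb_var = d_raw.get("d.embed")
                xr = Var(xb)
                xf = Var(fake)
                d_real = _d_forward_var(d_eff, _d_input(xr, oh, emb_var))
                d_fake = _d_forward_var(d_eff, _d_input(xf, oh, emb_var))
                use_gp = tcfg.loss == "wasserstein" and not dspec.spectral_norm
                mix = (
                    latent_rng.uniform(size=(xb.shape[0], 1)) if use_gp else None
                )
                d_loss, _ = compute_losses(
                    d_real, d_fake, tcfg.loss, tcfg.r1_gamma, xr,
                    gp_lambda=tcfg.gp_lambda if use_gp else 0.0,
                    d_fn=(lambda xh: _d_forward_var(d_eff, _d_input(xh, oh, emb_var)))
                    if use_gp else None,
                    fake_batch=xf, mix_eps=mix,
                )
                gd = grad(d_loss, [d_raw[k] for k in d_keys])
                _rmsprop_update(
                    params, {k: g.value for k, g in zip(d_keys, gd)}, cache_d,
                    tcfg.lr, tcfg.rmsprop_alpha, tcfg.rmsprop_eps,
                )
                d_loss_val = float(d_loss.value)

            # ---- generator update (D weights constant)
            z = latent_rng.standard_normal((xb.shape[0], gspec.latent_dim))
            g_vars = {k: Var(params[k]) for k in g_keys}
            embed_rows = (oh, g_vars["g.embed"]) if gspec.conditional else None
            fake_var = _g_forward_var(g_vars, z, embed_rows, gspec.conditional)
            d_eff_const, _ = _d_weight_vars(params, dspec, sn_state, update_sn=False)
            demb = Var(params["d.embed"]) if "d.embed" in params else None
            d_fake = _d_forward_var(d_eff_const, _d_input(fake_var, oh, demb))
            _, g_loss = compute_losses(
                Var(np.zeros((1, 1))), d_fake, tcfg.loss, 0.0, None
            )
            gg = grad(g_loss, [g_vars[k] for k in g_keys])
            _rmsprop_update(
                params, {k: g.value for k, g in zip(g_keys, gg)}, cache_g,
                tcfg.lr, tcfg.rmsprop_alpha, tcfg.rmsprop_eps,
            )
            g_loss_val = float(g_loss.value)

            if not (np.isfinite(d_loss_val) and np.isfinite(g_loss_val)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {step}: "
                    f"d={d_loss_val} g={g_loss_val}"
                )

            decay = tcfg.ema_decay if tcfg.ema else 0.0
            g_step += 1
            for k in g_keys:
                ema_raw[k] *= decay
                ema_raw[k] += (1.0 - decay) * params[k]

        correction = 1.0 - decay**g_step
        for k in g_keys:
            np.divide(ema_raw[k], correction, out=ema[k])

        entry = {"epoch": epoch, "d_loss": d_loss_val, "g_loss": g_loss_val}
        if val_data is not None:
            entry.update(_validation_entry(model, val_data, tcfg, val_rng))
            if tcfg.keep_best and (
                best is None or entry["val_l_total"] < best[0]
            ):
                best = (
                    entry["val_l_total"],
                    {k: params[k].copy() for k in g_keys},
                    {k: ema[k].copy() for k in g_keys},
                    epoch,
                )
        train_log.append(entry)

    if tcfg.keep_best and best is not None:
        for k in g_keys:  # params/ema are the model's own dicts
            params[k] = best[1][k]
            ema[k] = best[2][k]
        train_log.append({"best_epoch": best[3], "best_val_l_total": best[0]})

    return model


def _validation_entry(model, val_data, tcfg, val_rng):
    if isinstance(val_data, PhaseSpace):
        val_map = {int(val_data.kvp_label): val_data}
    else:
        val_map = {int(k): v for k, v in val_data.items()}
    reports = {}
    for kvp, ps in val_map.items():
        n_cmp = min(ps.n, tcfg.val_particles or ps.n)
        idx = val_rng.choice(ps.n, size=n_cmp, replace=False)
        ref = ps.batch.take(idx)
        label = kvp if model.gspec.conditional else None
        seed = int(val_rng.integers(2**31))
        try:
            gen = sample_particles(
                model, n_cmp, label=label, use_ema=tcfg.ema, seed=seed
            )
        except ModelQualityError:
            # unusable generator scores the disjoint-support worst case
            reports[kvp] = evaluation.HistogramLossReport(
                per_parameter={c: 2.0 * n_cmp for c in evaluation.COLUMNS},
                l_total=2.0 * n_cmp * evaluation.N_PARAMETERS,
                n_particles=n_cmp,
            )
            continue
        rep = evaluation.histogram_loss(
            ref, gen, evaluation.HistogramSpec(tcfg.val_bins, n_cmp)
        )
        reports[kvp] = rep
    mean_total = evaluation.conditional_total_loss(list(reports.values()))
    return {
        "val_l_total": mean_total,
        "val_per_label": {str(k): r.l_total for k, r in reports.items()},
        "val_error_percent": {
            str(k): r.error_percent for k, r in reports.items()
        },
    }


# ---------------------------------------------------------------------------
# sampling and interpolation
# ---------------------------------------------------------------------------

def sample_particles(
    g: TrainedGenerator,
    n: int,
    label=None,
    use_ema: bool = True,
    seed: int = 0,
    return_stats: bool = False,
):
    """Draw n valid particles: forward, denormalize, renormalize directions,
    reject rows with dz <= 0 or energy outside (0, kvp] and resample."""
    if n < 1:
        raise ValueError("n must be >= 1")
    kvp = float(label) if g.gspec.conditional else float(g.kvp)
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    accepted = 0
    proposed = 0
    while accepted < n:
        m = max(int(1.2 * (n - accepted)) + 64, 64)
        z = rng.standard_normal((m, g.gspec.latent_dim))
        raw = g.forward(z, label=label, use_ema=use_ema)
        cols = denormalize_batch(raw, g.norm).columns()
        dnorm = np.sqrt(cols[:, 2] ** 2 + cols[:, 3] ** 2 + cols[:, 4] ** 2)
        ok = dnorm > 1e-9
        cols[ok, 2:5] /= dnorm[ok, None]
        ok &= cols[:, 4] > 0.0
        ok &= (cols[:, 5] > 0.0) & (cols[:, 5] <= kvp)
        proposed += m
        kept = cols[ok]
        out.append(kept)
        accepted += kept.shape[0]
        if proposed >= 1024 and accepted / proposed < 0.5:
            raise ModelQualityError(
                f"sampling rejection rate {1 - accepted / proposed:.1%} exceeds 50%"
            )
    batch = ParticleBatch.from_columns(np.concatenate(out)[:n])
    if return_stats:
        return batch, {"proposed": proposed, "rejected": proposed - accepted}
    return batch


def sample_interpolated_particles(
    g: TrainedGenerator,
    n: int,
    lam: float,
    label1,
    label2,
    mode: str = "hidden",
    use_ema: bool = True,
    seed: int = 0,
) -> ParticleBatch:
    """Draw n valid particles from the energy-interpolated generator.

    Validity rules match :func:`sample_particles`; the energy bound is the
    larger of the two interpolated tube potentials.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    kvp = max(float(label1), float(label2))
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    accepted = proposed = 0
    while accepted < n:
        m = max(int(1.2 * (n - accepted)) + 64, 64)
        z = rng.standard_normal((m, g.gspec.latent_dim))
        raw = interpolate_energies(g, lam, label1, label2, z, mode, use_ema)
        cols = denormalize_batch(raw, g.norm).columns()
        dnorm = np.sqrt(cols[:, 2] ** 2 + cols[:, 3] ** 2 + cols[:, 4] ** 2)
        ok = dnorm > 1e-9
        cols[ok, 2:5] /= dnorm[ok, None]
        ok &= cols[:, 4] > 0.0
        ok &= (cols[:, 5] > 0.0) & (cols[:, 5] <= kvp)
        proposed += m
        kept = cols[ok]
        out.append(kept)
        accepted += kept.shape[0]
        if proposed >= 1024 and accepted / proposed < 0.5:
            raise ModelQualityError(
                f"sampling rejection rate {1 - accepted / proposed:.1%} exceeds 50%"
            )
    return ParticleBatch.from_columns(np.concatenate(out)[:n])


def interpolate_energies(
    g: TrainedGenerator,
    lam: float,
    label1,
    label2,
    z: np.ndarray,
    mode: str = "hidden",
    use_ema: bool = True,
) -> np.ndarray:
    """Energy interpolation between two embedded labels.

    ``hidden`` (the preferred scheme) mixes first-hidden-layer activations:
    p = G2-3(lam * G1(z, E(y1)) + (1 - lam) * G1(z, E(y2))); the companion
    ``embedding`` mode mixes the embedding vectors before G1.  lam = 1
    reproduces label1 bitwise, lam = 0 label2.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("interpolation coefficient must be in [0, 1]")
    if not g.gspec.conditional:
        raise ValueError("energy interpolation needs a conditional generator")
    z = np.asarray(z, float)
    if mode == "hidden":
        h = lam * g.first_layer(z, label1, use_ema) + (1.0 - lam) * g.first_layer(
            z, label2, use_ema
        )
        return g.rest(h, use_ema)
    if mode == "embedding":
        w = g._weights(use_ema)
        e1 = w["g.embed"][g._label_index(label1)]
        e2 = w["g.embed"][g._label_index(label2)]
        emb = lam * e1 + (1.0 - lam) * e2
        h = g.first_layer(z, embedding=emb, use_ema=use_ema)
        return g.rest(h, use_ema)
    raise ValueError("mode must be 'hidden' or 'embedding'")
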
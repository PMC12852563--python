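"""LipidGAN: simplex-constrained tabular GAN for lipid compositions.

A small fully-connected generator/discriminator pair, written directly in
numpy (forward and backward passes, Adam updates), learns the joint
distribution of five-component lipid formulations on the 0–1 fraction scale.
The generator ends in a softmax head, so every sample lies exactly on the
simplex; scaled by 100 it is a valid mol% composition by construction.

Training uses the standard non-saturating adversarial losses
    L_D = E[softplus(-D(x_real))] + E[softplus(D(G(z)))]
    L_G = E[softplus(-D(G(z)))]
and is deterministic end-to-end given the config seed (weight init, batch
shuffling, and latent noise all come from one Generator). Because adversarial
dynamics on a small table cycle around the equilibrium rather than settling
on it, sampling uses an exponential moving average of the generator weights
(decay 0.999), which averages out the cycling and substantially reduces drift
of the generated marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit, softmax

from .data import FormulationDataset, FormulationError, LipidComposition


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class GANConfig:
    latent_dim: int = 8
    hidden: tuple[int, ...] = (64, 64)
    epochs: int = 4000
    batch_size: int = 32
    lr_g: float = 1e-3
    lr_d: float = 1e-3
    beta1: float = 0.5
    beta2: float = 0.999
    ema_decay: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.latent_dim < 1:
            raise FormulationError("epochs and latent_dim must be >= 1")


def _init_mlp(rng: np.random.Generator, sizes: Sequence[int]) -> list[np.ndarray]:
    """He-style initialization; params stored flat as [W0, b0, W1, b1, ...]."""
    params = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        params.append(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        params.append(np.zeros(n_out))
    return params


def _lrelu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _mlp_forward(params: list[np.ndarray], x: np.ndarray) -> tuple[np.ndarray, list]:
    """Linear layers with leaky-ReLU between them; final layer left linear."""
    cache = []
    h = x
    n_layers = len(params) // 2
    for i in range(n_layers):
        W, b = params[2 * i], params[2 * i + 1]
        z = h @ W + b
        cache.append((h, z))
        h = _lrelu(z) if i < n_layers - 1 else z
    return h, cache


def _mlp_backward(
    params: list[np.ndarray], cache: list, grad_out: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Returns (param grads, grad wrt input)."""
    grads: list[np.ndarray] = [np.zeros_like(p) for p in params]
    n_layers = len(params) // 2
    g = grad_out
    for i in reversed(range(n_layers)):
        h_in, z = cache[i]
        if i < n_layers - 1:  # undo the activation of this layer's output
            g = g * np.where(z > 0, 1.0, 0.2)
        grads[2 * i] = h_in.T @ g
        grads[2 * i + 1] = g.sum(axis=0)
        g = g @ params[2 * i].T
    return grads, g


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1: float, beta2: float):
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)

    def state(self) -> dict:
        return {
            "m": [a.tolist() for a in self.m],
            "v": [a.tolist() for a in self.v],
            "t": self.t,
        }

    @classmethod
    def from_state(cls, params, lr, beta1, beta2, state) -> "_Adam":
        opt = cls(params, lr, beta1, beta2)
        opt.m = [np.asarray(a) for a in state["m"]]
        opt.v = [np.asarray(a) for a in state["v"]]
        opt.t = state["t"]
        return opt


@dataclass
class GANState:
    gen_params: list[np.ndarray]  # raw (training) generator weights
    ema_params: list[np.ndarray]  # averaged generator weights used for sampling
    disc_params: list[np.ndarray]
    loss_trace: list[tuple[float, float]]  # (disc loss, gen loss) per epoch
    config: GANConfig
    epochs_trained: int
    opt_g_state: dict = field(repr=False, default_factory=dict)
    opt_d_state: dict = field(repr=False, default_factory=dict)
    rng_state: dict = field(repr=False, default_factory=dict)

    # -- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "epochs_trained": self.epochs_trained,
            "loss_trace": self.loss_trace,
            "gen_params": [p.tolist() for p in self.gen_params],
            "ema_params": [p.tolist() for p in self.ema_params],
            "disc_params": [p.tolist() for p in self.disc_params],
            "opt_g_state": self.opt_g_state,
            "opt_d_state": self.opt_d_state,
            "rng_state": self.rng_state,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GANState":
        with open(path) as fh:
            payload = json.load(fh)
        cfgd = payload["config"]
        cfgd["hidden"] = tuple(cfgd["hidden"])
        return cls(
            gen_params=[np.asarray(p) for p in payload["gen_params"]],
            ema_params=[np.asarray(p) for p in payload["ema_params"]],
            disc_params=[np.asarray(p) for p in payload["disc_params"]],
            loss_trace=[tuple(t) for t in payload["loss_trace"]],
            config=GANConfig(**cfgd),
            epochs_trained=payload["epochs_trained"],
            opt_g_state=payload["opt_g_state"],
            opt_d_state=payload["opt_d_state"],
            rng_state=payload["rng_state"],
        )


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _generator_samples(gen_params: list[np.ndarray], z: np.ndarray) -> np.ndarray:
    logits, _ = _mlp_forward(gen_params, z)
    return softmax(logits, axis=1)


def train_gan(
    source: FormulationDataset,
    cfg: GANConfig | None = None,
    resume_from: GANState | None = None,
    extra_epochs: int | None = None,
) -> GANState:
    """Train (or resume) LipidGAN on a dataset's compositions.

    Only the compositions are used, on the 0–1 fraction scale. When
    ``resume_from`` is given, optimizer and RNG state are restored so that
    one long run and a chain of resumed runs produce the same model.
    """
    cfg = (resume_from.config if resume_from is not None else cfg) or GANConfig()
    if len(source) < 50:
        raise FormulationError(f"GAN training needs >= 50 records, got {len(source)}")
    x_real_all = source.compositions() / 100.0
    n = len(x_real_all)
    bs = min(cfg.batch_size, n)

    if resume_from is None:
        rng = np.random.default_rng(cfg.seed)
        gen_params = _init_mlp(rng, [cfg.latent_dim, *cfg.hidden, 5])
        ema_params = [p.copy() for p in gen_params]
        disc_params = _init_mlp(rng, [5, *cfg.hidden, 1])
        opt_g = _Adam(gen_params, cfg.lr_g, cfg.beta1, cfg.beta2)
        opt_d = _Adam(disc_params, cfg.lr_d, cfg.beta1, cfg.beta2)
        loss_trace: list[tuple[float, float]] = []
        epochs_to_run = cfg.epochs
        epochs_done = 0
    else:
        rng = np.random.default_rng()
        rng.bit_generator.state = resume_from.rng_state
        gen_params = [p.copy() for p in resume_from.gen_params]
        ema_params = [p.copy() for p in resume_from.ema_params]
        disc_params = [p.copy() for p in resume_from.disc_params]
        opt_g = _Adam.from_state(gen_params, cfg.lr_g, cfg.beta1, cfg.beta2, resume_from.opt_g_state)
        opt_d = _Adam.from_state(disc_params, cfg.lr_d, cfg.beta1, cfg.beta2, resume_from.opt_d_state)
        loss_trace = list(resume_from.loss_trace)
        epochs_to_run = extra_epochs if extra_epochs is not None else cfg.epochs
        epochs_done = resume_from.epochs_trained

    n_batches = max(n // bs, 1)
    for epoch in range(epochs_to_run):
        perm = rng.permutation(n)
        d_losses, g_losses = [], []
        for b in range(n_batches):
            x_real = x_real_all[perm[b * bs : (b + 1) * bs]]
            m = len(x_real)

            # --- discriminator step ---
            z = rng.standard_normal((m, cfg.latent_dim))
            x_fake = _generator_samples(gen_params, z)
            logit_r, cache_r = _mlp_forward(disc_params, x_real)
            logit_f, cache_f = _mlp_forward(disc_params, x_fake)
            d_loss = float(np.mean(_softplus(-logit_r)) + np.mean(_softplus(logit_f)))
            g_r = -expit(-logit_r) / m
            g_f = expit(logit_f) / m
            grads_r, _ = _mlp_backward(disc_params, cache_r, g_r)
            grads_f, _ = _mlp_backward(disc_params, cache_f, g_f)
            opt_d.step(disc_params, [a + b_ for a, b_ in zip(grads_r, grads_f)])

            # --- generator step ---
            z = rng.standard_normal((m, cfg.latent_dim))
            logits_g, cache_g = _mlp_forward(gen_params, z)
            p = softmax(logits_g, axis=1)
            logit_f, cache_f = _mlp_forward(disc_params, p)
            g_loss = float(np.mean(_softplus(-logit_f)))
            dl = -expit(-logit_f) / m
            _, dx = _mlp_backward(disc_params, cache_f, dl)
            # back through the softmax head: J^T v = p * (v - <v, p>)
            dlogits = p * (dx - np.sum(dx * p, axis=1, keepdims=True))
            grads_g, _ = _mlp_backward(gen_params, cache_g, dlogits)
            opt_g.step(gen_params, grads_g)
            for ema, p_ in zip(ema_params, gen_params):
                ema *= cfg.ema_decay
                ema += (1.0 - cfg.ema_decay) * p_

            d_losses.append(d_loss)
            g_losses.append(g_loss)

        ep_d, ep_g = float(np.mean(d_losses)), float(np.mean(g_losses))
        if not (np.isfinite(ep_d) and np.isfinite(ep_g)):
            raise TrainingError(f"non-finite GAN loss at epoch {epochs_done + epoch + 1}")
        loss_trace.append((ep_d, ep_g))

    return GANState(
        gen_params=gen_params,
        ema_params=ema_params,
        disc_params=disc_params,
        loss_trace=loss_trace,
        config=cfg,
        epochs_trained=epochs_done + epochs_to_run,
        opt_g_state=opt_g.state(),
        opt_d_state=opt_d.state(),
        rng_state=rng.bit_generator.state,
    )


def generate_formulations(state: GANState, n: int, seed: int = 0) -> np.ndarray:
    """Sample ``n`` compositions (mol%, rows sum to 100) from a trained GAN."""
    if n <= 0:
        raise FormulationError("n must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, state.config.latent_dim))
    fractions = _generator_samples(state.ema_params, z)
    return fractions * 100.0


def generate_compositions(state: GANState, n: int, seed: int = 0) -> list[LipidComposition]:
    return [LipidComposition.from_array(row) for row in generate_formulations(state, n, seed)]


# -- fidelity ---------------------------------------------------------------

@dataclass(frozen=True)
class FidelityMetrics:
    """Synthetic-vs-source marginal agreement, on the 0–1 fraction scale."""

    per_component_mae: dict[str, float]
    per_component_rmse: dict[str, float]
    per_component_range_overlap: dict[str, float]
    pooled_quantile_r: float
    degenerate: bool

    @property
    def mean_mae(self) -> float:
        return float(np.mean(list(self.per_component_mae.values())))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(list(self.per_component_rmse.values())))


def _quantile_pairs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort both samples; resample the longer by linear quantile interpolation."""
    a, b = np.sort(a), np.sort(b)
    k = min(len(a), len(b))
    grid = np.linspace(0.0, 1.0, k)
    if len(a) > k:
        a = np.quantile(a, grid, method="linear")
    if len(b) > k:
        b = np.quantile(b, grid, method="linear")
    return a, b


def _range_overlap(a: np.ndarray, b: np.ndarray) -> float:
    lo = max(a.min(), b.min())
    hi = min(a.max(), b.max())
    union = max(a.max(), b.max()) - min(a.min(), b.min())
    if union <= 0:
        return 1.0
    return max(hi - lo, 0.0) / union


def fidelity_report(real: FormulationDataset, synthetic: FormulationDataset) -> FidelityMetrics:
    """Compare synthetic to source compositions, marginal by marginal.

    Per component: both marginals are sorted, the longer is resampled to the
    shorter's length by linear quantile interpolation, and MAE/RMSE are
    computed on 0–1 fractions. The pooled R is the Pearson correlation of the
    paired quantiles concatenated across the five components.
    """
    if len(real) < 3 or len(synthetic) < 3:
        raise FormulationError("fidelity report needs >= 3 records on each side")
    from .data import LIPIDS

    xr = real.compositions() / 100.0
    xs = synthetic.compositions() / 100.0
    mae, rmse, overlap = {}, {}, {}
    pooled_a, pooled_b = [], []
    for j, name in enumerate(LIPIDS):
        a, b = _quantile_pairs(xr[:, j], xs[:, j])
        mae[name] = float(np.mean(np.abs(a - b)))
        rmse[name] = float(np.sqrt(np.mean((a - b) ** 2)))
        overlap[name] = _range_overlap(xr[:, j], xs[:, j])
        pooled_a.append(a)
        pooled_b.append(b)
    a = np.concatenate(pooled_a)
    b = np.concatenate(pooled_b)
    # zero within-component spread on either side means the pooled correlation
    # would reflect only the separation between component means, not
    # distributional match — report it as degenerate instead
    degenerate = bool(
        np.std(a) == 0
        or np.std(b) == 0
        or np.ptp(xr, axis=0).max() == 0
        or np.ptp(xs, axis=0).max() == 0
    )
    r = float("nan") if degenerate else float(np.corrcoef(a, b)[0, 1])
    return FidelityMetrics(mae, rmse, overlap, r, degenerate)
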
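"""The adversarial autoencoder: architecture, losses, training, latents.

The model encodes each contig's ``[TNF || co-abundance]`` vector into a
continuous Gaussian latent z (via reparameterised mu/sigma heads) and a
categorical latent y (softmax head, sampled through the Gumbel-softmax
relaxation at temperature tau). The decoder reconstructs both feature
blocks from ``[z || y]``; the abundance block gets a softmax output so the
reconstruction is a distribution over samples, the TNF block is linear.
Two discriminators adversarially pin z to a standard normal prior and y to
a relaxed one-hot categorical prior, each with a sigmoid probability
output.

Loss system (all probabilities clamped before logs):

* discriminators:  LDz = 1/2 BCE(D_z(z), 0) + 1/2 BCE(D_z(S~N(0,I)), 1)
  and analogously LDy with the Cat(tau) prior;
* reconstruction:  L_rec = w_coab * CE(A_in, A_out) + w_TNF * MSE(T_in, T_out);
* regularisation:  LRz = BCE(D_z(z), 1), LRy = BCE(D_y(y), 1),
  L_reg = (1 - slr) * LRz + slr * LRy   (optionally the negated
  discriminator-loss form behind ``minimax_regularization``);
* total:           L = (1 - sl) * L_rec + sl * L_reg.

Each minibatch performs three updates in fixed order: encoder/decoder on
L (gradients flow through frozen discriminators), then D_z on LDz, then
D_y on LDy. All three use Adam.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .features import TNF_DIM, FeatureDataset
from .nn import (
    Adam,
    BatchNorm,
    LeakyReLU,
    Linear,
    Param,
    Sequential,
    bce,
    cross_entropy,
    gumbel_softmax,
    sigmoid,
    softmax,
    softmax_backward,
)

logger = logging.getLogger(__name__)

SIGMA_MIN = 1e-6
SIGMA_MAX = 50.0
DEFAULT_ALPHA = 0.85  # reconstruction weight split between abundance and TNF

LOSS_COLUMNS = ("L_rec", "LRz", "LRy", "LDz", "LDy", "L_reg", "L")


@dataclass
class AAEConfig:
    """Hyperparameters of the adversarial autoencoder.

    Defaults are the tuned full-scale values: two hidden layers of 547
    units, 283-dim z, 700-dim y (adjustable to the expected taxonomic
    diversity), temperature 0.1596 for both the encoder relaxation and the
    categorical prior, loss mixing sl = 0.0964 and slr = 0.5.
    """

    n_hidden: int = 547
    n_hidden_layers: int = 2
    n_z: int = 283
    n_y: int = 700
    temperature: float = 0.1596
    sl: float = 0.0964
    slr: float = 0.5
    w_coab: float | None = None  # default alpha / ln(S)  (alpha if S == 1)
    w_tnf: float | None = None  # default 1 - alpha
    batch_size: int = 256
    epochs: int = 300
    learning_rate: float = 1e-3
    seed: int = 0
    minimax_regularization: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.sl <= 1.0 and 0.0 <= self.slr <= 1.0):
            raise ValueError("sl and slr must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("n_hidden", "n_hidden_layers", "n_z", "n_y", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def resolve_weights(self, n_samples: int) -> tuple[float, float]:
        w_coab = self.w_coab
        if w_coab is None:
            w_coab = (
                DEFAULT_ALPHA / math.log(n_samples) if n_samples > 1 else DEFAULT_ALPHA
            )
        w_tnf = self.w_tnf if self.w_tnf is not None else 1.0 - DEFAULT_ALPHA
        return w_coab, w_tnf


@dataclass
class EncoderOutput:
    mu: np.ndarray  # (batch, n_z)
    sigma: np.ndarray  # (batch, n_z), strictly positive
    y_probs: np.ndarray  # (batch, n_y), rows on the simplex
    y_logits: np.ndarray  # (batch, n_y)


@dataclass
class LossBreakdown:
    L_rec: float
    LRz: float
    LRy: float
    LDz: float
    LDy: float
    L_reg: float
    L: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def check_finite(self) -> None:
        for name, value in self.as_dict().items():
            if not math.isfinite(value):
                raise FloatingPointError(f"non-finite loss term {name} = {value}")


@dataclass
class LatentCodes:
    Z: np.ndarray  # (n, n_z) posterior means
    Y: np.ndarray  # (n,) integer labels in [0, n_y)
    contig_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# loss functions (pure, probability-level)


def reconstruction_loss(
    A_in: np.ndarray,
    A_out: np.ndarray,
    T_in: np.ndarray,
    T_out: np.ndarray,
    w_coab: float,
    w_tnf: float,
) -> float:
    """w_coab * CE(A_in, A_out) + w_tnf * MSE(T_in, T_out), batch-averaged.

    CE is -sum_s A_in[s] log A_out[s] per row (clamped); MSE is the mean
    squared error over all TNF elements.
    """
    ce = cross_entropy(A_in, A_out)
    mse = float(np.mean((T_in - T_out) ** 2))
    return w_coab * ce + w_tnf * mse


def discriminator_loss(p_latent: np.ndarray, p_prior: np.ndarray) -> float:
    """1/2 BCE(D(latent), 0) + 1/2 BCE(D(prior), 1) on probability outputs."""
    return 0.5 * bce(p_latent, 0) + 0.5 * bce(p_prior, 1)


def regularization_loss(
    p_z: np.ndarray, p_y: np.ndarray, slr: float
) -> tuple[float, float, float]:
    """(L_reg, LRz, LRy): encoder-side losses against the 'real' label."""
    lrz = bce(p_z, 1)
    lry = bce(p_y, 1)
    return (1.0 - slr) * lrz + slr * lry, lrz, lry


def total_loss(l_rec: float, l_reg: float, sl: float) -> float:
    """L = (1 - sl) * L_rec + sl * L_reg."""
    return (1.0 - sl) * l_rec + sl * l_reg


# ---------------------------------------------------------------------------
# network modules


def _trunk(n_in: int, n_hidden: int, n_layers: int, rng, batchnorm: bool) -> Sequential:
    layers: list = []
    d = n_in
    for _ in range(n_layers):
        layers.append(Linear(d, n_hidden, rng))
        if batchnorm:
            layers.append(BatchNorm(n_hidden))
        layers.append(LeakyReLU())
        d = n_hidden
    return Sequential(layers)


class Encoder:
    def __init__(self, n_in: int, cfg: AAEConfig, rng: np.random.Generator):
        self.trunk = _trunk(n_in, cfg.n_hidden, cfg.n_hidden_layers, rng, True)
        self.lin_mu = Linear(cfg.n_hidden, cfg.n_z, rng)
        self.lin_sigma = Linear(cfg.n_hidden, cfg.n_z, rng)
        self.lin_y = Linear(cfg.n_hidden, cfg.n_y, rng)
        self._sigma_unclamped: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> EncoderOutput:
        if not np.isfinite(x).all():
            raise ValueError("non-finite values in encoder input")
        h = self.trunk.forward(x, train=train)
        mu = self.lin_mu.forward(h, train=train)
        s_lin = self.lin_sigma.forward(h, train=train)
        # positive transform with clamping for numerical safety
        sigma_raw = np.exp(np.clip(s_lin, -700.0, 700.0))
        sigma = np.clip(sigma_raw, SIGMA_MIN, SIGMA_MAX)
        self._sigma_unclamped = (sigma_raw > SIGMA_MIN) & (sigma_raw < SIGMA_MAX)
        y_logits = self.lin_y.forward(h, train=train)
        return EncoderOutput(
            mu=mu, sigma=sigma, y_probs=softmax(y_logits), y_logits=y_logits
        )

    def backward(
        self, g_mu: np.ndarray, g_sigma: np.ndarray, g_y_logits: np.ndarray,
        sigma: np.ndarray,
    ) -> None:
        g_slin = np.where(self._sigma_unclamped, g_sigma * sigma, 0.0)
        gh = self.lin_mu.backward(g_mu)
        gh += self.lin_sigma.backward(g_slin)
        gh += self.lin_y.backward(g_y_logits)
        self.trunk.backward(gh)

    def params(self) -> list[Param]:
        return (
            self.trunk.params()
            + self.lin_mu.params()
            + self.lin_sigma.params()
            + self.lin_y.params()
        )

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Decoder:
    """Mirror of the encoder; softmax abundance head, linear TNF head."""

    def __init__(self, n_samples: int, cfg: AAEConfig, rng: np.random.Generator):
        self.trunk = _trunk(
            cfg.n_z + cfg.n_y, cfg.n_hidden, cfg.n_hidden_layers, rng, True
        )
        self.lin_ab = Linear(cfg.n_hidden, n_samples, rng)
        self.lin_tnf = Linear(cfg.n_hidden, TNF_DIM, rng)
        self.n_z = cfg.n_z

    def forward(
        self, z: np.ndarray, y: np.ndarray, train: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        h = self.trunk.forward(np.hstack([z, y]), train=train)
        a_out = softmax(self.lin_ab.forward(h, train=train))
        t_out = self.lin_tnf.forward(h, train=train)
        return a_out, t_out

    def backward(
        self, g_ab_logits: np.ndarray, g_tnf: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        gh = self.lin_ab.backward(g_ab_logits) + self.lin_tnf.backward(g_tnf)
        g_in = self.trunk.backward(gh)
        return g_in[:, : self.n_z], g_in[:, self.n_z:]

    def params(self) -> list[Param]:
        return self.trunk.params() + self.lin_ab.params() + self.lin_tnf.params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Discriminator:
    """Same trunk shape as the decoder but without batch normalisation;
    single sigmoid output interpreted as P(input came from the prior)."""

    def __init__(self, n_in: int, cfg: AAEConfig, rng: np.random.Generator):
        self.trunk = _trunk(n_in, cfg.n_hidden, cfg.n_hidden_layers, rng, False)
        self.lin_out = Linear(cfg.n_hidden, 1, rng)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.trunk.forward(x, train=train)
        return self.lin_out.forward(h, train=train)[:, 0]  # logits

    def backward(self, g_logit: np.ndarray) -> np.ndarray:
        gh = self.lin_out.backward(g_logit[:, None])
        return self.trunk.backward(gh)

    def params(self) -> list[Param]:
        return self.trunk.params() + self.lin_out.params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# sampling


def sample_latents(
    enc: EncoderOutput, tau: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reparameterised samples: z = mu + sigma * eps, y ~ Gumbel-softmax(tau).

    Returns (z, y_relaxed, eps); eps is kept for backpropagation.
    """
    eps = rng.normal(size=enc.mu.shape)
    z = enc.mu + enc.sigma * eps
    y_relaxed = gumbel_softmax(enc.y_logits, tau, rng)
    return z, y_relaxed, eps


# ---------------------------------------------------------------------------
# the model


class AAE:
    def __init__(self, n_samples: int, config: AAEConfig):
        self.config = config
        self.n_samples = n_samples
        self.n_in = TNF_DIM + n_samples
        rng = np.random.default_rng(config.seed)
        self.encoder = Encoder(self.n_in, config, rng)
        self.decoder = Decoder(n_samples, config, rng)
        self.d_z = Discriminator(config.n_z, config, rng)
        self.d_y = Discriminator(config.n_y, config, rng)
        self._rng = rng
        lr = config.learning_rate
        self.opt_ae = Adam(self.encoder.params() + self.decoder.params(), lr=lr)
        self.opt_dz = Adam(self.d_z.params(), lr=lr)
        self.opt_dy = Adam(self.d_y.params(), lr=lr)
        self.history: list[dict[str, float]] = []  # per-epoch means
        self.steps: list[LossBreakdown] = []  # per-minibatch

    # -- single minibatch ---------------------------------------------------

    def _train_batch(
        self, x: np.ndarray, w_coab: float, w_tnf: float
    ) -> LossBreakdown:
        cfg = self.config
        rng = self._rng
        batch = x.shape[0]
        a_in = x[:, TNF_DIM:]
        t_in = x[:, :TNF_DIM]

        # (1) encoder/decoder update on L = (1-sl) L_rec + sl L_reg
        self.encoder.zero_grad()
        self.decoder.zero_grad()
        self.d_z.zero_grad()
        self.d_y.zero_grad()
        enc = self.encoder.forward(x, train=True)
        z, y_rel, eps = sample_latents(enc, cfg.temperature, rng)
        a_out, t_out = self.decoder.forward(z, y_rel, train=True)
        tz = self.d_z.forward(z, train=True)
        ty = self.d_y.forward(y_rel, train=True)
        pz, py = sigmoid(tz), sigmoid(ty)

        l_rec = reconstruction_loss(a_in, a_out, t_in, t_out, w_coab, w_tnf)
        l_reg_nonsat, lrz, lry = regularization_loss(pz, py, cfg.slr)

        sl, slr = cfg.sl, cfg.slr
        g_ab_logits = (1.0 - sl) * w_coab * (a_out - a_in) / batch
        g_tnf = (1.0 - sl) * w_tnf * 2.0 * (t_out - t_in) / (batch * TNF_DIM)
        gz, gy = self.decoder.backward(g_ab_logits, g_tnf)
        if cfg.minimax_regularization:
            # L_reg = (1-slr)(-LDz) + slr(-LDy); only the latent branch of
            # each discriminator loss depends on the encoder
            g_tz = sl * (1.0 - slr) * (-0.5) * pz / batch
            g_ty = sl * slr * (-0.5) * py / batch
        else:
            g_tz = sl * (1.0 - slr) * (pz - 1.0) / batch
            g_ty = sl * slr * (py - 1.0) / batch
        gz = gz + self.d_z.backward(g_tz)
        gy = gy + self.d_y.backward(g_ty)
        g_mu = gz
        g_sigma = gz * eps
        g_y_logits = softmax_backward(y_rel, gy) / cfg.temperature
        self.encoder.backward(g_mu, g_sigma, g_y_logits, enc.sigma)
        self.opt_ae.step()
        # discriminator gradients from the encoder pass are discarded
        self.d_z.zero_grad()
        self.d_y.zero_grad()

        # (2) D_z update on LDz (latents treated as constants)
        prior_z = rng.normal(size=z.shape)
        t_lat = self.d_z.forward(z, train=True)
        p_lat = sigmoid(t_lat)
        self.d_z.backward(0.5 * p_lat / batch)
        t_pri = self.d_z.forward(prior_z, train=True)
        p_pri = sigmoid(t_pri)
        self.d_z.backward(0.5 * (p_pri - 1.0) / batch)
        ldz = discriminator_loss(p_lat, p_pri)
        self.opt_dz.step()

        # (3) D_y update on LDy with the relaxed categorical prior
        prior_y = gumbel_softmax(
            np.zeros_like(y_rel), cfg.temperature, rng
        )
        t_lat = self.d_y.forward(y_rel, train=True)
        p_lat = sigmoid(t_lat)
        self.d_y.backward(0.5 * p_lat / batch)
        t_pri = self.d_y.forward(prior_y, train=True)
        p_pri = sigmoid(t_pri)
        self.d_y.backward(0.5 * (p_pri - 1.0) / batch)
        ldy = discriminator_loss(p_lat, p_pri)
        self.opt_dy.step()

        if cfg.minimax_regularization:
            l_reg = (1.0 - slr) * -ldz + slr * -ldy
        else:
            l_reg = l_reg_nonsat
        loss = LossBreakdown(
            L_rec=l_rec, LRz=lrz, LRy=lry, LDz=ldz, LDy=ldy, L_reg=l_reg,
            L=total_loss(l_rec, l_reg, sl),
        )
        loss.check_finite()
        return loss

    # -- training loop ------------------------------------------------------

    def train(self, dataset: FeatureDataset) -> list[dict[str, float]]:
        """Train on the full dataset; returns the per-epoch loss history."""
        if dataset.n_contigs == 0:
            raise ValueError("cannot train on an empty dataset")
        if dataset.X.shape[1] != self.n_in:
            raise ValueError(
                f"dataset has {dataset.X.shape[1]} columns, model expects {self.n_in}"
            )
        cfg = self.config
        w_coab, w_tnf = cfg.resolve_weights(dataset.n_samples)
        x = dataset.X
        n = x.shape[0]
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            epoch_losses: list[LossBreakdown] = []
            for start in range(0, n, cfg.batch_size):
                batch_idx = order[start: start + cfg.batch_size]
                if batch_idx.size < 2:
                    continue  # batchnorm needs >= 2 rows
                loss = self._train_batch(x[batch_idx], w_coab, w_tnf)
                epoch_losses.append(loss)
                self.steps.append(loss)
            if not epoch_losses:
                raise ValueError(
                    "no trainable minibatch (need >= 2 contigs per batch)"
                )
            means = {
                k: float(np.mean([getattr(l, k) for l in epoch_losses]))
                for k in LOSS_COLUMNS
            }
            means["epoch"] = epoch
            self.history.append(means)
            if epoch == 0 or (epoch + 1) % 50 == 0:
                logger.info(
                    "epoch %d: L=%.4f L_rec=%.4f LDz=%.4f LDy=%.4f",
                    epoch, means["L"], means["L_rec"], means["LDz"], means["LDy"],
                )
        return self.history

    # -- inference ----------------------------------------------------------

    def encode(self, x: np.ndarray, train: bool = False) -> EncoderOutput:
        return self.encoder.forward(x, train=train)

    def decode(self, z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.decoder.forward(z, y, train=False)

    def extract_latents(self, dataset: FeatureDataset) -> LatentCodes:
        """Deterministic latents in evaluation mode: Z = mu(X), Y = argmax y."""
        enc = self.encoder.forward(dataset.X, train=False)
        return LatentCodes(
            Z=enc.mu,
            Y=enc.y_probs.argmax(axis=1),
            contig_ids=list(dataset.contig_ids),
        )

    # -- persistence --------------------------------------------------------

    def _named_params(self) -> dict[str, Param]:
        out = {}
        for net_name, net in (
            ("encoder", self.encoder), ("decoder", self.decoder),
            ("d_z", self.d_z), ("d_y", self.d_y),
        ):
            for i, p in enumerate(net.params()):
                out[f"{net_name}.{i}"] = p
        return out

    def _batchnorms(self) -> list[BatchNorm]:
        bns = []
        for net in (self.encoder.trunk, self.decoder.trunk):
            bns.extend(l for l in net.layers if isinstance(l, BatchNorm))
        return bns

    def save(self, path: str | Path) -> None:
        arrays = {k: p.value for k, p in self._named_params().items()}
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"bn{i}.running_mean"] = bn.running_mean
            arrays[f"bn{i}.running_var"] = bn.running_var
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(
                    {"n_samples": self.n_samples, **asdict(self.config)}
                ).encode(),
                dtype=np.uint8,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "AAE":
        data = np.load(path)
        meta = json.loads(bytes(data["__config__"]).decode())
        n_samples = meta.pop("n_samples")
        model = cls(n_samples, AAEConfig(**meta))
        for k, p in model._named_params().items():
            p.value[...] = data[k]
        for i, bn in enumerate(model._batchnorms()):
            bn.running_mean[...] = data[f"bn{i}.running_mean"]
            bn.running_var[...] = data[f"bn{i}.running_var"]
        return model


def write_loss_history(history: list[dict[str, float]], path: str | Path) -> None:
    """Loss-history TSV: epoch then the seven loss components per row."""
    with open(path, "w") as fh:
        fh.write("epoch\t" + "\t".join(LOSS_COLUMNS) + "\n")
        for row in history:
            fh.write(
                f"{int(row['epoch'])}\t"
                + "\t".join(f"{row[k]:.6g}" for k in LOSS_COLUMNS)
                + "\n"
            )
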
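"""Stage 1: adversarial imputation with a per-timestep uncertainty score.

The generator receives, for each timestep, the observed vector (placeholder 0
at missing cells), its mask, and masked noise, and emits an estimate for every
dimension; observed cells then overwrite the estimate (the merge step).  The
discriminator predicts, per dimension, the probability that a cell of the
merged vector is genuinely observed, and is trained against the true mask —
the mask-discrimination game that drives generative-adversarial imputers.
Alongside the fill, each timestep gets an uncertainty score: the RMS residual
between the generator's estimate and the reference value over the
missing-weighted dimensions, normalized by the observed count.  The score is
exported to the stage-2 corrector.

All data entering this module must already be on the normalized [-1, 1]
scale (the generator head is tanh).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import MLP, Adam, clamp_prob

__all__ = ["UganConfig", "UganState", "ImputationResult", "sample_noise",
           "generate", "merge_observed", "compute_uncertainty",
           "discriminator_loss", "generator_loss", "train_ugan",
           "apply_ugan"]


@dataclass
class UganConfig:
    """Hyperparameters of the adversarial imputer.

    ``alpha`` weights the masked reconstruction term of the generator loss;
    ``n_iter`` counts minibatch iterations of the alternating D/G loop.
    Noise perturbs the zero placeholders only, so its default range is small.
    """

    alpha: float = 10.0
    batch_size: int = 128
    n_iter: int = 1000
    learning_rate: float = 0.001
    noise_low: float = -0.01
    noise_high: float = 0.01
    g_hidden: tuple | None = None   # None -> (d, d)
    d_hidden: tuple | None = None
    seed: int = 1024

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.noise_low > self.noise_high:
            raise ValueError("noise_low must not exceed noise_high")


@dataclass
class UganState:
    """Trained generator/discriminator pair plus training diagnostics."""

    generator: MLP
    discriminator: MLP
    config: UganConfig
    d_loss_history: list = field(default_factory=list)
    g_loss_history: list = field(default_factory=list)
    recon_history: list = field(default_factory=list)


@dataclass
class ImputationResult:
    """Stage-1 output for one record (normalized scale).

    ``ddm`` holds the raw generator estimates for every cell (observed or
    not), ``merged`` the observed-overwritten fill, and ``uncertainty`` the
    per-timestep RMS deviation score.
    """

    ddm: np.ndarray
    merged: np.ndarray
    uncertainty: np.ndarray


def sample_noise(shape, config: UganConfig, rng: np.random.Generator):
    """I.i.d. uniform noise on ``[noise_low, noise_high]``."""
    return rng.uniform(config.noise_low, config.noise_high, size=shape)


def generate(state: UganState, x, m, z):
    """Generator estimates for a batch of timestep vectors.

    Rows are timesteps; the generator sees ``[x, m, (1-m) * z]`` so noise
    only enters at missing cells.  Estimates cover every dimension.
    """
    x, m, z = (np.atleast_2d(np.asarray(a, dtype=float)) for a in (x, m, z))
    if not x.shape == m.shape == z.shape:
        raise ValueError("x, m and z must share a (batch, d) shape")
    inp = np.concatenate([x, m, (1.0 - m) * z], axis=1)
    return state.generator.forward(inp)


def merge_observed(x, m, x_hat):
    """Overwrite generator estimates with the observed values."""
    x, m, x_hat = (np.asarray(a, dtype=float) for a in (x, m, x_hat))
    return m * x + (1.0 - m) * x_hat


def compute_uncertainty(x, m, x_hat, reference=None):
    """Per-timestep RMS residual over missing-weighted dimensions.

    For each timestep vector: ``u = sqrt(sum_i ((ref_i - xhat_i)(1-m_i))^2 /
    max(k, 1))`` with ``k`` the number of observed dimensions.  ``reference``
    defaults to ``x`` itself — in deployment the residual at a missing cell
    is then taken against the 0 placeholder; during benchmark evaluation the
    known ground truth can be passed instead.  Fully observed timesteps score
    exactly 0.
    """
    x, m, x_hat = (np.atleast_2d(np.asarray(a, dtype=float))
                   for a in (x, m, x_hat))
    ref = x if reference is None else np.atleast_2d(np.asarray(reference, float))
    resid = (ref - x_hat) * (1.0 - m)
    k = np.maximum(m.sum(axis=1), 1.0)
    return np.sqrt((resid ** 2).sum(axis=1) / k)


def discriminator_loss(d_prob, m):
    """Masked binary cross-entropy of mask prediction, averaged per cell."""
    p = clamp_prob(np.asarray(d_prob, dtype=float))
    m = np.asarray(m, dtype=float)
    ce = -(m * np.log(p) + (1.0 - m) * np.log(1.0 - p))
    return float(ce.mean())


def generator_loss(d_prob, x, x_hat, m, alpha):
    """Non-saturating adversarial term plus masked reconstruction.

    The adversarial part pushes the discriminator toward labelling imputed
    cells as observed; the reconstruction part anchors the generator to the
    observed cells, weighted by ``alpha``.
    """
    p = clamp_prob(np.asarray(d_prob, dtype=float))
    m = np.asarray(m, dtype=float)
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    adv = -((1.0 - m) * np.log(p)).mean()
    recon = (m * (x - x_hat) ** 2).mean()
    return float(adv + alpha * recon)


def _stack_timesteps(records):
    """Pool every record's timestep vectors into (N, d) value/mask arrays."""
    xs = [r.values.T for r in records]
    ms = [r.mask.T for r in records]
    return np.concatenate(xs, axis=0), np.concatenate(ms, axis=0)


def train_ugan(records, config: UganConfig):
    """Alternating D/G training on pooled timestep vectors.

    ``records`` are normalized :class:`~tdgan.data_model.MaskedSeries`.
    Returns the trained state and one :class:`ImputationResult` per record.
    Deterministic for a fixed config seed on one device.
    """
    if not records:
        raise ValueError("empty training set")
    X, M = _stack_timesteps(records)
    n_rows, d = X.shape
    rng = np.random.default_rng(config.seed)
    g_hidden = config.g_hidden or (d, d)
    d_hidden = config.d_hidden or (d, d)
    state = UganState(
        generator=MLP(rng, (3 * d, *g_hidden, d), head="tanh"),
        discriminator=MLP(rng, (d, *d_hidden, d), head="sigmoid"),
        config=config,
    )
    G, D = state.generator, state.discriminator
    opt_d = Adam(D.params(), lr=config.learning_rate)
    opt_g = Adam(G.params(), lr=config.learning_rate)
    mb = min(config.batch_size, n_rows)

    for it in range(config.n_iter):
        idx = rng.choice(n_rows, size=mb, replace=False)
        xb, mbk = X[idx], M[idx]
        zb = sample_noise(xb.shape, config, rng)

        # --- discriminator step (merged batch treated as fixed input)
        x_hat = generate(state, xb, mbk, zb)
        x_bar = merge_observed(xb, mbk, x_hat)
        p = D.forward(x_bar)
        loss_d = discriminator_loss(p, mbk)
        pc = clamp_prob(p)
        grad_p = (-(mbk / pc) + (1.0 - mbk) / (1.0 - pc)) / p.size
        D.backward(grad_p)
        opt_d.step()

        # --- generator step (discriminator frozen, gradient flows through it)
        x_hat = generate(state, xb, mbk, zb)
        x_bar = merge_observed(xb, mbk, x_hat)
        p = D.forward(x_bar)
        loss_g = generator_loss(p, xb, x_hat, mbk, config.alpha)
        pc = clamp_prob(p)
        grad_p = -((1.0 - mbk) / pc) / p.size
        grad_xbar = D.backward(grad_p)          # gradients w.r.t. D input
        grad_xhat = grad_xbar * (1.0 - mbk)
        grad_xhat += -2.0 * config.alpha * mbk * (xb - x_hat) / x_hat.size
        G.backward(grad_xhat)
        opt_g.step()

        if not (np.isfinite(loss_d) and np.isfinite(loss_g)):
            raise FloatingPointError(
                f"non-finite loss at iteration {it}: D={loss_d}, G={loss_g}")
        state.d_loss_history.append(loss_d)
        state.g_loss_history.append(loss_g)
        state.recon_history.append(float((mbk * (xb - x_hat) ** 2).mean()))

    results = [apply_ugan(state, r, rng) for r in records]
    return state, results


def apply_ugan(state: UganState, record, rng=None) -> ImputationResult:
    """Run the trained generator over one record's timesteps."""
    if rng is None:
        rng = np.random.default_rng(state.config.seed)
    x = record.values.T
    m = record.mask.T
    z = sample_noise(x.shape, state.config, rng)
    x_hat = generate(state, x, m, z)
    merged = merge_observed(x, m, x_hat)
    u = compute_uncertainty(x, m, x_hat)
    return ImputationResult(ddm=x_hat.T, merged=merged.T, uncertainty=u)
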
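"""Stage 2: recurrent correction of the adversarial fill via time decay.

The corrector walks each record in time order.  At every step it holds a
hidden summary of the history, regresses a history-based estimate from it,
and blends that estimate with the stage-1 fill through a decay factor
``v = exp(-max(0, W u + b))`` driven by the stage-1 uncertainty score ``u``:
a confidently generated fill (small ``u``) keeps ``v`` near 1 and is
trusted, an uncertain fill is shaded toward the history regression.
Observed cells always pass through untouched in the completed output.
Training minimizes the mean absolute error of the blended estimate against
the observed cells.

The fill stream entering the blend is the stage-1 *raw estimate* matrix
(the generator's estimate for every cell, observed or not), not the
observed-merged fill.  At observed cells the merged fill equals the truth
by construction, so blending it would give the loss a degenerate optimum —
trust the fill fully, learn nothing; with raw estimates both the fill and
the history regression are fallible predictors at observed cells and the
decay factor learns a genuine reliability trade-off that then transfers to
the missing cells.

Two recurrences are available: the default gated cell (update and reset
gates, as in GRU-family decay cells) and a literal single-squash recurrence
``h_t = tanh(W_h h_hat + P_h [x_c, m] + b_h)`` selected by
``literal_eq12=True``.

The module is written against NumPy with an explicit backward pass
(truncated nowhere: full-length backpropagation through time); gradient
correctness is pinned down by finite-difference tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, dsigmoid, dtanh, glorot, sigmoid, tanh

__all__ = ["GrudConfig", "GrudParams", "GrudTrace", "decay_factor",
           "regress_estimate", "combine_estimate", "complete_vector",
           "hidden_update", "mae_loss", "train_grud", "run_grud", "impute"]


@dataclass
class GrudConfig:
    """Hyperparameters of the decay corrector.

    ``hidden_size`` is the dimension of the recurrent state; ``literal_eq12``
    switches from the gated cell to the plain single-squash recurrence.
    """

    hidden_size: int = 16
    epochs: int = 1000
    learning_rate: float = 0.001
    batch_size: int = 128
    seed: int = 1024
    literal_eq12: bool = False

    def __post_init__(self):
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")


class GrudParams:
    """Trainable arrays of the decay corrector.

    Two independent decay heads of the same exponential-relu form map the
    scalar uncertainty to a length-``d`` input decay and a length-``H``
    hidden decay.  The regression head maps the (decayed) hidden state to a
    length-``d`` history estimate.  The recurrence consumes the completed
    vector concatenated with its mask (length ``2d``).
    """

    RECURRENT = ("Wh", "Ph", "bh", "Wz", "Pz", "bz", "Wg", "Pg", "bg")

    def __init__(self, rng: np.random.Generator, d: int, hidden: int):
        H = hidden
        self.d, self.H = d, H
        # Decay heads: positive slope at init so larger uncertainty decays
        # more, and a small positive bias so the blend starts strictly inside
        # (0, 1) and both the fill path and the regression path receive
        # gradient from the first step.
        self.Wux = np.abs(rng.normal(0.0, 0.1, size=d))
        self.bux = np.full(d, 0.1)
        self.Wuh = np.abs(rng.normal(0.0, 0.1, size=H))
        self.buh = np.full(H, 0.1)
        self.Wr = glorot(rng, H, d)
        self.br = np.zeros(d)
        self.Wh = glorot(rng, H, H)
        self.Ph = glorot(rng, 2 * d, H)
        self.bh = np.zeros(H)
        self.Wz = glorot(rng, H, H)
        self.Pz = glorot(rng, 2 * d, H)
        self.bz = np.zeros(H)
        self.Wg = glorot(rng, H, H)
        self.Pg = glorot(rng, 2 * d, H)
        self.bg = np.zeros(H)
        self.names = ["Wux", "bux", "Wuh", "buh", "Wr", "br"] + list(self.RECURRENT)
        self.grads = {k: np.zeros_like(getattr(self, k)) for k in self.names}

    def zero_grads(self):
        for g in self.grads.values():
            g.fill(0.0)

    def adam_pairs(self):
        return [(getattr(self, k), self.grads[k]) for k in self.names]


@dataclass
class GrudTrace:
    """Per-timestep internals of one record's pass (normalized scale)."""

    v_input: np.ndarray    # (n, d) input decay factors, each in (0, 1]
    v_hidden: np.ndarray   # (n, H) hidden decay factors
    x_reg: np.ndarray      # (n, d) history regression estimates
    combined: np.ndarray   # (n, d) decay-blended estimates c_t
    completed: np.ndarray  # (n, d) observed-overwritten output x_t^c
    hidden: np.ndarray     # (n, H) hidden states


# ---------------------------------------------------------------------------
# elementary operations (the public per-step contract)

def decay_factor(u, W, b):
    """``exp(-max(0, W u + b))`` element-wise; every entry lies in (0, 1]."""
    u = np.asarray(u, dtype=float)
    s = np.maximum(0.0, u[..., None] * W + b) if u.ndim else np.maximum(0.0, W * u + b)
    return np.exp(-s)


def regress_estimate(h_hat, Wr, br):
    """Affine history regression ``W_r h_hat + b_r``."""
    h_hat = np.asarray(h_hat, dtype=float)
    return h_hat @ Wr.T + br


def combine_estimate(v, x_bar, x_reg):
    """Element-wise convex combination ``v * x_bar + (1 - v) * x_reg``."""
    return v * x_bar + (1.0 - v) * x_reg


def complete_vector(m, x, c):
    """Keep observed values, insert estimates at missing cells."""
    return m * x + (1.0 - m) * c


def hidden_update(h_prev, vh_prev, x_c, m, params: GrudParams,
                  config: GrudConfig):
    """One recurrence step on a batch; returns the new hidden state.

    The previous hidden state is decayed first (``h_hat = vh_prev * h_prev``),
    then fed to either the gated or the literal cell together with the
    concatenated ``[x_c, m]`` input.
    """
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    vh_prev = np.atleast_2d(np.asarray(vh_prev, dtype=float))
    x_c = np.atleast_2d(np.asarray(x_c, dtype=float))
    m = np.atleast_2d(np.asarray(m, dtype=float))
    h_hat = vh_prev * h_prev
    inp = np.concatenate([x_c, m], axis=1)
    if config.literal_eq12:
        return tanh(h_hat @ params.Wh.T + inp @ params.Ph.T + params.bh)
    z = sigmoid(h_hat @ params.Wz.T + inp @ params.Pz.T + params.bz)
    r = sigmoid(h_hat @ params.Wg.T + inp @ params.Pg.T + params.bg)
    h_tilde = tanh((r * h_hat) @ params.Wh.T + inp @ params.Ph.T + params.bh)
    return (1.0 - z) * h_hat + z * h_tilde


def mae_loss(x, m, c):
    """Mean absolute error of the estimates over observed cells only."""
    x, m, c = (np.asarray(a, dtype=float) for a in (x, m, c))
    n_obs = m.sum()
    if n_obs == 0:
        return 0.0
    return float((m * np.abs(x - c)).sum() / n_obs)


# ---------------------------------------------------------------------------
# batched forward/backward over full-length sequences

def _forward(params, config, X, M, XBAR, U, want_trace=False):
    """Forward pass over a batch of equal-length records.

    X, M, XBAR: (B, n, d); U: (B, n).  Returns (loss, caches) where caches
    feed :func:`_backward`, or per-record traces when ``want_trace``.
    """
    B, n, d = X.shape
    H = params.H
    h = np.zeros((B, H))
    vh = np.ones((B, H))
    sh = None                     # pre-relu of the hidden decay at t-1
    caches = []
    total_abs = 0.0
    n_obs = max(M.sum(), 1.0)
    for t in range(n):
        u_t = U[:, t][:, None]
        vh_prev, sh_prev, h_prev = vh, sh, h
        h_hat = vh_prev * h_prev
        x_reg = h_hat @ params.Wr.T + params.br
        sx = u_t * params.Wux + params.bux
        vx = np.exp(-np.maximum(0.0, sx))
        c = vx * XBAR[:, t] + (1.0 - vx) * x_reg
        xc = M[:, t] * X[:, t] + (1.0 - M[:, t]) * c
        inp = np.concatenate([xc, M[:, t]], axis=1)
        if config.literal_eq12:
            h = tanh(h_hat @ params.Wh.T + inp @ params.Ph.T + params.bh)
            gate = None
        else:
            z = sigmoid(h_hat @ params.Wz.T + inp @ params.Pz.T + params.bz)
            r = sigmoid(h_hat @ params.Wg.T + inp @ params.Pg.T + params.bg)
            h_tilde = tanh((r * h_hat) @ params.Wh.T + inp @ params.Ph.T
                           + params.bh)
            h = (1.0 - z) * h_hat + z * h_tilde
            gate = (z, r, h_tilde)
        # hidden decay produced at t, consumed at t+1
        sh = u_t * params.Wuh + params.buh
        vh = np.exp(-np.maximum(0.0, sh))
        total_abs += (M[:, t] * np.abs(X[:, t] - c)).sum()
        caches.append(dict(u=u_t, vh_prev=vh_prev, sh_prev=sh_prev,
                           h_prev=h_prev, h_hat=h_hat, x_reg=x_reg, sx=sx,
                           vx=vx, c=c, inp=inp, gate=gate, h=h, vh=vh, sh=sh))
    loss = total_abs / n_obs
    if want_trace:
        return loss, caches
    return loss, caches


def _backward(params, config, X, M, XBAR, caches):
    """Analytic gradients of the observed-cell MAE; fills ``params.grads``."""
    B, n, d = X.shape
    g = params.grads
    params.zero_grads()
    n_obs = max(M.sum(), 1.0)
    dh = np.zeros((B, params.H))
    dvh_next = np.zeros((B, params.H))   # grad w.r.t. vh produced at step t
    for t in range(n - 1, -1, -1):
        cc = caches[t]
        # decay head producing vh at t (consumed at t+1)
        if t < n - 1:
            # relu subgradient at 0 taken as 1 so a decay head sitting exactly
            # at the hinge (u = 0 with zero bias) stays trainable
            dsh = -cc["vh"] * dvh_next * (cc["sh"] >= 0)
            g["Wuh"] += (dsh * cc["u"]).sum(axis=0)
            g["buh"] += dsh.sum(axis=0)
        # recurrence
        h_hat, inp = cc["h_hat"], cc["inp"]
        if config.literal_eq12:
            dah = dh * dtanh(cc["h"])
            g["Wh"] += dah.T @ h_hat
            g["Ph"] += dah.T @ inp
            g["bh"] += dah.sum(axis=0)
            dh_hat = dah @ params.Wh
            dinp = dah @ params.Ph
        else:
            z, r, h_tilde = cc["gate"]
            daz = dh * (h_tilde - h_hat) * dsigmoid(z)
            dhtil = dh * z
            dah = dhtil * dtanh(h_tilde)
            dh_hat = dh * (1.0 - z)
            g["Wh"] += dah.T @ (r * h_hat)
            drh = dah @ params.Wh
            dar = drh * h_hat * dsigmoid(r)
            dh_hat += drh * r
            g["Ph"] += dah.T @ inp
            g["bh"] += dah.sum(axis=0)
            dinp = dah @ params.Ph
            g["Wz"] += daz.T @ h_hat
            g["Pz"] += daz.T @ inp
            g["bz"] += daz.sum(axis=0)
            dh_hat += daz @ params.Wz
            dinp += daz @ params.Pz
            g["Wg"] += dar.T @ h_hat
            g["Pg"] += dar.T @ inp
            g["bg"] += dar.sum(axis=0)
            dh_hat += dar @ params.Wg
            dinp += dar @ params.Pg
        # blended estimate: loss term + completed-vector feed into the input
        dc = M[:, t] * np.sign(cc["c"] - X[:, t]) / n_obs
        dc += dinp[:, :d] * (1.0 - M[:, t])
        dvx = dc * (XBAR[:, t] - cc["x_reg"])
        dx_reg = dc * (1.0 - cc["vx"])
        dsx = -cc["vx"] * dvx * (cc["sx"] >= 0)
        g["Wux"] += (dsx * cc["u"]).sum(axis=0)
        g["bux"] += dsx.sum(axis=0)
        g["Wr"] += dx_reg.T @ h_hat
        g["br"] += dx_reg.sum(axis=0)
        dh_hat += dx_reg @ params.Wr
        # through the decayed hidden state to the previous step
        dvh_next = dh_hat * cc["h_prev"]
        dh = dh_hat * cc["vh_prev"]
        if t == 0:
            break  # vh_prev at t=0 is the constant 1 (no decay before history)


def train_grud(records, stage1, config: GrudConfig,
               params: GrudParams | None = None):
    """Fit the corrector on stage-1 outputs by Adam on observed-cell MAE.

    Parameters
    ----------
    records : list of MaskedSeries
        Normalized records (placeholder 0 at missing cells).
    stage1 : list of ImputationResult
        Matching stage-1 fills and uncertainty streams.
    config : GrudConfig
    params : GrudParams, optional
        Warm-start parameters (used by ablation runs that share one
        initialization); freshly initialized from the seed when omitted.

    Returns the trained :class:`GrudParams` and the loss history.
    """
    usable = [(r, s) for r, s in zip(records, stage1) if r.n_steps >= 2]
    if len(usable) < len(records):
        warnings.warn(f"skipped {len(records) - len(usable)} record(s) "
                      "shorter than 2 timesteps")
    if not usable:
        raise ValueError("no trainable records (all shorter than 2 steps)")
    d = usable[0][0].n_features
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = GrudParams(rng, d, config.hidden_size)
    opt = Adam(params.adam_pairs(), lr=config.learning_rate)

    # group equal-length records so each group trains as one dense batch
    groups: dict[int, list] = {}
    for r, s in usable:
        groups.setdefault(r.n_steps, []).append((r, s))
    batches = []
    for n, members in sorted(groups.items()):
        X = np.stack([r.values.T for r, _ in members])
        M = np.stack([r.mask.T for r, _ in members])
        XFILL = np.stack([s.ddm.T for _, s in members])
        U = np.stack([s.uncertainty for _, s in members])
        batches.append((X, M, XFILL, U))

    history = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        for X, M, XBAR, U in batches:
            loss, caches = _forward(params, config, X, M, XBAR, U)
            _backward(params, config, X, M, XBAR, caches)
            opt.step()
            epoch_loss += loss * M.sum()
        total_obs = sum(M.sum() for _, M, _, _ in batches)
        history.append(epoch_loss / max(total_obs, 1.0))
        if not np.isfinite(history[-1]):
            raise FloatingPointError("non-finite corrector loss")
    return params, history


def run_grud(record, stage1_result, params: GrudParams,
             config: GrudConfig) -> GrudTrace:
    """Trace one record through the trained corrector (normalized scale)."""
    X = record.values.T[None]
    M = record.mask.T[None]
    XBAR = stage1_result.ddm.T[None]
    U = stage1_result.uncertainty[None]
    _, caches = _forward(params, config, X, M, XBAR, U, want_trace=True)
    n = record.n_steps
    v_in = np.stack([caches[t]["vx"][0] for t in range(n)])
    v_hid = np.stack([caches[t]["vh_prev"][0] for t in range(n)])
    x_reg = np.stack([caches[t]["x_reg"][0] for t in range(n)])
    comb = np.stack([caches[t]["c"][0] for t in range(n)])
    hidden = np.stack([caches[t]["h"][0] for t in range(n)])
    completed = record.mask.T * record.values.T + (1.0 - record.mask.T) * comb
    return GrudTrace(v_input=v_in, v_hidden=v_hid, x_reg=x_reg,
                     combined=comb, completed=completed, hidden=hidden)


def impute(record, stage1_result, params: GrudParams, config: GrudConfig,
           norm_state=None) -> np.ndarray:
    """Complete one record; observed cells pass through untouched.

    Returns the dense ``d x n`` matrix, de-normalized when a normalization
    state is supplied.
    """
    trace = run_grud(record, stage1_result, params, config)
    out = trace.completed.T
    if norm_state is not None:
        out = norm_state.inverse(out)
        obs = record.mask == 1.0
        original = norm_state.inverse(record.values)
        out[obs] = original[obs]
    return out
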
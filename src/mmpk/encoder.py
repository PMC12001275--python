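"""Amortized-inference encoders: patient data -> Gaussian posterior over random effects.

Two drug-specific variants share the same contract: they emit a mean and a
log-variance per IIV parameter (``PosteriorStats``), so posterior variances
are strictly positive by construction.

* 5FU: each steady-state measurement is its own sample; a feed-forward
  network reads ``[concentration, dose, weight, LBM, FM, BSA, age, sex,
  height]`` plus a binary missing mask and emits stats for K = {CL}.
* Sunitinib: a static-covariate block and a time-gated LSTM over the
  (delta-t, parent, metabolite) sequence are concatenated and projected by
  two subnetworks of |K| = 4 outputs each (K = {CLS, V2S, FM, V2M}).

Missing covariates use mask-concatenation: inputs are standardized with
statistics computed on training data only, missing slots are zero-filled
after normalization, and the mask itself is appended as features.  The
value stored in a masked-out slot therefore never influences the output.

The time-gated recurrent cell multiplies the carried cell state by
``T = exp(-softplus(w) * delta_t)`` before the standard LSTM update, so at
``delta_t = 0`` the gate is exactly neutral and the plain LSTM is
recovered; larger gaps discount older memory more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from mmpk.autodiff import Tensor, Parameter, concat, as_tensor

FU5_FEATURES = ("concentration", "dose", "weight", "lbm", "fm", "bsa",
                "age", "sex", "height")
FU5_IIV = ("CL",)
SUNITINIB_IIV = ("CLS", "V2S", "FM", "V2M")


@dataclass
class PosteriorStats:
    names: tuple
    mu: np.ndarray        # (..., |K|)
    log_var: np.ndarray   # (..., |K|)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.log_var = np.asarray(self.log_var, dtype=float)
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.log_var))):
            raise ValueError("posterior statistics must be finite")

    @property
    def sigma2(self):
        return np.exp(self.log_var)


@dataclass
class EncoderConfig:
    static_hidden: tuple = (64, 64)
    recurrent_hidden: int = 64
    projection_hidden: int = 64
    dropout: float = 0.1
    time_mode: str = "time_gate"    # "time_gate" | "delta_feature"

    def to_dict(self):
        d = asdict(self)
        d["static_hidden"] = list(self.static_hidden)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["static_hidden"] = tuple(d["static_hidden"])
        return cls(**d)


class InputNormalizer:
    """Per-feature standardization fitted on training data only."""

    def __init__(self, mean=None, scale=None):
        self.mean = mean
        self.scale = scale

    def fit(self, values, mask=None):
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.ones_like(values)
        mask = np.asarray(mask, dtype=float)
        n = np.maximum(mask.sum(axis=0), 1.0)
        mean = (values * mask).sum(axis=0) / n
        var = (((values - mean) ** 2) * mask).sum(axis=0) / n
        scale = np.sqrt(var)
        scale[scale < 1e-8] = 1.0
        self.mean, self.scale = mean, scale
        return self

    def transform(self, values, mask=None):
        """Standardize, zero-fill missing slots, append the mask."""
        if self.mean is None:
            raise RuntimeError("normalizer must be fitted on training data first")
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if mask is None:
            mask = np.ones_like(values)
        mask = np.atleast_2d(np.asarray(mask, dtype=float))
        z = (values - self.mean) / self.scale
        z = z * mask
        return np.concatenate([z, mask], axis=-1)

    def to_dict(self):
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["mean"]), np.asarray(d["scale"]))


def _glorot(rng, n_in, n_out):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


class _MLP:
    def __init__(self, rng, sizes, name, out_bias=0.0):
        self.name = name
        self.weights, self.biases = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            self.weights.append(Parameter(_glorot(rng, a, b)))
            self.biases.append(Parameter(np.zeros(b)))
        # e.g. log-variance heads start below the prior variance
        self.biases[-1].data += out_bias

    def __call__(self, x, dropout=0.0, rng=None):
        h = as_tensor(x)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = h.silu()
                if dropout > 0.0 and rng is not None:
                    keep = (rng.random(h.data.shape) >= dropout) / (1.0 - dropout)
                    h = h * keep
        return h

    def parameters(self):
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"{self.name}.W{i}"] = w
            out[f"{self.name}.b{i}"] = b
        return out

    def state(self):
        return [(w.data.tolist(), b.data.tolist())
                for w, b in zip(self.weights, self.biases)]

    def load_state(self, state):
        for (wd, bd), w, b in zip(state, self.weights, self.biases):
            w.data = np.asarray(wd, dtype=float)
            b.data = np.asarray(bd, dtype=float)


class TimeLSTMCell:
    """LSTM cell with a multiplicative elapsed-time gate on the carried memory."""

    def __init__(self, rng, n_in, n_hidden, time_mode="time_gate"):
        self.n_in, self.n_hidden, self.time_mode = n_in, n_hidden, time_mode
        n_x = n_in + (1 if time_mode == "delta_feature" else 0)
        self.w_x = Parameter(_glorot(rng, n_x, 4 * n_hidden))
        self.w_h = Parameter(_glorot(rng, n_hidden, 4 * n_hidden))
        self.b = Parameter(np.zeros(4 * n_hidden))
        # decay rates per hidden unit; softplus keeps them positive
        self.w_decay = Parameter(np.full(n_hidden, -1.0))

    def step(self, h, c, x, delta_t):
        """One recurrent update; ``delta_t`` is the elapsed time (>= 0)."""
        if delta_t < 0:
            raise ValueError("delta_t must be nonnegative")
        x = as_tensor(x)
        if self.time_mode == "delta_feature":
            x = concat([x, Tensor(np.array([delta_t]))], axis=0)
        else:
            decay = (self.w_decay.softplus() * (-float(delta_t))).exp()
            c = c * decay
        gates = x @ self.w_x + h @ self.w_h + self.b
        nh = self.n_hidden
        i = gates[0:nh].sigmoid()
        f = gates[nh:2 * nh].sigmoid()
        g = gates[2 * nh:3 * nh].tanh()
        o = gates[3 * nh:4 * nh].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def run(self, xs, dts):
        h = Tensor(np.zeros(self.n_hidden))
        c = Tensor(np.zeros(self.n_hidden))
        for x, dt in zip(xs, dts):
            h, c = self.step(h, c, x, dt)
        return h

    def parameters(self):
        return {"lstm.w_x": self.w_x, "lstm.w_h": self.w_h,
                "lstm.b": self.b, "lstm.w_decay": self.w_decay}

    def state(self):
        return {k: p.data.tolist() for k, p in self.parameters().items()}

    def load_state(self, state):
        for k, p in self.parameters().items():
            p.data = np.asarray(state[k], dtype=float)


def time_recurrent_update(cell, hidden, input_values, delta_t):
    """Functional wrapper around one time-gated recurrent step."""
    h, c = hidden
    return cell.step(h, c, input_values, delta_t)


class Encoder5FU:
    """Per-measurement encoder for the 5FU cohort; K = {CL}."""

    n_features = len(FU5_FEATURES)

    def __init__(self, config=None, seed=0):
        self.config = config or EncoderConfig()
        self.names = FU5_IIV
        rng = np.random.default_rng(seed)
        n_in = 2 * self.n_features            # features + mask
        sizes = [n_in, *self.config.static_hidden]
        self.trunk = _MLP(rng, sizes, "trunk")
        ph = self.config.projection_hidden
        self.head_mu = _MLP(rng, [sizes[-1], ph, len(self.names)], "head_mu")
        self.head_lv = _MLP(rng, [sizes[-1], ph, len(self.names)], "head_lv",
                            out_bias=-2.0)
        self.normalizer = InputNormalizer()

    def fit_normalizer(self, values, mask=None):
        self.normalizer.fit(values, mask)
        return self

    def forward(self, values, mask=None, train=False, rng=None):
        """Tensor-valued (mu, log_var), each (B, |K|); used by the training loop."""
        x = self.normalizer.transform(values, mask)
        p = self.config.dropout if train else 0.0
        h = self.trunk(Tensor(x), dropout=p, rng=rng).silu()
        return self.head_mu(h, dropout=p, rng=rng), self.head_lv(h, dropout=p, rng=rng)

    def encode(self, values, mask=None):
        mu, lv = self.forward(values, mask, train=False)
        return PosteriorStats(self.names, mu.data, lv.data)

    def parameters(self):
        out = {}
        for blk in (self.trunk, self.head_mu, self.head_lv):
            out.update(blk.parameters())
        return out

    # -- checkpointing ------------------------------------------------------
    def to_dict(self):
        return {"kind": "fu5", "config": self.config.to_dict(),
                "normalizer": self.normalizer.to_dict(),
                "trunk": self.trunk.state(), "head_mu": self.head_mu.state(),
                "head_lv": self.head_lv.state()}

    @classmethod
    def from_dict(cls, d):
        enc = cls(EncoderConfig.from_dict(d["config"]))
        enc.normalizer = InputNormalizer.from_dict(d["normalizer"])
        enc.trunk.load_state(d["trunk"])
        enc.head_mu.load_state(d["head_mu"])
        enc.head_lv.load_state(d["head_lv"])
        return enc


class EncoderSunitinib:
    """Multimodal encoder: static covariates + time-gated LSTM over the
    (delta-t, parent, metabolite) sequence; K = {CLS, V2S, FM, V2M}."""

    n_static = 7          # sex, age, weight, height, bsa, lbm, fm (mask appended)
    n_seq = 2             # parent, metabolite concentrations

    def __init__(self, config=None, seed=0):
        self.config = config or EncoderConfig()
        self.names = SUNITINIB_IIV
        rng = np.random.default_rng(seed)
        sizes = [2 * self.n_static, *self.config.static_hidden]
        self.static_block = _MLP(rng, sizes, "static")
        self.lstm = TimeLSTMCell(rng, self.n_seq, self.config.recurrent_hidden,
                                 self.config.time_mode)
        joint = sizes[-1] + self.config.recurrent_hidden
        ph = self.config.projection_hidden
        self.head_mu = _MLP(rng, [joint, ph, len(self.names)], "head_mu")
        self.head_lv = _MLP(rng, [joint, ph, len(self.names)], "head_lv",
                            out_bias=-2.0)
        self.static_norm = InputNormalizer()
        self.seq_norm = InputNormalizer()
        self.dt_scale = 1.0

    def fit_normalizers(self, static_values, static_mask, seq_values, delta_ts):
        self.static_norm.fit(static_values, static_mask)
        self.seq_norm.fit(np.asarray(seq_values, dtype=float))
        dts = np.asarray(delta_ts, dtype=float)
        self.dt_scale = float(dts.mean()) if dts.size and dts.mean() > 0 else 1.0
        return self

    def forward(self, static_values, static_mask, seq_values, seq_times,
                train=False, rng=None):
        """(mu, log_var) tensors of shape (|K|,) for one patient sequence."""
        seq_values = np.atleast_2d(np.asarray(seq_values, dtype=float))
        seq_times = np.asarray(seq_times, dtype=float)
        if seq_values.shape[0] == 0:
            raise ValueError("sequence must contain at least one element")
        if np.any(np.diff(seq_times) < 0):
            raise ValueError("sequence times must be sorted")
        p = self.config.dropout if train else 0.0
        xs = self.static_norm.transform(static_values, static_mask)[0]
        s = self.static_block(Tensor(xs), dropout=p, rng=rng).silu()
        zs = self.seq_norm.transform(seq_values)[:, :self.n_seq]
        dts = np.diff(seq_times, prepend=seq_times[0]) / self.dt_scale
        h = self.lstm.run([Tensor(z) for z in zs], dts)
        joint = concat([s, h], axis=0)
        return (self.head_mu(joint, dropout=p, rng=rng),
                self.head_lv(joint, dropout=p, rng=rng))

    def encode(self, static_values, static_mask, seq_values, seq_times):
        mu, lv = self.forward(static_values, static_mask, seq_values, seq_times)
        return PosteriorStats(self.names, mu.data, lv.data)

    def parameters(self):
        out = {}
        for blk in (self.static_block, self.head_mu, self.head_lv):
            out.update(blk.parameters())
        out.update(self.lstm.parameters())
        return out

    # -- checkpointing ------------------------------------------------------
    def to_dict(self):
        return {"kind": "sunitinib", "config": self.config.to_dict(),
                "static_norm": self.static_norm.to_dict(),
                "seq_norm": self.seq_norm.to_dict(), "dt_scale": self.dt_scale,
                "static": self.static_block.state(), "lstm": self.lstm.state(),
                "head_mu": self.head_mu.state(), "head_lv": self.head_lv.state()}

    @classmethod
    def from_dict(cls, d):
        enc = cls(EncoderConfig.from_dict(d["config"]))
        enc.static_norm = InputNormalizer.from_dict(d["static_norm"])
        enc.seq_norm = InputNormalizer.from_dict(d["seq_norm"])
        enc.dt_scale = d["dt_scale"]
        enc.static_block.load_state(d["static"])
        enc.lstm.load_state(d["lstm"])
        enc.head_mu.load_state(d["head_mu"])
        enc.head_lv.load_state(d["head_lv"])
        return enc


def save_encoder(encoder, path):
    with open(path, "w") as fh:
        json.dump(encoder.to_dict(), fh)


def load_encoder(path):
    with open(path) as fh:
        d = json.load(fh)
    if d["kind"] == "fu5":
        return Encoder5FU.from_dict(d)
    return EncoderSunitinib.from_dict(d)
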
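"""Generative attention-network designer trained by statistics matching.

The model maps an allotype's evolutionary statistics — the site-frequency
vector (flattened to length L*A) and the joint-frequency matrix (reshaped to
(L*A) x (L*A)) — to per-position residue probabilities ``P[i, a]``. Training
matches the model's implied statistics to the native ones:

* ``loss1``: mean squared error on joint frequencies only (L1 designs);
* ``loss2``: frequency MSE + lambda * loss1 (L2 designs).

Because designed sequences are sampled independently per position, the
model-implied joint frequencies are the product-of-marginals surrogate
``P[i,a] * P[j,b]`` for i != j, with ``delta_ab * P[i,a]`` on the diagonal
blocks — the unique construction consistent with independent sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..evostats import FrequencyProfile, JointFrequencyTensor
from ..peptide_io import ALPHABET, PeptideAlignment, decode_alignment
from .autodiff import Adam, Tensor, concat, conv1d, conv2d, softmax


@dataclass
class DesignModelConfig:
    L: int = 9
    alphabet_size: int = 20
    n_blocks: int = 12
    n_heads: int = 4
    model_dim: int = 128
    conv1d_channels: int = 16
    conv2d_channels: int = 8
    kernel: int = 3
    head_kernel: int = 3
    ff_mult: int = 4
    logit_scale: float = 20.0
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.model_dim % self.n_heads:
            raise ValueError("model_dim must be divisible by n_heads")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @property
    def key_dim(self) -> int:
        return self.model_dim // self.n_heads

    @property
    def n_tokens(self) -> int:
        return self.L * self.alphabet_size

    @classmethod
    def reduced(cls, L: int = 9, **kw) -> "DesignModelConfig":
        """Small CPU-friendly preset used by the test suite."""
        kw.setdefault("n_blocks", 2)
        kw.setdefault("model_dim", 64)
        kw.setdefault("conv1d_channels", 8)
        kw.setdefault("conv2d_channels", 4)
        return cls(L=L, **kw)


@dataclass
class TrainingConfig:
    loss_kind: str = "loss2"      # {loss1, loss2}
    lam: float = 65.0
    learning_rate: float = 1e-4
    epochs: int = 2000
    batch_size: int | None = None  # None: all allotypes per step
    seed: int = 0
    n_repeats: int = 1
    plateau_tol: float = 0.0       # >0 enables plateau early stop
    plateau_window: int = 100

    def __post_init__(self) -> None:
        if self.loss_kind not in ("loss1", "loss2"):
            raise ValueError(f"unknown loss_kind {self.loss_kind!r}")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainingHistory:
    total: np.ndarray
    freq_term: np.ndarray
    joint_term: np.ndarray

    @property
    def epochs(self) -> int:
        return len(self.total)


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def featurize(fp: FrequencyProfile, jf: JointFrequencyTensor) -> tuple[np.ndarray, np.ndarray]:
    """Flatten statistics into model inputs: F of shape (L*A,), T of shape
    (L*A, L*A). Row-major over (position, residue), matching the fixed
    alphabet ordering."""
    if jf.fj.shape != (fp.L, fp.A, fp.L, fp.A):
        raise ValueError("profile / joint tensor shape mismatch")
    n = fp.L * fp.A
    return fp.f.reshape(n).copy(), jf.fj.reshape(n, n).copy()


def unfeaturize(F: np.ndarray, T: np.ndarray, L: int, A: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`featurize` (returns raw arrays)."""
    return F.reshape(L, A).copy(), T.reshape(L, A, L, A).copy()


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _xavier(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in = shape[-2] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=shape)


class DesignModel:
    """Conv featurizer + pre-norm attention stack + convolutional softmax head."""

    def __init__(self, cfg: DesignModelConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d, c1, c2, k = cfg.model_dim, cfg.conv1d_channels, cfg.conv2d_channels, cfg.kernel
        dk, H = cfg.key_dim, cfg.n_heads
        P: dict[str, Tensor] = {}

        def param(name: str, data: np.ndarray) -> Tensor:
            t = Tensor(data, requires_grad=True)
            P[name] = t
            return t

        param("conv1_w", _xavier(rng, c1, 1, k) * np.sqrt(k))
        param("conv1_b", np.zeros(c1))
        param("conv2_w", _xavier(rng, c2, 1, k, k))
        param("conv2_b", np.zeros(c2))
        param("proj_w", _xavier(rng, c1 + c2, d))
        param("proj_b", np.zeros(d))
        for blk in range(cfg.n_blocks):
            p = f"b{blk}_"
            param(p + "ln1_g", np.ones(d))
            param(p + "ln1_b", np.zeros(d))
            for h in range(H):
                param(p + f"wq{h}", _xavier(rng, d, dk))
                param(p + f"wk{h}", _xavier(rng, d, dk))
                param(p + f"wv{h}", _xavier(rng, d, dk))
            param(p + "wo", _xavier(rng, d, d))
            param(p + "bo", np.zeros(d))
            param(p + "ln2_g", np.ones(d))
            param(p + "ln2_b", np.zeros(d))
            param(p + "ff1_w", _xavier(rng, d, cfg.ff_mult * d))
            param(p + "ff1_b", np.zeros(cfg.ff_mult * d))
            param(p + "ff2_w", _xavier(rng, cfg.ff_mult * d, d))
            param(p + "ff2_b", np.zeros(d))
        param("lnf_g", np.ones(d))
        param("lnf_b", np.zeros(d))
        param("head_w", _xavier(rng, 1, d, cfg.head_kernel) * 0.1)
        param("head_b", np.zeros(1))
        self.params = P

        # constant masks for the joint-frequency surrogate
        n, L, A = cfg.n_tokens, cfg.L, cfg.alphabet_size
        block = np.ones((n, n))
        for i in range(L):
            block[i * A:(i + 1) * A, i * A:(i + 1) * A] = 0.0
        self._offblock = Tensor(block)
        self._eye = Tensor(np.eye(n))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward ------------------------------------------------------------

    @staticmethod
    def _layernorm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-6) -> Tensor:
        m = x.mean(axis=1, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=1, keepdims=True)
        return xc * (v + eps) ** -0.5 * g + b

    def forward(self, F: np.ndarray, T: np.ndarray) -> Tensor:
        """Map inputs to the (L, A) output-probability Tensor (rows sum to 1)."""
        cfg = self.cfg
        n = cfg.n_tokens
        if F.shape != (n,) or T.shape != (n, n):
            raise ValueError("input shapes do not match the model configuration")
        P = self.params
        f_feat = conv1d(Tensor(F.reshape(1, n)), P["conv1_w"], P["conv1_b"]).gelu()
        t_feat = conv2d(Tensor(T.reshape(1, n, n)), P["conv2_w"], P["conv2_b"]).gelu()
        t_feat = t_feat.mean(axis=2)                    # (c2, n)
        Z = concat([f_feat.T, t_feat.T], axis=1)        # (n, c1 + c2)
        X = Z @ P["proj_w"] + P["proj_b"]

        scale = 1.0 / np.sqrt(cfg.key_dim)
        for blk in range(cfg.n_blocks):
            p = f"b{blk}_"
            Xn = self._layernorm(X, P[p + "ln1_g"], P[p + "ln1_b"])
            heads = []
            for h in range(cfg.n_heads):
                q = Xn @ P[p + f"wq{h}"]
                k = Xn @ P[p + f"wk{h}"]
                v = Xn @ P[p + f"wv{h}"]
                att = softmax(q @ k.T * scale, axis=-1)
                heads.append(att @ v)
            X = X + concat(heads, axis=1) @ P[p + "wo"] + P[p + "bo"]
            Xn = self._layernorm(X, P[p + "ln2_g"], P[p + "ln2_b"])
            X = X + (Xn @ P[p + "ff1_w"] + P[p + "ff1_b"]).gelu() @ P[p + "ff2_w"] \
                + P[p + "ff2_b"]

        Y = self._layernorm(X, P["lnf_g"], P["lnf_b"])
        logits = conv1d(Y.T, P["head_w"], P["head_b"])          # (1, n)
        logits = logits.reshape(cfg.L, cfg.alphabet_size) * cfg.logit_scale
        return softmax(logits, axis=-1)

    def output_distribution(self, F: np.ndarray, T: np.ndarray) -> np.ndarray:
        """Deterministic inference: the (L, A) probability matrix as numpy."""
        return self.forward(F, T).data.copy()

    def predicted_joint(self, Pout: Tensor) -> Tensor:
        """Differentiable surrogate joint frequencies, shape (n, n)."""
        n = self.cfg.n_tokens
        pf = Pout.reshape(n, 1)
        outer = pf @ pf.reshape(1, n)
        return outer * self._offblock + self._eye * pf.reshape(1, n)


def predicted_statistics(Pout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Numpy counterpart of the surrogate: (f_hat (L,A), joint_hat (L,A,L,A))."""
    L, A = Pout.shape
    fj = np.einsum("ia,jb->iajb", Pout, Pout)
    idx, ar = np.arange(L), np.arange(A)
    fj[idx[:, None], :, idx[:, None], :] = 0.0
    fj[idx[:, None], ar[None, :], idx[:, None], ar[None, :]] = Pout
    return Pout.copy(), fj


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def loss1_terms(pred_joint: Tensor, native_joint: np.ndarray) -> Tensor:
    """Per-allotype joint-frequency MSE, normalized by (L*A)^2."""
    n = pred_joint.shape[0]
    d = pred_joint - Tensor(native_joint)
    return (d * d).sum() * (1.0 / (n * n))


def freq_terms(pred: Tensor, native_freq: np.ndarray) -> Tensor:
    """Per-allotype frequency squared-error term (summed over i, a)."""
    d = pred - Tensor(native_freq)
    return (d * d).sum()


def loss1(pred_joints: list[Tensor], native_joints: list[np.ndarray]) -> Tensor:
    """Batch-mean joint-frequency MSE (the L1 training loss)."""
    B = len(pred_joints)
    total = loss1_terms(pred_joints[0], native_joints[0])
    for p, t in zip(pred_joints[1:], native_joints[1:]):
        total = total + loss1_terms(p, t)
    return total * (1.0 / B)


def loss2(
    preds: list[Tensor],
    native_freqs: list[np.ndarray],
    pred_joints: list[Tensor],
    native_joints: list[np.ndarray],
    lam: float,
) -> tuple[Tensor, Tensor, Tensor]:
    """Batch-mean frequency MSE + lambda * loss1.

    Returns (total, freq_component, joint_component) so histories can record
    the decomposition; total == freq + lam * joint up to float rounding.
    """
    B = len(preds)
    f_total = freq_terms(preds[0], native_freqs[0])
    for p, t in zip(preds[1:], native_freqs[1:]):
        f_total = f_total + freq_terms(p, t)
    f_total = f_total * (1.0 / B)
    j_total = loss1(pred_joints, native_joints)
    return f_total + j_total * lam, f_total, j_total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    stats_by_allotype: dict[str, tuple[FrequencyProfile, JointFrequencyTensor]],
    mcfg: DesignModelConfig,
    tcfg: TrainingConfig,
) -> tuple[DesignModel, TrainingHistory]:
    """Gradient training of the design network on per-allotype statistics.

    One training example is one allotype's (frequency, joint) pair; by
    default every allotype is included in each step. Deterministic for a
    fixed seed. Aborts on non-finite loss.
    """
    if not stats_by_allotype:
        raise ValueError("need at least one allotype")
    model = DesignModel(mcfg, seed=tcfg.seed)
    featurized = {
        name: featurize(fp, jf) for name, (fp, jf) in stats_by_allotype.items()
    }
    names = list(featurized)
    opt = Adam(model.parameters(), lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed + 1)
    bs = tcfg.batch_size or len(names)

    hist_total, hist_freq, hist_joint = [], [], []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(len(names)) if bs < len(names) else np.arange(len(names))
        ep_total = ep_freq = ep_joint = 0.0
        n_batches = 0
        for start in range(0, len(names), bs):
            batch = [names[i] for i in order[start:start + bs]]
            preds, pred_joints, nat_freqs, nat_joints = [], [], [], []
            for name in batch:
                F, T = featurized[name]
                Pout = model.forward(F, T)
                preds.append(Pout)
                pred_joints.append(model.predicted_joint(Pout))
                nat_freqs.append(F.reshape(mcfg.L, mcfg.alphabet_size))
                nat_joints.append(T)
            if tcfg.loss_kind == "loss1":
                jt = loss1(pred_joints, nat_joints)
                total, ft = jt, Tensor(0.0)
            else:
                total, ft, jt = loss2(
                    preds, nat_freqs, pred_joints, nat_joints, tcfg.lam
                )
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={total.data}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_total += float(total.data)
            ep_freq += float(ft.data)
            ep_joint += float(jt.data)
            n_batches += 1
        hist_total.append(ep_total / n_batches)
        hist_freq.append(ep_freq / n_batches)
        hist_joint.append(ep_joint / n_batches)
        if tcfg.plateau_tol > 0 and epoch >= tcfg.plateau_window:
            past = hist_total[-tcfg.plateau_window - 1]
            if past > 0 and abs(past - hist_total[-1]) / past < tcfg.plateau_tol:
                break

    history = TrainingHistory(
        total=np.asarray(hist_total),
        freq_term=np.asarray(hist_freq),
        joint_term=np.asarray(hist_joint),
    )
    return model, history


def train_repeated(
    stats_by_allotype,
    mcfg: DesignModelConfig,
    tcfg: TrainingConfig,
) -> list[tuple[DesignModel, TrainingHistory]]:
    """Independent repeated trainings (seeds tcfg.seed, tcfg.seed+1, ...)."""
    out = []
    for r in range(tcfg.n_repeats):
        sub = TrainingConfig(**{**tcfg.__dict__, "seed": tcfg.seed + r,
                                "n_repeats": 1})
        out.append(train(stats_by_allotype, mcfg, sub))
    return out


def design_from_model(
    model: DesignModel,
    stats: tuple[FrequencyProfile, JointFrequencyTensor],
    n: int,
    seed: int,
    allotype: str = "",
) -> PeptideAlignment:
    """Sample ``n`` sequences from the model's per-position distributions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    F, T = featurize(*stats)
    Pout = model.output_distribution(F, T)
    if Pout.shape[1] != len(ALPHABET):
        raise ValueError("design requires the 20-letter alphabet")
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(Pout, axis=1)
    u = rng.random((n, Pout.shape[0]))
    enc = (u[:, :, None] > cdf[None, :, :]).sum(axis=2)
    return decode_alignment(enc, allotype=allotype)


def save_model(model: DesignModel, path) -> None:
    """Checkpoint weights + config to an ``.npz`` container."""
    cfg = {f"cfg_{k}": v for k, v in model.cfg.__dict__.items()}
    np.savez(path, **cfg, **{k: t.data for k, t in model.params.items()})


def load_model(path) -> DesignModel:
    with np.load(path) as z:
        cfg_kw = {k[4:]: z[k].item() for k in z.files if k.startswith("cfg_")}
        cfg_kw = {k: (int(v) if isinstance(v, (np.integer, int)) else float(v))
                  for k, v in cfg_kw.items()}
        for int_key in ("L", "alphabet_size", "n_blocks", "n_heads", "model_dim",
                        "conv1d_channels", "conv2d_channels", "kernel",
                        "head_kernel", "ff_mult"):
            cfg_kw[int_key] = int(cfg_kw[int_key])
        model = DesignModel(DesignModelConfig(**cfg_kw), seed=0)
        for k, t in model.params.items():
            t.data = z[k].astype(np.float64)
    return model
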
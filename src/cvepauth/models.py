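"""Verification back-ends: the c-EEGNet deep model and the TRCA baseline.

c-EEGNet is a four-branch compact convolutional network for quadruple
samples (one sub-network per stimulus position).  Each branch applies a
temporal convolution (N1 kernels of length 60), a depthwise spatial
("channel") convolution (N2 kernels per virtual epoch) with ELU, average
pooling by N3, and a depthwise second temporal convolution (length 16);
every convolution is followed by batch normalization, and dropout follows
each pooling layer.  The combined block concatenates the four branch
outputs, reduces the merged branch x feature axis with N4 pointwise
(length-1) convolutions plus ELU, pools by N5, and classifies the flattened
vector with a softmax dense layer (genuine vs impostor).

The implementation is pure NumPy: forward, backward and the Adam update are
written out explicitly, which keeps the model dependency-light and bit-for-
bit reproducible from a seed.  The heavy temporal convolution is evaluated
as one BLAS matrix product per branch over a slice-filled column buffer.

TRCA (task-related component analysis) is the template-matching baseline:
per stimulus position it finds the spatial filter maximizing inter-trial
covariance relative to total variance (a generalized eigenproblem), builds
a filtered class-mean template, and scores a sample by the mean Pearson
correlation over the four positions; the accept threshold is calibrated to
maximize F1 on training-packet scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping

import numpy as np
import scipy.linalg

from .sampling import POSITIONS, TrainingPacket

__all__ = [
    "CEEGNetConfig",
    "TrainConfig",
    "CEEGNet",
    "TRCAModel",
    "build_ceegnet",
    "train_ceegnet",
    "authenticate_ceegnet",
    "trca_fit",
    "trca_calibrate_threshold",
    "trca_scores",
    "authenticate_trca",
    "save_model",
    "load_model",
]

logger = logging.getLogger("cvepauth.models")

MODEL_FORMAT_VERSION = 1
_EPS = 1e-5  # batch-norm epsilon


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEEGNetConfig:
    """Architecture hyperparameters.

    Defaults are the published operating point: N1=32 temporal kernels of
    length 60, N2=2 spatial kernels per virtual epoch, pooling N3=4 then
    N5=8, N4=64 pointwise kernels, second temporal kernel length 16,
    dropout 0.5, for 9-channel 262-point epochs.
    """

    n1: int = 32
    n2: int = 2
    n3: int = 4
    n4: int = 64
    n5: int = 8
    time_kernel: int = 60
    time_kernel2: int = 16
    dropout: float = 0.5
    n_channels: int = 9
    n_times: int = 262
    #: "full" merges the branch and per-branch feature axes into one
    #: 4*N1*N2 feature axis before the pointwise convolution; "branch"
    #: preserves the feature axis and combines across branches only
    #: (one 4-weight kernel per feature; requires n4 == n1*n2).
    merge_mode: Literal["full", "branch"] = "full"

    def __post_init__(self):
        for name in ("n1", "n2", "n3", "n4", "n5", "time_kernel", "time_kernel2",
                     "n_channels", "n_times"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.time_kernel > self.n_times:
            raise ValueError("time kernel longer than the input epoch")
        if self.time_kernel2 > self.pooled1:
            raise ValueError("second time kernel longer than the pooled epoch")
        if self.merge_mode == "branch" and self.n4 != self.n1 * self.n2:
            raise ValueError("merge_mode='branch' requires n4 == n1*n2")

    @property
    def pooled1(self) -> int:
        return self.n_times // self.n3

    @property
    def pooled2(self) -> int:
        return self.pooled1 // self.n5

    @property
    def n_features(self) -> int:
        """Merged feature-axis length entering the pointwise convolution."""
        return 4 * self.n1 * self.n2

    @property
    def flat_len(self) -> int:
        return self.n4 * self.pooled2


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam, cross-entropy, stratified 20% validation
    split with early stopping)."""

    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.2
    #: stop once validation loss falls below this floor (the split is
    #: effectively solved; further epochs only shave decimals off the loss)
    val_loss_floor: float = 0.01
    rng_seed: int = 0


# ---------------------------------------------------------------------------
# Small functional pieces (each returns output + backward closure state)
# ---------------------------------------------------------------------------

def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(y: np.ndarray, x: np.ndarray, dy: np.ndarray) -> np.ndarray:
    out = dy * (y + 1.0)
    np.copyto(out, dy, where=x > 0)
    return out


class _BatchNorm:
    """Batch normalization over all axes except the parameter axes."""

    def __init__(self, shape: tuple[int, ...], axes: tuple[int, ...], momentum: float = 0.1):
        self.gamma = np.ones(shape, dtype=np.float32)
        self.beta = np.zeros(shape, dtype=np.float32)
        self.running_mean = np.zeros(shape, dtype=np.float32)
        self.running_var = np.ones(shape, dtype=np.float32)
        self.axes = axes
        self.momentum = momentum
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=self.axes, keepdims=True)
            var = x.var(axis=self.axes, keepdims=True)
            ivar = 1.0 / np.sqrt(var + _EPS)
            xhat = (x - mu) * ivar
            self.running_mean += self.momentum * (mu.astype(np.float32) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float32) - self.running_var)
            self._cache = (xhat, ivar)
            return self.gamma * xhat + self.beta
        ivar = 1.0 / np.sqrt(self.running_var + _EPS)
        a = (self.gamma * ivar).astype(np.float32)
        b = (self.beta - a * self.running_mean).astype(np.float32)
        return a * x + b

    def backward(self, dy: np.ndarray):
        xhat, ivar = self._cache
        n = dy.size // self.gamma.size
        dgamma = (dy * xhat).sum(axis=self.axes, keepdims=True)
        dbeta = dy.sum(axis=self.axes, keepdims=True)
        # dx = (gamma*ivar/n)*(n*dy - dbeta - xhat*dgamma), grouped into
        # three broadcast passes
        a = (self.gamma * ivar).astype(np.float32)
        b = (-a * dgamma / n).astype(np.float32)
        c = (-a * dbeta / n).astype(np.float32)
        dx = a * dy + b * xhat + c
        return dx.astype(np.float32), dgamma.astype(np.float32), dbeta.astype(np.float32)

    def state(self) -> dict[str, np.ndarray]:
        return {
            "gamma": self.gamma, "beta": self.beta,
            "running_mean": self.running_mean, "running_var": self.running_var,
        }


def _avgpool(x: np.ndarray, pool: int) -> np.ndarray:
    """Mean over consecutive blocks along the last axis; remainder dropped."""
    n = (x.shape[-1] // pool) * pool
    shp = x.shape[:-1] + (n // pool, pool)
    return x[..., :n].reshape(shp).mean(axis=-1)


def _avgpool_grad(dy: np.ndarray, pool: int, in_len: int) -> np.ndarray:
    dx = np.zeros(dy.shape[:-1] + (in_len,), dtype=np.float32)
    n = dy.shape[-1] * pool
    dx[..., :n].reshape(dy.shape + (pool,))[:] = (dy / pool)[..., None]
    return dx


# ---------------------------------------------------------------------------
# c-EEGNet
# ---------------------------------------------------------------------------

class CEEGNet:
    """The four-branch verification network (see module docstring).

    Parameters are float32 NumPy arrays; ``rng_seed`` fixes initialization,
    the train/validation split, batch shuffling and dropout, so training is
    deterministic end to end.
    """

    def __init__(self, config: CEEGNetConfig | None = None, rng_seed: int = 0):
        self.config = config or CEEGNetConfig()
        self.rng_seed = rng_seed
        self.metadata: dict = {"seed": rng_seed, "trained": False}
        cfg = self.config
        rng = np.random.default_rng(rng_seed)

        def glorot(*shape):
            fan = sum(shape) / len(shape)
            return (rng.standard_normal(shape) / np.sqrt(fan)).astype(np.float32)

        self.params: dict[str, np.ndarray] = {}
        self.bns: dict[str, _BatchNorm] = {}
        for br in range(4):
            self.params[f"W1_{br}"] = glorot(cfg.n1, cfg.time_kernel)
            self.params[f"Wd_{br}"] = glorot(cfg.n1, cfg.n2, cfg.n_channels)
            self.params[f"Wt_{br}"] = glorot(cfg.n1, cfg.n2, cfg.time_kernel2)
            self.bns[f"bn1_{br}"] = _BatchNorm((cfg.n1, 1, 1, 1), (1, 2, 3))
            self.bns[f"bn2_{br}"] = _BatchNorm((cfg.n1, 1, cfg.n2, 1), (1, 3))
            self.bns[f"bn3_{br}"] = _BatchNorm((cfg.n1, 1, cfg.n2, 1), (1, 3))
        if cfg.merge_mode == "full":
            self.params["Wp"] = glorot(cfg.n4, cfg.n_features)
        else:
            self.params["Wp"] = glorot(cfg.n4, 4)
        self.bns["bnp"] = _BatchNorm((1, cfg.n4, 1), (0, 2))
        self.params["Wout"] = glorot(2, cfg.flat_len)
        self.params["bout"] = np.zeros(2, dtype=np.float32)
        self._train_rng = np.random.default_rng(rng_seed + 1)

    # -- bookkeeping ------------------------------------------------------

    @property
    def param_count(self) -> int:
        n = sum(p.size for p in self.params.values())
        n += sum(bn.gamma.size + bn.beta.size for bn in self.bns.values())
        return n

    def all_arrays(self) -> dict[str, np.ndarray]:
        """Every learnable / running array, flat-named (for serialization)."""
        out = dict(self.params)
        for name, bn in self.bns.items():
            for k, v in bn.state().items():
                out[f"{name}.{k}"] = v
        return out

    def load_arrays(self, arrays: Mapping[str, np.ndarray]) -> None:
        for name in self.params:
            self.params[name] = np.asarray(arrays[name], dtype=np.float32)
        for name, bn in self.bns.items():
            bn.gamma = np.asarray(arrays[f"{name}.gamma"], dtype=np.float32)
            bn.beta = np.asarray(arrays[f"{name}.beta"], dtype=np.float32)
            bn.running_mean = np.asarray(arrays[f"{name}.running_mean"], dtype=np.float32)
            bn.running_var = np.asarray(arrays[f"{name}.running_var"], dtype=np.float32)

    # -- forward / backward ----------------------------------------------

    def _branch_forward(self, Xb, br, train, rng, cache):
        cfg = self.config
        K, F1, J = cfg.time_kernel, cfg.n1, cfg.n2
        B, C, T = Xb.shape
        pl = (K - 1) // 2
        Xp = np.pad(Xb, ((0, 0), (0, 0), (pl, K - 1 - pl))).astype(np.float32)
        col = np.empty((K, B * C * T), dtype=np.float32)
        flat = Xp.reshape(B * C, -1)
        for k in range(K):
            col[k] = flat[:, k : k + T].reshape(-1)
        A1 = (self.params[f"W1_{br}"] @ col).reshape(F1, B, C, T)
        # First batch-norm fused into the (linear) depthwise channel conv:
        # with the per-map affine N1 = s*A1 + r, the conv output is
        # s_f * (Wd @ A1) + r_f * sum_c Wd, so the big normalized tensor is
        # never materialized.
        bn1 = self.bns[f"bn1_{br}"]
        if train:
            n_per = A1[0].size
            mu = (A1.mean(axis=(1, 2, 3))).reshape(-1, 1, 1, 1)
            sumsq = np.einsum("fx,fx->f", A1.reshape(F1, -1), A1.reshape(F1, -1))
            var = (sumsq / n_per).reshape(-1, 1, 1, 1) - mu * mu
            np.maximum(var, 0.0, out=var)
            bn1.running_mean += bn1.momentum * (mu.astype(np.float32) - bn1.running_mean)
            bn1.running_var += bn1.momentum * (var.astype(np.float32) - bn1.running_var)
        else:
            mu, var = bn1.running_mean, bn1.running_var
        ivar = 1.0 / np.sqrt(var + _EPS)
        s = (bn1.gamma * ivar).astype(np.float32)  # (F1,1,1,1)
        r = (bn1.beta - s * mu).astype(np.float32)
        Wd = self.params[f"Wd_{br}"]
        M = np.matmul(Wd[:, None], A1)  # (F1,B,J,T)
        swd = Wd.sum(axis=-1)  # (F1,J)
        A2 = s * M + r * swd[:, None, :, None]  # s, r are (F1,1,1,1)
        N2 = self.bns[f"bn2_{br}"].forward(A2, train)
        E2 = _elu(N2)
        P1 = _avgpool(E2, cfg.n3)  # (F1,B,J,T1)
        if train and cfg.dropout > 0:
            mask1 = (rng.random(P1.shape) >= cfg.dropout).astype(np.float32) / (1 - cfg.dropout)
            D1 = P1 * mask1
        else:
            mask1, D1 = None, P1
        # depthwise second temporal conv, 'same' padding
        K2 = cfg.time_kernel2
        T1 = D1.shape[-1]
        p2 = (K2 - 1) // 2
        Dp = np.pad(D1, ((0, 0), (0, 0), (0, 0), (p2, K2 - 1 - p2)))
        Wt = self.params[f"Wt_{br}"]
        A3 = np.zeros_like(D1)
        for k in range(K2):
            A3 += Wt[:, None, :, k : k + 1] * Dp[..., k : k + T1]
        N3 = self.bns[f"bn3_{br}"].forward(A3, train)
        if train:
            # sliding column sums (for the constant term of the W1 gradient)
            Sp = Xp.sum(axis=(0, 1))
            cs = np.concatenate([[0.0], np.cumsum(Sp)])
            colsum = (cs[np.arange(K) + T] - cs[np.arange(K)]).astype(np.float32)
            cache[br] = dict(col=col, A1=A1, M=M, s=s, r=r, mu=mu, ivar=ivar,
                             swd=swd, colsum=colsum, N2=N2, E2=E2, mask1=mask1, Dp=Dp)
        return N3  # (F1, B, J, T1)

    def _branch_backward(self, dN3, br, cache, grads):
        cfg = self.config
        c = cache[br]
        F1, J, K2 = cfg.n1, cfg.n2, cfg.time_kernel2
        dA3, dg, db = self.bns[f"bn3_{br}"].backward(dN3)
        grads[f"bn3_{br}.gamma"] = dg
        grads[f"bn3_{br}.beta"] = db
        T1 = dA3.shape[-1]
        p2 = (K2 - 1) // 2
        Wt = self.params[f"Wt_{br}"]
        dWt = np.empty_like(Wt)
        dDp = np.zeros_like(c["Dp"])
        for k in range(K2):
            dWt[:, :, k] = (dA3 * c["Dp"][..., k : k + T1]).sum(axis=(1, 3))
            dDp[..., k : k + T1] += Wt[:, None, :, k : k + 1] * dA3
        grads[f"Wt_{br}"] = dWt
        dD1 = dDp[..., p2 : p2 + T1]
        if c["mask1"] is not None:
            dD1 = dD1 * c["mask1"]
        dE2 = _avgpool_grad(dD1, cfg.n3, c["E2"].shape[-1])
        dN2 = _elu_grad(c["E2"], c["N2"], dE2)
        dA2, dg, db = self.bns[f"bn2_{br}"].backward(dN2)
        grads[f"bn2_{br}.gamma"] = dg
        grads[f"bn2_{br}.beta"] = db
        # backward through the fused BN1 + channel conv (see forward)
        Wd = self.params[f"Wd_{br}"]
        A1, M, s, r = c["A1"], c["M"], c["s"], c["r"]
        mu, ivar, swd = c["mu"], c["ivar"], c["swd"]
        dA2_jsum = dA2.sum(axis=(1, 3))  # (F1,J)
        dbeta = (dA2_jsum * swd).sum(axis=1)  # (F1,)
        dgamma = (ivar.reshape(-1) * ((dA2 * M).sum(axis=(1, 2, 3))
                                      - mu.reshape(-1) * dbeta))
        grads[f"bn1_{br}.gamma"] = dgamma.reshape(s.shape).astype(np.float32)
        grads[f"bn1_{br}.beta"] = dbeta.reshape(s.shape).astype(np.float32)
        term1 = np.matmul(dA2, A1.transpose(0, 1, 3, 2)).sum(axis=1)  # (F1,J,C)
        grads[f"Wd_{br}"] = (s.reshape(-1, 1, 1) * term1
                             + r.reshape(-1, 1, 1) * dA2_jsum[..., None])
        dN1 = np.matmul(Wd.transpose(0, 2, 1)[:, None], dA2)  # (F1,B,C,T)
        # dA1 = s*dN1 + c1*A1 + c0 is never materialized: its product with
        # the column matrix distributes over the three terms (the constant
        # one contracts with the cached sliding column sums).
        n = dN1[0].size
        dg4 = dgamma.reshape(s.shape).astype(np.float32)
        db4 = dbeta.reshape(s.shape).astype(np.float32)
        c1 = (-(s * ivar * dg4) / n).astype(np.float32)
        c0 = ((-s * db4 + s * ivar * mu * dg4) / n).astype(np.float32)
        colT = c["col"].T
        grads[f"W1_{br}"] = (
            s.reshape(-1, 1) * (dN1.reshape(cfg.n1, -1) @ colT)
            + c1.reshape(-1, 1) * (A1.reshape(cfg.n1, -1) @ colT)
            + c0.reshape(-1, 1) * c["colsum"][None, :]
        )
        # input gradient is not needed (first layer)

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                cache: dict | None = None) -> np.ndarray:
        """Class probabilities for samples ``X`` of shape (B, 4, C, T)."""
        cfg = self.config
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        if X.shape[1:] != (4, cfg.n_channels, cfg.n_times):
            raise ValueError(
                f"expected samples of shape (B, 4, {cfg.n_channels}, {cfg.n_times}); "
                f"got {X.shape}"
            )
        B = X.shape[0]
        rng = rng or np.random.default_rng(0)
        cache = cache if cache is not None else {}
        outs = [self._branch_forward(X[:, br], br, train, rng, cache) for br in range(4)]
        Z = np.stack(outs)  # (4, F1, B, J, T1)
        T1 = Z.shape[-1]
        if cfg.merge_mode == "full":
            Zc = np.ascontiguousarray(Z.transpose(2, 0, 1, 3, 4)).reshape(B, cfg.n_features, T1)
            Y = np.matmul(self.params["Wp"], Zc)  # (B, n4, T1)
        else:
            # combine across the branch axis only, one kernel per feature
            Zb = np.ascontiguousarray(Z.transpose(2, 1, 3, 0, 4)).reshape(B, cfg.n4, 4, T1)
            Zc = Zb
            Y = np.einsum("bfat,fa->bft", Zb, self.params["Wp"], optimize=True)
        Np = self.bns["bnp"].forward(Y, train)
        Ep = _elu(Np)
        P2 = _avgpool(Ep, cfg.n5)  # (B, n4, T2)
        if train and cfg.dropout > 0:
            mask2 = (rng.random(P2.shape) >= cfg.dropout).astype(np.float32) / (1 - cfg.dropout)
            D2 = P2 * mask2
        else:
            mask2, D2 = None, P2
        flat = D2.reshape(B, -1)
        logits = flat @ self.params["Wout"].T + self.params["bout"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache["head"] = dict(Zc=Zc, Y=Y, Np=Np, Ep=Ep, mask2=mask2, D2=D2,
                             flat=flat, probs=probs, B=B, T1=T1)
        return probs

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy and gradients for one training batch."""
        cfg = self.config
        cache: dict = {}
        probs = self.forward(X, train=True, rng=rng, cache=cache)
        h = cache["head"]
        B = h["B"]
        loss = float(-np.log(np.clip(probs[np.arange(B), y], 1e-12, None)).mean())
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads["Wout"] = dlogits.T @ h["flat"]
        grads["bout"] = dlogits.sum(axis=0)
        dflat = dlogits @ self.params["Wout"]
        dD2 = dflat.reshape(h["D2"].shape)
        if h["mask2"] is not None:
            dD2 = dD2 * h["mask2"]
        dEp = _avgpool_grad(dD2, cfg.n5, h["Ep"].shape[-1])
        dNp = _elu_grad(h["Ep"], h["Np"], dEp)
        dY, dg, db = self.bns["bnp"].backward(dNp)
        grads["bnp.gamma"] = dg
        grads["bnp.beta"] = db
        T1 = h["T1"]
        if cfg.merge_mode == "full":
            grads["Wp"] = np.matmul(dY, h["Zc"].transpose(0, 2, 1)).sum(axis=0)
            dZc = np.matmul(self.params["Wp"].T, dY)  # (B, n_features, T1)
            dZ = dZc.reshape(B, 4, cfg.n1, cfg.n2, T1).transpose(1, 2, 0, 3, 4)
        else:
            grads["Wp"] = np.einsum("bfat,bft->fa", h["Zc"], dY, optimize=True)
            dZb = np.einsum("bft,fa->bfat", dY, self.params["Wp"], optimize=True)
            dZ = dZb.reshape(B, cfg.n1, cfg.n2, 4, T1).transpose(3, 1, 0, 2, 4)
        for br in range(4):
            self._branch_backward(np.ascontiguousarray(dZ[br]), br, cache, grads)
        return loss, grads

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Genuine/impostor probabilities, dropout disabled, batched."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        out = [self.forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
        return np.concatenate(out)

    # -- training ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            train_config: TrainConfig | None = None) -> dict:
        """Train with Adam + early stopping; returns the history metadata.

        The validation split is stratified by label; the best-validation-
        loss parameter set is restored at the end.  Raises on non-finite
        loss (divergence).
        """
        tc = train_config or TrainConfig()
        rng = np.random.default_rng(tc.rng_seed)
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        # stratified split
        val_idx, train_idx = [], []
        for label in np.unique(y):
            idx = np.flatnonzero(y == label)
            idx = idx[rng.permutation(len(idx))]
            n_val = max(1, int(round(tc.val_fraction * len(idx))))
            val_idx.extend(idx[:n_val])
            train_idx.extend(idx[n_val:])
        train_idx = np.array(train_idx)
        val_idx = np.array(val_idx)
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]

        m = {k: np.zeros_like(v) for k, v in self._opt_params().items()}
        v = {k: np.zeros_like(p) for k, p in self._opt_params().items()}
        step = 0
        best_loss = np.inf
        best_state = None
        best_epoch = -1
        history = {"train_loss": [], "val_loss": [], "val_acc": []}
        for epoch in range(tc.max_epochs):
            order = rng.permutation(len(Xtr))
            losses = []
            for start in range(0, len(order), tc.batch_size):
                batch = order[start : start + tc.batch_size]
                loss, grads = self.loss_and_grads(Xtr[batch], ytr[batch], rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={loss}"
                    )
                step += 1
                self._adam_step(grads, m, v, step, tc.lr)
                losses.append(loss)
            pv = self.predict_proba(Xval)
            val_loss = float(
                -np.log(np.clip(pv[np.arange(len(yval)), yval], 1e-12, None)).mean()
            )
            val_acc = float((pv.argmax(axis=1) == yval).mean())
            history["train_loss"].append(float(np.mean(losses)))
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_epoch = epoch
                best_state = {k: p.copy() for k, p in self.all_arrays().items()}
            if val_loss < tc.val_loss_floor or epoch - best_epoch >= tc.patience:
                break
        if best_state is not None:
            self.load_arrays(best_state)
        self.metadata.update(
            trained=True,
            train_config=asdict(tc),
            epochs_run=len(history["train_loss"]),
            best_epoch=best_epoch,
            final_train_loss=history["train_loss"][-1],
            best_val_loss=best_loss,
            val_acc=history["val_acc"][best_epoch],
            history=history,
        )
        logger.info(
            "c-EEGNet trained: %d epochs, val acc %.3f",
            self.metadata["epochs_run"], self.metadata["val_acc"],
        )
        return self.metadata

    def _opt_params(self) -> dict[str, np.ndarray]:
        out = dict(self.params)
        for name, bn in self.bns.items():
            out[f"{name}.gamma"] = bn.gamma
            out[f"{name}.beta"] = bn.beta
        return out

    def _adam_step(self, grads, m, v, step, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        params = self._opt_params()
        for k, g in grads.items():
            g = g.reshape(params[k].shape)
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v[k] = beta2 * v[k] + (1 - beta2) * g * g
            mhat = m[k] / (1 - beta1**step)
            vhat = v[k] / (1 - beta2**step)
            params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)


def build_ceegnet(config: CEEGNetConfig | None = None, rng_seed: int = 0) -> CEEGNet:
    """Construct an untrained c-EEGNet (shape contract checked at build)."""
    model = CEEGNet(config, rng_seed)
    logger.info("built c-EEGNet with %d parameters", model.param_count)
    return model


def train_ceegnet(model: CEEGNet, packet: TrainingPacket,
                  train_config: TrainConfig | None = None) -> CEEGNet:
    """Train a model on one claimed subject's packet (in place)."""
    model.fit(packet.X, packet.y, train_config)
    model.metadata["claimed_subject"] = packet.claimed_subject
    model.metadata["n_avg"] = packet.n_avg
    return model


def authenticate_ceegnet(
    model: CEEGNet, sample: np.ndarray,
    rule: Literal["argmax", "threshold"] = "argmax", theta: float = 0.5,
) -> dict:
    """Accept/reject one sample.  The genuine probability is always
    returned; a probability exactly at the boundary accepts."""
    probs = model.predict_proba(np.asarray(sample)[None] if np.asarray(sample).ndim == 3
                                else np.asarray(sample))
    score = float(probs[0, 1])
    cut = 0.5 if rule == "argmax" else float(theta)
    return {"decision": "accept" if score >= cut else "reject", "score": score}


# ---------------------------------------------------------------------------
# TRCA
# ---------------------------------------------------------------------------

@dataclass
class TRCAModel:
    """Per-position spatial filters and templates with an accept threshold."""

    filters: dict[str, np.ndarray]  # position -> (C,) unit-norm filter
    templates: dict[str, np.ndarray]  # position -> (T,) filtered class mean
    theta: float = 0.0
    eigenvalues: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _trca_filter(trials: np.ndarray, ridge: float = 1e-6) -> tuple[np.ndarray, float]:
    """Leading generalized eigenvector of (S, Q) for one class.

    ``trials`` is (K, C, T).  S sums the cross-trial covariances over all
    ordered pairs j != k; Q is the covariance of the temporally concatenated
    (per-trial centered) data.  A singular Q is ridge-regularized.
    """
    K, C, T = trials.shape
    Xc = trials - trials.mean(axis=-1, keepdims=True)
    total = Xc.sum(axis=0)  # (C, T)
    Q = np.einsum("kct,kdt->cd", Xc, Xc, optimize=True)
    S = total @ total.T - Q
    S = 0.5 * (S + S.T)
    Q = 0.5 * (Q + Q.T)
    try:
        w_all, V = scipy.linalg.eigh(S, Q)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        reg = ridge * np.trace(Q) / C
        logger.info("TRCA: singular Q, ridge-regularizing with eps=%.3g", reg)
        w_all, V = scipy.linalg.eigh(S, Q + reg * np.eye(C))
    if not np.all(np.isfinite(V)):
        reg = ridge * np.trace(Q) / C
        w_all, V = scipy.linalg.eigh(S, Q + reg * np.eye(C))
    w = V[:, -1]
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w.astype(np.float64), float(w_all[-1])


def trca_fit(epochs_by_position: Mapping[str, np.ndarray]) -> TRCAModel:
    """Fit per-position TRCA filters and templates from enrollment epochs.

    ``epochs_by_position`` maps each of the four positions to a (K, C, T)
    array with K >= 2 trials.  The template is the filter applied to the
    trial mean.  The accept threshold is left at 0 until calibrated.
    """
    filters, templates, eigs = {}, {}, {}
    for pos in POSITIONS:
        trials = np.asarray(epochs_by_position[pos], dtype=np.float64)
        if trials.ndim != 3 or trials.shape[0] < 2:
            raise ValueError(f"position {pos!r} needs >= 2 trials of shape (C, T)")
        w, lam = _trca_filter(trials)
        filters[pos] = w
        eigs[pos] = lam
        templates[pos] = w @ trials.mean(axis=0)
    return TRCAModel(filters=filters, templates=templates, eigenvalues=eigs)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        logger.info("TRCA: zero-variance filtered signal; correlation set to 0")
        return 0.0
    return float(a @ b / (na * nb))


def trca_scores(model: TRCAModel, X: np.ndarray) -> np.ndarray:
    """Aggregate correlation score for samples (n, 4, C, T): the mean over
    positions of the Pearson correlation between the filtered component and
    the position template."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 3:
        X = X[None]
    scores = np.empty(len(X))
    for i, sample in enumerate(X):
        s = 0.0
        for k, pos in enumerate(POSITIONS):
            comp = model.filters[pos] @ sample[k]
            s += _pearson(comp, model.templates[pos])
        scores[i] = s / len(POSITIONS)
    return scores


def trca_calibrate_threshold(model: TRCAModel, X: np.ndarray, y: np.ndarray,
                             n_folds: int = 5, rng_seed: int = 0) -> float:
    """Set the accept threshold to the F1-maximizing cut, averaged over
    stratified folds of training-packet scores."""
    scores = trca_scores(model, X)
    y = np.asarray(y)
    rng = np.random.default_rng(rng_seed)
    folds = []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        idx = idx[rng.permutation(len(idx))]
        folds.append(np.array_split(idx, n_folds))
    thetas = []
    for f in range(n_folds):
        held = np.concatenate([folds[k][f] for k in range(len(folds))])
        fit_idx = np.setdiff1d(np.arange(len(y)), held)
        thetas.append(_f1_max_threshold(scores[fit_idx], y[fit_idx]))
    model.theta = float(np.mean(thetas))
    model.metadata["calibration"] = {"n_folds": n_folds, "fold_thetas": thetas}
    return model.theta


def _f1_max_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    order = np.argsort(scores)
    s, lab = scores[order], y[order]
    cuts = np.concatenate([[s[0] - 1e-6], (s[:-1] + s[1:]) / 2, [s[-1] + 1e-6]])
    best_f1, best_cut = -1.0, 0.0
    npos = lab.sum()
    for cut in cuts:
        pred = s >= cut
        tp = int((pred & (lab == 1)).sum())
        fp = int((pred & (lab == 0)).sum())
        fn = int(npos - tp)
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        if f1 > best_f1:
            best_f1, best_cut = f1, float(cut)
    return best_cut


def authenticate_trca(model: TRCAModel, sample: np.ndarray) -> dict:
    """Accept iff the aggregate correlation score reaches the threshold."""
    score = float(trca_scores(model, sample)[0])
    return {"decision": "accept" if score >= model.theta else "reject", "score": score}


# ---------------------------------------------------------------------------
# Serialization (shared container for both model types)
# ---------------------------------------------------------------------------

def save_model(model: CEEGNet | TRCAModel, path) -> None:
    """Write a model to an HDF5 container with a JSON header; parameter
    round-trips are bit-exact."""
    import h5py

    with h5py.File(path, "w") as f:
        if isinstance(model, CEEGNet):
            header = {
                "model_type": "ceegnet",
                "version": MODEL_FORMAT_VERSION,
                "config": asdict(model.config),
                "seed": model.rng_seed,
            }
            grp = f.create_group("params")
            for k, v in model.all_arrays().items():
                grp.create_dataset(k, data=v)
        elif isinstance(model, TRCAModel):
            header = {
                "model_type": "trca",
                "version": MODEL_FORMAT_VERSION,
                "theta": model.theta,
                "eigenvalues": model.eigenvalues,
            }
            grp = f.create_group("params")
            for pos in POSITIONS:
                grp.create_dataset(f"filter_{pos}", data=model.filters[pos])
                grp.create_dataset(f"template_{pos}", data=model.templates[pos])
        else:
            raise TypeError(f"cannot serialize {type(model)}")
        f.attrs["header"] = json.dumps(header)


def load_model(path) -> CEEGNet | TRCAModel:
    """Read a model container written by :func:`save_model`."""
    import h5py

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"not a readable model container: {path} ({exc})") from exc
    with f:
        try:
            header = json.loads(f.attrs["header"])
        except (KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"corrupted model header in {path}") from exc
        version = header.get("version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model container version {version} != supported {MODEL_FORMAT_VERSION}"
            )
        if header["model_type"] == "ceegnet":
            model = CEEGNet(CEEGNetConfig(**header["config"]), rng_seed=header["seed"])
            model.load_arrays({k: v[()] for k, v in f["params"].items()})
            return model
        if header["model_type"] == "trca":
            return TRCAModel(
                filters={p: f["params"][f"filter_{p}"][()] for p in POSITIONS},
                templates={p: f["params"][f"template_{p}"][()] for p in POSITIONS},
                theta=header["theta"],
                eigenvalues=header.get("eigenvalues", {}),
            )
        raise ValueError(f"unknown model_type {header['model_type']!r}")
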
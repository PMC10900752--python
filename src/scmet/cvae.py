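"""Conditional variational auto-encoder over log-normalized expression.

The generator learns a per-cell-type conditional distribution of expression
profiles: the encoder maps an expression vector concatenated with a one-hot
cell-type condition to a diagonal Gaussian in latent space, and the decoder
maps a latent draw plus the same condition back to expression, with a
softplus output so generated profiles are nonnegative. Training minimizes
mean reconstruction error plus beta times the KL divergence of the
approximate posterior from the standard normal prior, with early stopping
on a held-out validation split.

Sampling the prior at a chosen scale (``sigma_scale``) and decoding with a
cell-type condition yields new cells of that type; larger scales produce
more dispersed cells, ``sigma_scale = 0`` the deterministic per-type
archetype. The whole model is plain numpy (dense MLPs, manual gradients,
Adam), sized to train on a CPU in seconds to minutes at reference scales of
a few thousand cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .errors import (DivergenceError, ParameterError, VocabularyError)

__all__ = ["CVAEGenerator", "GenerationBatch", "TrainTrace", "build_pool",
           "evaluate_generation"]


@dataclass
class TrainTrace:
    """Per-epoch training and validation losses."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass
class GenerationBatch:
    """Generated cells in normalized-expression space with their labels."""

    matrix: np.ndarray
    labels: np.ndarray
    sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2 or len(self.labels) != self.matrix.shape[0]:
            raise ParameterError("labels must align with matrix rows")
        if self.matrix.size and self.matrix.min() < 0:
            raise ParameterError("generated expression must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


def _relu(x):
    return np.maximum(x, 0.0)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    """Adam optimizer over a dict of numpy arrays."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


class CVAEGenerator(BaseEstimator):
    """Conditional VAE generator of single-cell expression profiles.

    Parameters
    ----------
    latent_dim
        Latent Gaussian dimension.
    hidden1, hidden2
        Encoder layer widths (the decoder mirrors them).
    beta
        Weight of the KL term in the loss.
    learning_rate, batch_size, max_epochs
        Adam optimization schedule.
    patience
        Early-stopping patience on validation loss, in epochs.
    val_fraction
        Fraction of cells held out for validation.
    min_cells_per_label
        Every label must have at least this many cells to train.
    random_state
        Seed controlling the split, shuffling, initialization and the
        reparameterization noise; training is reproducible given the seed.

    Attributes
    ----------
    label_vocab_ : list of str
        Cell types the model can condition on (sorted unique labels).
    gene_list_ : list of str
        Genes, in the column order of the training matrix.
    train_loss_, val_loss_ : list of float
        Per-epoch loss trace; the kept weights are the validation optimum.
    trace_ : TrainTrace
    """

    def __init__(self, latent_dim: int = 64, hidden1: int = 512,
                 hidden2: int = 256, beta: float = 0.5,
                 learning_rate: float = 1e-3, batch_size: int = 128,
                 max_epochs: int = 200, patience: int = 10,
                 val_fraction: float = 0.1, min_cells_per_label: int = 10,
                 random_state: int = 0):
        self.latent_dim = latent_dim
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.beta = beta
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.min_cells_per_label = min_cells_per_label
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, gene_list=None):
        """Train on log-normalized expression ``X`` with cell-type labels ``y``."""
        X = self._as_dense(X)
        y = np.asarray(y, dtype=object)
        if len(y) != X.shape[0]:
            raise ParameterError("labels must align with rows of X")
        vocab, counts = np.unique(y.astype(str), return_counts=True)
        starved = vocab[counts < self.min_cells_per_label]
        if len(starved):
            raise ParameterError(
                "labels with fewer than "
                f"{self.min_cells_per_label} cells: {', '.join(starved)}")
        self.label_vocab_ = [str(v) for v in vocab]
        self.gene_list_ = ([f"G{i}" for i in range(X.shape[1])]
                           if gene_list is None else [str(g) for g in gene_list])
        if len(self.gene_list_) != X.shape[1]:
            raise ParameterError("gene_list must match the number of columns")
        self.norm_meta_ = {"space": "log1p_cp10k", "scale": 1e4}

        rng = np.random.default_rng(self.random_state)
        n, g = X.shape
        c = len(self.label_vocab_)
        onehot = self._onehot(y)

        n_val = max(1, int(round(self.val_fraction * n))) if n > 1 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, Ytr = X[tr_idx], onehot[tr_idx]
        Xva, Yva = X[val_idx], onehot[val_idx]

        self.params_ = self._init_params(g, c, rng)
        opt = _Adam(self.params_, self.learning_rate)

        best_val = np.inf
        best_params = {k: v.copy() for k, v in self.params_.items()}
        best_epoch = 0
        stall = 0
        train_trace: list[float] = []
        val_trace: list[float] = []

        n_tr = Xtr.shape[0]
        bs = min(self.batch_size, max(1, n_tr))
        for epoch in range(self.max_epochs):
            order = rng.permutation(n_tr)
            epoch_loss = 0.0
            for start in range(0, n_tr, bs):
                idx = order[start:start + bs]
                loss, grads = self._loss_and_grads(Xtr[idx], Ytr[idx], rng)
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite loss at epoch {epoch + 1}; "
                        f"last stable epoch {epoch}")
                opt.step(self.params_, grads)
                epoch_loss += loss * len(idx)
            train_trace.append(epoch_loss / n_tr)
            val = (self._eval_loss(Xva, Yva) if len(val_idx)
                   else train_trace[-1])
            val_trace.append(val)
            if val < best_val - 1e-9:
                best_val = val
                best_params = {k: v.copy() for k, v in self.params_.items()}
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break

        self.params_ = best_params
        self.best_epoch_ = best_epoch
        self.train_loss_ = train_trace
        self.val_loss_ = val_trace
        self.trace_ = TrainTrace(train_loss=train_trace, val_loss=val_trace,
                                 converged=stall >= self.patience)
        self.n_features_in_ = g
        return self

    # ----------------------------------------------------------- generation

    def sample(self, label: str, n: int, sigma_scale: float = 1.0,
               seed: int = 0) -> GenerationBatch:
        """Generate ``n`` cells of type ``label``.

        Latents are drawn from ``Normal(0, sigma_scale^2 I)`` and decoded
        with the label condition; ``sigma_scale = 0`` decodes the zero
        latent, yielding ``n`` identical archetype rows. Deterministic
        given ``seed``.
        """
        self._check_fitted()
        if label not in self.label_vocab_:
            raise VocabularyError(
                f"unknown label {label!r}; vocabulary: {self.label_vocab_}")
        if n < 0:
            raise ParameterError(f"n must be >= 0, got {n}")
        if sigma_scale < 0:
            raise ParameterError(f"sigma_scale must be >= 0, got {sigma_scale}")
        rng = np.random.default_rng(seed)
        z = sigma_scale * rng.standard_normal((n, self.latent_dim))
        onehot = np.zeros((n, len(self.label_vocab_)))
        onehot[:, self.label_vocab_.index(label)] = 1.0
        out = self._decode(z, onehot) if n else np.zeros((0, len(self.gene_list_)))
        return GenerationBatch(matrix=np.clip(out, 0.0, None),
                               labels=np.array([label] * n, dtype=object),
                               sigma_scale=sigma_scale)

    def reconstruct(self, X, y) -> np.ndarray:
        """Deterministic reconstruction (decode the posterior mean)."""
        self._check_fitted()
        X = self._as_dense(X)
        mu, _, _ = self._encode(X, self._onehot(np.asarray(y, dtype=object)))
        return self._decode(mu, self._onehot(np.asarray(y, dtype=object)))

    # ------------------------------------------------------------ internals

    @staticmethod
    def _as_dense(X) -> np.ndarray:
        if sp.issparse(X):
            return np.asarray(X.todense(), dtype=float)
        return np.asarray(X, dtype=float)

    def _onehot(self, y: np.ndarray) -> np.ndarray:
        lut = {v: i for i, v in enumerate(self.label_vocab_)}
        out = np.zeros((len(y), len(self.label_vocab_)))
        for i, lab in enumerate(y):
            if str(lab) not in lut:
                raise VocabularyError(f"unknown label {lab!r}")
            out[i, lut[str(lab)]] = 1.0
        return out

    def _init_params(self, g: int, c: int, rng) -> dict:
        L, h1, h2 = self.latent_dim, self.hidden1, self.hidden2

        def glorot(fan_in, fan_out):
            s = np.sqrt(2.0 / (fan_in + fan_out))
            return rng.standard_normal((fan_in, fan_out)) * s

        return {
            "W1": glorot(g + c, h1), "b1": np.zeros(h1),
            "W2": glorot(h1, h2), "b2": np.zeros(h2),
            "Wm": glorot(h2, L), "bm": np.zeros(L),
            "Wv": glorot(h2, L), "bv": np.zeros(L),
            "U1": glorot(L + c, h2), "c1": np.zeros(h2),
            "U2": glorot(h2, h1), "c2": np.zeros(h1),
            "U3": glorot(h1, g), "c3": np.zeros(g),
        }

    def _encode(self, X, Y):
        p = self.params_
        inp = np.hstack([X, Y])
        h1 = _relu(inp @ p["W1"] + p["b1"])
        h2 = _relu(h1 @ p["W2"] + p["b2"])
        mu = h2 @ p["Wm"] + p["bm"]
        logvar = np.clip(h2 @ p["Wv"] + p["bv"], -15.0, 15.0)
        return mu, logvar, (inp, h1, h2)

    def _decode(self, Z, Y):
        p = self.params_
        dinp = np.hstack([Z, Y])
        d1 = _relu(dinp @ p["U1"] + p["c1"])
        d2 = _relu(d1 @ p["U2"] + p["c2"])
        return _softplus(d2 @ p["U3"] + p["c3"])

    def _loss_and_grads(self, X, Y, rng):
        p = self.params_
        B = X.shape[0]
        mu, logvar, (inp, h1, h2) = self._encode(X, Y)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * logvar)
        z = mu + std * eps

        dinp = np.hstack([z, Y])
        d1 = _relu(dinp @ p["U1"] + p["c1"])
        d2 = _relu(d1 @ p["U2"] + p["c2"])
        o = d2 @ p["U3"] + p["c3"]
        xhat = _softplus(o)

        diff = xhat - X
        recon = float((diff ** 2).sum() / B)
        kl = float(-0.5 * (1.0 + logvar - mu ** 2 - np.exp(logvar)).sum() / B)
        loss = recon + self.beta * kl

        # backward pass
        g = {}
        do = (2.0 * diff / B) * _sigmoid(o)
        g["U3"] = d2.T @ do
        g["c3"] = do.sum(0)
        dd2 = (do @ p["U3"].T) * (d2 > 0)
        g["U2"] = d1.T @ dd2
        g["c2"] = dd2.sum(0)
        dd1 = (dd2 @ p["U2"].T) * (d1 > 0)
        g["U1"] = dinp.T @ dd1
        g["c1"] = dd1.sum(0)
        dz = (dd1 @ p["U1"].T)[:, : self.latent_dim]

        dmu = dz + self.beta * mu / B
        dlogvar = dz * eps * 0.5 * std + self.beta * 0.5 * (np.exp(logvar) - 1.0) / B
        g["Wm"] = h2.T @ dmu
        g["bm"] = dmu.sum(0)
        g["Wv"] = h2.T @ dlogvar
        g["bv"] = dlogvar.sum(0)
        dh2 = (dmu @ p["Wm"].T + dlogvar @ p["Wv"].T) * (h2 > 0)
        g["W2"] = h1.T @ dh2
        g["b2"] = dh2.sum(0)
        dh1 = (dh2 @ p["W2"].T) * (h1 > 0)
        g["W1"] = inp.T @ dh1
        g["b1"] = dh1.sum(0)
        return loss, g

    def _eval_loss(self, X, Y) -> float:
        """Deterministic loss at the posterior mean (no sampling noise)."""
        B = X.shape[0]
        mu, logvar, _ = self._encode(X, Y)
        xhat = self._decode(mu, Y)
        recon = float(((xhat - X) ** 2).sum() / B)
        kl = float(-0.5 * (1.0 + logvar - mu ** 2 - np.exp(logvar)).sum() / B)
        return recon + self.beta * kl

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise ParameterError("model is not fitted")

    # -------------------------------------------------------- serialization

    def _state_dict(self) -> dict:
        self._check_fitted()
        return dict(self.params_)

    def _load_state(self, state: dict, gene_list, label_vocab, norm_meta,
                    loss_history) -> None:
        self.params_ = {k: np.asarray(v, dtype=float) for k, v in state.items()}
        self.gene_list_ = [str(g) for g in gene_list]
        self.label_vocab_ = [str(v) for v in label_vocab]
        self.norm_meta_ = norm_meta
        self.train_loss_ = list(loss_history.get("train", []))
        self.val_loss_ = list(loss_history.get("val", []))
        self.trace_ = TrainTrace(train_loss=self.train_loss_,
                                 val_loss=self.val_loss_)
        self.n_features_in_ = len(self.gene_list_)


# ---------------------------------------------------------------- functions

def train_cvae(X, y, gene_list=None, **config) -> tuple[CVAEGenerator, TrainTrace]:
    """Functional wrapper: fit a :class:`CVAEGenerator` and return it with its trace."""
    model = CVAEGenerator(**config)
    model.fit(X, y, gene_list=gene_list)
    return model, model.trace_


def generate(model: CVAEGenerator, label: str, n: int,
             sigma_scale: float = 1.0, seed: int = 0) -> GenerationBatch:
    """Functional wrapper over :meth:`CVAEGenerator.sample`."""
    return model.sample(label, n, sigma_scale=sigma_scale, seed=seed)


def build_pool(model: CVAEGenerator, sizes: dict[str, int],
               sigma_scale: float = 1.0, seed: int = 0) -> GenerationBatch:
    """Concatenated per-label generation forming the candidate pool.

    Each label draws from a sub-seed spawned deterministically from the
    master seed, in vocabulary order, so the pool is reproducible and
    per-label content does not depend on which other labels are requested
    sizes for.
    """
    for lab, n in sizes.items():
        if n < 0:
            raise ParameterError(f"size for {lab!r} must be >= 0")
    children = np.random.SeedSequence(seed).spawn(len(model.label_vocab_))
    parts, labels = [], []
    for lab, child in zip(model.label_vocab_, children):
        n = int(sizes.get(lab, 0))
        if n == 0:
            continue
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        batch = model.sample(lab, n, sigma_scale=sigma_scale, seed=sub_seed)
        parts.append(batch.matrix)
        labels.extend([lab] * n)
    if not parts:
        return GenerationBatch(matrix=np.zeros((0, len(model.gene_list_))),
                               labels=np.array([], dtype=object),
                               sigma_scale=sigma_scale)
    return GenerationBatch(matrix=np.vstack(parts),
                           labels=np.array(labels, dtype=object),
                           sigma_scale=sigma_scale)


def evaluate_generation(real_X, real_labels, gen: GenerationBatch,
                        real_genes=None, gen_genes=None,
                        top_real: int = 20, top_gen: int = 100) -> dict:
    """Fidelity metrics of generated cells against the real reference.

    Returns per-type Pearson correlation between mean real and mean
    generated expression, and a marker-concordance score: the fraction of
    each type's ``top_real`` real marker genes (one-vs-rest log fold
    change) found among the generated type's ``top_gen`` markers.
    Gene spaces are aligned by identifier when gene lists are given.
    """
    from .deconv import rank_markers  # local import avoids a cycle

    real_X = CVAEGenerator._as_dense(real_X)
    gen_X = gen.matrix
    if real_genes is not None and gen_genes is not None:
        real_genes = np.asarray(real_genes, dtype=object)
        gen_genes = np.asarray(gen_genes, dtype=object)
        shared = [g for g in real_genes if g in set(gen_genes)]
        if not shared:
            raise ParameterError("real and generated gene sets are disjoint")
        ridx = {g: i for i, g in enumerate(real_genes)}
        gidx = {g: i for i, g in enumerate(gen_genes)}
        real_X = real_X[:, [ridx[g] for g in shared]]
        gen_X = gen_X[:, [gidx[g] for g in shared]]
    elif real_X.shape[1] != gen_X.shape[1]:
        raise ParameterError("gene spaces differ; pass gene lists to align")

    real_labels = np.asarray(real_labels, dtype=object)
    corr: dict[str, float] = {}
    concord: dict[str, float] = {}
    types = sorted(set(map(str, real_labels)) & set(map(str, gen.labels)))
    n_genes = real_X.shape[1]
    k_real = min(top_real, n_genes)
    k_gen = min(top_gen, n_genes)
    real_markers = rank_markers(real_X, real_labels, k=k_real, min_frac=0.0)
    gen_markers = rank_markers(gen_X, gen.labels, k=k_gen, min_frac=0.0)
    for t in types:
        rm = real_X[real_labels.astype(str) == t].mean(axis=0)
        gm = gen_X[gen.labels.astype(str) == t].mean(axis=0)
        corr[t] = float(np.corrcoef(rm, gm)[0, 1])
        top = set(gen_markers[t])
        concord[t] = sum(1 for g in real_markers[t] if g in top) / len(real_markers[t])
    return {"per_type_correlation": corr, "marker_concordance": concord}
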
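"""Marker-based deconvolution of bulk profiles into cell-type proportions.

Per-type markers are ranked by one-vs-rest log2 fold change of mean CP10K
expression (with a pseudocount), restricted to genes expressed in at least
a floor fraction of the type's cells. The signature matrix stacks the mean
reference expression of the marker union per type, and proportions are the
nonnegative least-squares solution of ``S p ~= b`` over the shared marker
genes, renormalized onto the simplex. The bulk vector is library-size
scaled to 10,000 before the solve, so scaling the bulk by any constant
leaves the estimate unchanged.

The solve runs in linear CP10K space by default: a bulk mixture is a
(depth-weighted) linear combination of cell-type mean profiles, so the
linear model is the one under which NNLS is unbiased. A log-space mode
(``space="log"``: log1p signatures against the log1p bulk) is kept for
comparison, but the log of a mixture is not the mixture of logs, which
biases recovered proportions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator

from .errors import ConsistencyError, ParameterError
from .qc import DEFAULT_SCALE
from .types import BulkProfile


@dataclass
class SignatureMatrix:
    """Marker x type matrix of reference mean expression.

    ``space`` records the expression scale of ``S``: ``"linear"`` for mean
    CP10K (default) or ``"log"`` for mean log1p CP10K.
    """

    markers: np.ndarray          # ordered marker gene names (union)
    types: list[str]             # ordered cell types
    S: np.ndarray                # |markers| x |types|, >= 0
    k: int                       # markers requested per type
    space: str = "linear"

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=object)
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.markers), len(self.types)):
            raise ConsistencyError("signature dimensions do not match labels")
        if self.S.size and self.S.min() < 0:
            raise ParameterError("signature must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.markers, columns=self.types)


@dataclass
class ProportionVector:
    """Per-type fractions on the simplex plus the NNLS residual norm."""

    types: list[str]
    fractions: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < -1e-12):
            raise ParameterError("fractions must be nonnegative")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ParameterError("fractions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {t: float(f) for t, f in zip(self.types, self.fractions)}


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def rank_markers(X, labels, k: int, min_frac: float = 0.1,
                 method: str = "lfc") -> dict[str, np.ndarray]:
    """Per-type ranked marker gene indices.

    For each type, genes expressed in at least ``min_frac`` of the type's
    cells are ranked by one-vs-rest log2 fold change of mean (linearized)
    expression with a pseudocount of 1; ``method='wilcoxon'`` ranks by the
    one-vs-rest rank-sum statistic instead. Ties resolve to the earlier
    gene; ``k`` larger than the eligible gene count is capped with a
    warning.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    X = _dense(X)
    labels = np.asarray(labels, dtype=object).astype(str)
    types = sorted(str(t) for t in set(labels))
    if len(types) < 2:
        raise ParameterError("need at least 2 cell types to rank markers")
    lin = np.expm1(X)  # back to CP10K scale for fold changes
    out: dict[str, np.ndarray] = {}
    for t in types:
        mask = labels == t
        frac = (X[mask] > 0).mean(axis=0)
        eligible = frac >= min_frac
        if method == "lfc":
            m_in = lin[mask].mean(axis=0)
            m_out = lin[~mask].mean(axis=0)
            score = np.log2((m_in + 1.0) / (m_out + 1.0))
        elif method == "wilcoxon":
            score = np.zeros(X.shape[1])
            for j in range(X.shape[1]):
                if not eligible[j]:
                    continue
                score[j] = scipy.stats.mannwhitneyu(
                    X[mask, j], X[~mask, j], alternative="greater").statistic
        else:
            raise ParameterError(f"unknown method {method!r}")
        score = np.where(eligible, score, -np.inf)
        n_eligible = int(eligible.sum())
        kk = k
        if k > n_eligible:
            warnings.warn(
                f"type {t!r}: only {n_eligible} genes pass the expression "
                f"floor; capping k={k}", stacklevel=2)
            kk = n_eligible
        out[t] = np.argsort(-score, kind="stable")[:kk]
    return out


def compute_signature(X, labels, marker_lists: dict[str, np.ndarray],
                      genes=None, k: int | None = None,
                      space: str = "linear") -> SignatureMatrix:
    """Mean reference expression of the marker union, per type.

    ``X`` is log-normalized; ``space="linear"`` stores mean CP10K
    (``expm1`` of the log values averaged per type), ``space="log"`` stores
    the mean log values. The union preserves first-appearance order across
    the per-type lists in type order; a marker shared between lists appears
    once.
    """
    if space not in ("linear", "log"):
        raise ParameterError(f"space must be 'linear' or 'log', got {space!r}")
    X = _dense(X)
    if space == "linear":
        X = np.expm1(X)
    labels = np.asarray(labels, dtype=object).astype(str)
    types = sorted(str(t) for t in marker_lists)
    union: list[int] = []
    seen: set[int] = set()
    for t in types:
        for g in marker_lists[t]:
            g = int(g)
            if g not in seen:
                seen.add(g)
                union.append(g)
    if not union:
        raise ParameterError("empty marker union")
    S = np.zeros((len(union), len(types)))
    for j, t in enumerate(types):
        mask = labels == t
        if not mask.any():
            raise ConsistencyError(f"no reference cells of type {t!r}")
        S[:, j] = X[mask][:, union].mean(axis=0)
    names = (np.array([f"G{i}" for i in union], dtype=object) if genes is None
             else np.asarray(genes, dtype=object)[union])
    kk = k if k is not None else max(len(v) for v in marker_lists.values())
    return SignatureMatrix(markers=names, types=types, S=S, k=kk, space=space)


def _bulk_to_signature_space(bulk: BulkProfile, sig: SignatureMatrix,
                             scale: float = DEFAULT_SCALE):
    """Library-size scale the full bulk vector into the signature's space,
    restricted to shared markers."""
    total = bulk.values.sum()
    if total <= 0:
        raise ParameterError(f"bulk sample {bulk.sample_id!r} is all zero")
    scaled = scale * bulk.values / total
    if sig.space == "log":
        scaled = np.log1p(scaled)
    idx = {g: i for i, g in enumerate(bulk.genes)}
    shared_rows = [j for j, g in enumerate(sig.markers) if g in idx]
    if len(shared_rows) < len(sig.types):
        raise ConsistencyError(
            f"only {len(shared_rows)} marker genes shared with bulk sample "
            f"{bulk.sample_id!r}; need at least {len(sig.types)}")
    b = np.array([scaled[idx[sig.markers[j]]] for j in shared_rows])
    return b, shared_rows


def estimate_proportions(bulk: BulkProfile, sig: SignatureMatrix) -> ProportionVector:
    """Nonnegative least-squares proportions of ``bulk`` under ``sig``."""
    b, rows = _bulk_to_signature_space(bulk, sig)
    if not np.any(b > 0):
        raise ParameterError(
            f"bulk sample {bulk.sample_id!r} is zero over all shared markers")
    A = sig.S[rows]
    p, resid = scipy.optimize.nnls(A, b)
    s = p.sum()
    if s <= 0:
        raise ParameterError(
            f"degenerate NNLS solution for sample {bulk.sample_id!r}")
    return ProportionVector(types=list(sig.types), fractions=p / s,
                            residual=float(resid))


def sweep_marker_count(X, labels, bulks: list[BulkProfile],
                       true_proportions: list[dict[str, float]],
                       k_values, genes=None, min_frac: float = 0.1,
                       space: str = "linear") -> pd.DataFrame:
    """Mean L1 recovery error (and an operation-count proxy) per marker count ``k``."""
    k_values = list(k_values)
    rows = []
    for k in k_values:
        markers = rank_markers(X, labels, k=k, min_frac=min_frac)
        sig = compute_signature(X, labels, markers, genes=genes, k=k,
                                space=space)
        l1s = []
        for bulk, truth in zip(bulks, true_proportions):
            est = estimate_proportions(bulk, sig).as_dict()
            l1s.append(sum(abs(est.get(t, 0.0) - truth.get(t, 0.0))
                           for t in set(est) | set(truth)))
        rows.append({
            "k": k,
            "n_markers": len(sig.markers),
            "mean_l1_error": float(np.mean(l1s)),
            "ops_proxy": len(sig.markers) * len(sig.types) * len(bulks),
        })
    return pd.DataFrame(rows)


class SignatureDeconvolver(BaseEstimator):
    """Estimator facade: fit a marker signature, transform bulk profiles.

    Parameters
    ----------
    markers_per_type
        Markers requested per cell type (the union forms the signature).
    min_expr_frac
        Expression-fraction floor a gene must reach within a type to be an
        eligible marker.
    method
        Marker ranking rule: ``'lfc'`` (one-vs-rest log2 fold change,
        default) or ``'wilcoxon'``.
    space
        Expression scale of the solve: ``'linear'`` (CP10K, default) or
        ``'log'`` (log1p CP10K).
    """

    def __init__(self, markers_per_type: int = 25, min_expr_frac: float = 0.1,
                 method: str = "lfc", space: str = "linear"):
        self.markers_per_type = markers_per_type
        self.min_expr_frac = min_expr_frac
        self.method = method
        self.space = space

    def fit(self, X, y, genes=None):
        """Rank markers and build the signature from log-normalized ``X``."""
        self.markers_ = rank_markers(X, y, k=self.markers_per_type,
                                     min_frac=self.min_expr_frac,
                                     method=self.method)
        self.signature_ = compute_signature(X, y, self.markers_, genes=genes,
                                            k=self.markers_per_type,
                                            space=self.space)
        self.types_ = list(self.signature_.types)
        return self

    def transform(self, bulks: list[BulkProfile]) -> pd.DataFrame:
        """Proportions for each profile, samples x types, plus a residual column."""
        if not hasattr(self, "signature_"):
            raise ParameterError("deconvolver is not fitted")
        rows = {}
        resid = {}
        for b in bulks:
            pv = estimate_proportions(b, self.signature_)
            rows[b.sample_id] = pv.as_dict()
            resid[b.sample_id] = pv.residual
        df = pd.DataFrame.from_dict(rows, orient="index")[self.types_]
        df["residual"] = pd.Series(resid)
        return df

    def fit_transform(self, X, y=None, bulks=None, genes=None):
        return self.fit(X, y, genes=genes).transform(bulks)
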
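"""Quality control and normalization for the single-cell reference.

Cell filtering uses the two classic per-cell criteria — detected-gene count
and mitochondrial-count fraction — with strict boundary semantics: a cell
with *fewer than* ``min_genes`` detected genes is removed (exactly
``min_genes`` is kept), and a cell whose mitochondrial fraction *exceeds*
``max_mito`` is removed (exactly ``max_mito`` is kept). Gene filtering keeps
genes expressed in at least ``min_cells`` cells. Doublets are scored by a
self-contained simulation-based detector (artificial doublets from summed
cell pairs, PCA embedding, k-nearest-neighbor vote calibrated by the
expected doublet rate) and removed above a score threshold, strict ``>``.

Normalization is log1p CP10K: per-cell totals scaled to 10,000 followed by
``ln(1 + x)`` — the space shared by signatures, bulk profiles and generated
cells throughout the package.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ConsistencyError, ParameterError
from .types import CellMatrix

DEFAULT_SCALE = 1e4


@dataclass
class QCReport:
    """Bookkeeping for one QC stage; counts reconcile input and output dims."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_low_gene: int = 0
    removed_high_mito: int = 0
    removed_doublets: int = 0
    removed_genes: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @staticmethod
    def combine(reports: list["QCReport"]) -> "QCReport":
        """Chain per-stage reports into one summary (input of the first, output of the last)."""
        first, last = reports[0], reports[-1]
        out = QCReport(
            n_cells_in=first.n_cells_in, n_cells_out=last.n_cells_out,
            n_genes_in=first.n_genes_in, n_genes_out=last.n_genes_out)
        for r in reports:
            out.removed_low_gene += r.removed_low_gene
            out.removed_high_mito += r.removed_high_mito
            out.removed_doublets += r.removed_doublets
            out.removed_genes += r.removed_genes
            out.thresholds.update(r.thresholds)
        return out


@dataclass
class DoubletScores:
    """Per-cell doublet scores in [0, 1] with the calibration metadata."""

    scores: np.ndarray
    expected_rate: float
    threshold: float = 0.3

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def flagged(self) -> np.ndarray:
        return self.scores > self.threshold


def filter_cells(m: CellMatrix, min_genes: int = 200,
                 max_mito: float = 0.10) -> tuple[CellMatrix, QCReport]:
    """Remove cells with too few detected genes or too high a mito fraction.

    Kept cells satisfy ``detected >= min_genes`` and ``mito_frac <= max_mito``.
    """
    if min_genes < 0:
        raise ParameterError(f"min_genes must be >= 0, got {min_genes}")
    if not 0.0 <= max_mito <= 1.0:
        raise ParameterError(f"max_mito must be in [0, 1], got {max_mito}")
    counts = m.counts
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    depth = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    mito = m.mito_mask
    mito_counts = np.asarray(counts[:, mito].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(depth > 0, mito_counts / np.maximum(depth, 1e-300), 0.0)
    low_gene = detected < min_genes
    high_mito = mito_frac > max_mito
    keep = ~(low_gene | high_mito)
    report = QCReport(
        n_cells_in=m.n_cells, n_cells_out=int(keep.sum()),
        n_genes_in=m.n_genes, n_genes_out=m.n_genes,
        removed_low_gene=int(low_gene.sum()),
        removed_high_mito=int(high_mito.sum()),
        thresholds={"min_genes": min_genes, "max_mito": max_mito})
    return m.subset_cells(keep), report


def filter_genes(m: CellMatrix, min_cells: int = 3) -> tuple[CellMatrix, QCReport]:
    """Keep genes with nonzero counts in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ParameterError(f"min_cells must be >= 0, got {min_cells}")
    n_expressing = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    keep = n_expressing >= min_cells
    report = QCReport(
        n_cells_in=m.n_cells, n_cells_out=m.n_cells,
        n_genes_in=m.n_genes, n_genes_out=int(keep.sum()),
        removed_genes=int((~keep).sum()),
        thresholds={"min_cells": min_cells})
    return m.subset_genes(keep), report


def normalize_log1p(counts: sp.spmatrix | np.ndarray,
                    scale: float = DEFAULT_SCALE) -> sp.csr_matrix:
    """log1p CP10K: scale each cell to ``scale`` total counts, then ln(1+x).

    Zero-depth cells are rejected — filter first.
    """
    x = sp.csr_matrix(counts, dtype=float)
    depth = np.asarray(x.sum(axis=1)).ravel()
    if np.any(depth <= 0):
        raise ParameterError(
            "matrix contains zero-depth cells; run filter_cells first")
    x = sp.diags(scale / depth) @ x
    x.data = np.log1p(x.data)
    return sp.csr_matrix(x)


def select_hvgs(normalized: sp.spmatrix | np.ndarray, n: int,
                n_bins: int = 20) -> np.ndarray:
    """Top-``n`` highly variable genes by binned standardized dispersion.

    Dispersion is variance/mean of the log-normalized values; genes are
    binned by mean expression and the dispersion z-scored within each bin,
    which removes the trivial mean-dispersion trend. Deterministic; ties
    resolve to the earlier gene.
    """
    if n <= 0:
        raise ParameterError(f"n must be positive, got {n}")
    x = sp.csr_matrix(normalized, dtype=float)
    if n > x.shape[1]:
        raise ParameterError(f"n={n} exceeds {x.shape[1]} genes")
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = sq - mean ** 2
    var[var <= 1e-12 * (1.0 + mean ** 2)] = 0.0  # constant up to rounding
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    # bin genes by mean, z-score dispersion within each occupied bin
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, min(n_bins, len(order)))
    z = np.zeros_like(disp)
    for idx in bins:
        if len(idx) == 0:
            continue
        d = disp[idx]
        sd = d.std()
        z[idx] = (d - d.mean()) / sd if sd > 0 else 0.0
    # never promote a zero-variance gene over one with signal
    z[var == 0] = -np.inf
    ranked = np.argsort(-z, kind="stable")
    return np.sort(ranked[:n]) if n == x.shape[1] else ranked[:n]


class DoubletDetector(BaseEstimator):
    """Simulation-based doublet scoring for a raw count matrix.

    Artificial doublets are synthesized by summing the counts of random
    observed cell pairs, the union is embedded by PCA on log-normalized
    highly variable genes, and each observed cell is scored by the fraction
    of simulated doublets among its k nearest neighbors, calibrated into a
    posterior-like doublet score by the expected doublet rate and the
    simulated/observed ratio.

    Parameters
    ----------
    expected_rate
        Prior fraction of doublets in the data (0 < rate < 1).
    sim_ratio
        Simulated doublets per observed cell.
    n_components
        PCA dimensions for the embedding.
    n_hvgs
        Genes kept for the embedding (capped at the matrix width).
    random_state
        Seed; scores are deterministic given the seed.
    """

    def __init__(self, expected_rate: float = 0.05, sim_ratio: float = 2.0,
                 n_components: int = 30, n_hvgs: int = 1000,
                 random_state: int = 0):
        self.expected_rate = expected_rate
        self.sim_ratio = sim_ratio
        self.n_components = n_components
        self.n_hvgs = n_hvgs
        self.random_state = random_state

    def fit(self, X, y=None):
        """Compute doublet scores for the raw counts ``X`` (cells x genes)."""
        if not 0.0 < self.expected_rate < 1.0:
            raise ParameterError(
                f"expected_rate must be in (0, 1), got {self.expected_rate}")
        counts = sp.csr_matrix(X)
        n_obs = counts.shape[0]
        if n_obs < 20:
            raise ParameterError(f"need at least 20 cells, got {n_obs}")
        rng = np.random.default_rng(self.random_state)

        n_sim = int(round(self.sim_ratio * n_obs))
        a = rng.integers(0, n_obs, size=n_sim)
        b = rng.integers(0, n_obs - 1, size=n_sim)
        b = np.where(b >= a, b + 1, b)  # distinct parents
        sim_counts = counts[a] + counts[b]

        combined = sp.vstack([counts, sim_counts])
        norm = normalize_log1p(combined)
        obs_norm = norm[:n_obs]
        n_hvg = min(self.n_hvgs, counts.shape[1])
        hvgs = select_hvgs(obs_norm, n_hvg)
        sub = np.asarray(norm[:, hvgs].todense())

        n_comp = min(self.n_components, n_obs - 1, sub.shape[1])
        pca = PCA(n_components=n_comp, random_state=self.random_state)
        emb = np.vstack([pca.fit_transform(sub[:n_obs]),
                         pca.transform(sub[n_obs:])])

        n_total = n_obs + n_sim
        k = math.ceil(0.5 * math.sqrt(n_total))
        nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
        _, idx = nn.kneighbors(emb[:n_obs])
        neigh = idx[:, 1:]  # drop self
        n_sim_neigh = (neigh >= n_obs).sum(axis=1)

        # Bayesian-smoothed neighbor fraction, calibrated to a posterior
        # doublet probability given the simulated/observed ratio r and the
        # prior rate rho (Scrublet-style).
        rho, r = self.expected_rate, n_sim / n_obs
        q = (n_sim_neigh + 1) / (k + 2)
        denom = 1.0 - rho - q * (1.0 - rho - rho / r)
        scores = (q * rho / r) / np.maximum(denom, 1e-12)
        self.scores_ = np.clip(scores, 0.0, 1.0)
        self.k_ = k
        self.n_features_in_ = counts.shape[1]
        return self

    def fit_predict(self, X, y=None, threshold: float = 0.3) -> np.ndarray:
        """Boolean doublet calls at ``threshold`` (strict ``>``)."""
        self.fit(X)
        return self.scores_ > threshold


def score_doublets(m: CellMatrix, expected_rate: float = 0.05,
                   seed: int = 0) -> DoubletScores:
    """Score every cell of ``m``; see :class:`DoubletDetector`."""
    det = DoubletDetector(expected_rate=expected_rate, random_state=seed)
    det.fit(m.counts)
    return DoubletScores(scores=det.scores_, expected_rate=expected_rate)


def remove_doublets(m: CellMatrix, s: DoubletScores,
                    threshold: float = 0.3) -> tuple[CellMatrix, QCReport]:
    """Drop exactly the cells with score strictly above ``threshold``."""
    if len(s.scores) != m.n_cells:
        raise ConsistencyError(
            f"{len(s.scores)} scores for {m.n_cells} cells")
    drop = s.scores > threshold
    report = QCReport(
        n_cells_in=m.n_cells, n_cells_out=int((~drop).sum()),
        n_genes_in=m.n_genes, n_genes_out=m.n_genes,
        removed_doublets=int(drop.sum()),
        thresholds={"doublet_threshold": threshold,
                    "expected_doublet_rate": s.expected_rate})
    return m.subset_cells(~drop), report


def run_qc(m: CellMatrix, min_genes: int = 200, max_mito: float = 0.10,
           min_cells: int = 3, expected_rate: float = 0.05,
           doublet_threshold: float = 0.3,
           seed: int = 0) -> tuple[CellMatrix, QCReport]:
    """Full QC chain in order: cell filters, gene filter, doublet removal."""
    m1, r1 = filter_cells(m, min_genes=min_genes, max_mito=max_mito)
    m2, r2 = filter_genes(m1, min_cells=min_cells)
    scores = score_doublets(m2, expected_rate=expected_rate, seed=seed)
    m3, r3 = remove_doublets(m2, scores, threshold=doublet_threshold)
    return m3, QCReport.combine([r1, r2, r3])
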
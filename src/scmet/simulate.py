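"""Synthetic single-cell references and pseudo-bulk mixtures with ground truth.

The generator emulates the two inputs the pipeline consumes: a labelled
single-cell reference and bulk expression profiles of known cell-type
composition. Per-type gene means come from a shared lognormal baseline with
planted, disjoint marker blocks up-regulated by ``2**marker_lfc``; counts
are negative binomial (gamma-Poisson) around per-cell depths drawn
lognormally, reproducing the overdispersion the generator model must learn.
A fraction of genes is named with the ``MT-`` prefix and scaled to a small
fixed share of counts so mitochondrial QC has something realistic to
measure. Cross-type doublets are injected by summing the counts of random
cell pairs of different types. Pseudo-bulk samples are multinomial draws at
a chosen depth from a known mixture of the per-type mean profiles.

Everything is deterministic under the configured seed; the ground truth
(labels, doublet flags, marker lists, type means, mixing proportions) is
returned alongside each matrix so every downstream stage can be scored.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ParameterError
from .types import BulkProfile, CellMatrix

# mitochondrial genes get this fixed share of each type's expected counts,
# well below the 10% QC cut so unmanipulated cells pass
_MITO_SHARE = 0.03


@dataclass
class SimConfig:
    """Knobs of the synthetic reference generator."""

    n_types: int = 3
    n_genes: int = 200
    cells_per_type: int = 500
    marker_frac: float = 0.05
    marker_lfc: float = 3.0        # log2 fold change of planted markers
    nb_dispersion: float = 0.3     # var = m + dispersion * m^2
    depth_log_mean: float = math.log(2000.0)
    depth_log_sd: float = 0.3
    mito_gene_frac: float = 0.05
    doublet_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_types < 1 or self.n_genes < 1 or self.cells_per_type < 1:
            raise ParameterError("n_types, n_genes, cells_per_type must be >= 1")
        for name in ("marker_frac", "mito_gene_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0 or self.depth_log_sd < 0:
            raise ParameterError("dispersion and depth sd must be >= 0")
        if not 0.0 <= self.doublet_rate < 0.5:
            raise ParameterError("doublet_rate must be in [0, 0.5)")
        n_mark = int(round(self.marker_frac * self.n_genes))
        n_mito = int(round(self.mito_gene_frac * self.n_genes))
        if self.n_types * n_mark + n_mito > self.n_genes:
            raise ParameterError(
                "marker blocks and mito genes do not fit into n_genes")


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    cell_types: np.ndarray
    doublet_flags: np.ndarray
    marker_lists: dict[str, np.ndarray]        # gene indices per type
    type_means: dict[str, np.ndarray]          # expected count share per gene
    bulk_proportions: dict[str, float] | None = None
    genes: np.ndarray = field(default=None)


def _nb_counts(mean: np.ndarray, dispersion: float, rng) -> np.ndarray:
    """Gamma-Poisson draw with var = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_reference(cfg: SimConfig) -> tuple[CellMatrix, GroundTruth]:
    """Multi-type NB count matrix with planted markers and mito genes."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G, T, C = cfg.n_genes, cfg.n_types, cfg.cells_per_type
    n_mark = int(round(cfg.marker_frac * G))
    n_mito = int(round(cfg.mito_gene_frac * G))

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    type_names = [f"type{chr(ord('A') + t)}" if t < 26 else f"type{t}"
                  for t in range(T)]
    # disjoint marker blocks at the front, mito genes at the back
    marker_lists = {
        type_names[t]: np.arange(t * n_mark, (t + 1) * n_mark)
        for t in range(T)
    }
    mito_idx = np.arange(G - n_mito, G)
    genes = np.array([f"GENE{i:05d}" for i in range(G)], dtype=object)
    genes[mito_idx] = [f"MT-GENE{i:05d}" for i in mito_idx]

    type_means: dict[str, np.ndarray] = {}
    for t, name in enumerate(type_names):
        mu = baseline.copy()
        mu[marker_lists[name]] *= 2.0 ** cfg.marker_lfc
        if n_mito:
            # pin the mito share of expected counts
            non_mito = mu.sum() - mu[mito_idx].sum()
            target = non_mito * _MITO_SHARE / (1.0 - _MITO_SHARE)
            mu[mito_idx] *= target / mu[mito_idx].sum()
        type_means[name] = mu / mu.sum()

    n_cells = T * C
    labels = np.repeat(type_names, C)
    depths = rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, size=n_cells)
    counts = np.zeros((n_cells, G), dtype=np.int64)
    for i in range(n_cells):
        counts[i] = _nb_counts(depths[i] * type_means[str(labels[i])],
                               cfg.nb_dispersion, rng)

    m = CellMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=np.array([f"CELL{i:06d}" for i in range(n_cells)], dtype=object),
        genes=genes,
        labels=np.asarray(labels, dtype=object))
    gt = GroundTruth(
        cell_types=np.asarray(labels, dtype=object),
        doublet_flags=np.zeros(n_cells, dtype=bool),
        marker_lists=marker_lists,
        type_means=type_means,
        genes=genes)

    if cfg.doublet_rate > 0:
        m, flags = inject_doublets(m, cfg.doublet_rate, seed=cfg.seed + 1)
        gt.cell_types = m.labels
        gt.doublet_flags = flags
    return m, gt


def inject_doublets(m: CellMatrix, rate: float,
                    seed: int = 0) -> tuple[CellMatrix, np.ndarray]:
    """Append ``ceil(rate * n)`` cross-type pair-sum cells; flags mark them."""
    if not 0.0 <= rate < 0.5:
        raise ParameterError(f"rate must be in [0, 0.5), got {rate}")
    if m.labels is None or len(set(m.labels)) < 2:
        raise ParameterError("cross-type doublets need >= 2 labelled types")
    n = m.n_cells
    n_dbl = math.ceil(rate * n)
    flags = np.zeros(n + n_dbl, dtype=bool)
    if n_dbl == 0:
        return m, flags[:n]
    rng = np.random.default_rng(seed)
    a = rng.integers(0, n, size=n_dbl)
    b = np.empty(n_dbl, dtype=int)
    for i, ai in enumerate(a):  # resample partner until the type differs
        bi = rng.integers(0, n)
        while m.labels[bi] == m.labels[ai]:
            bi = rng.integers(0, n)
        b[i] = bi
    dbl_counts = m.counts[a] + m.counts[b]
    out = CellMatrix(
        counts=sp.vstack([m.counts, dbl_counts], format="csr"),
        barcodes=np.concatenate([m.barcodes,
                                 [f"DBL{i:06d}" for i in range(n_dbl)]]),
        genes=m.genes,
        labels=np.concatenate([m.labels, m.labels[a]]),
        mito_prefix=m.mito_prefix, mito_genes=m.mito_genes)
    flags[n:] = True
    return out, flags


def simulate_bulk(gt: GroundTruth, proportions: dict[str, float],
                  depth: int = 1_000_000, seed: int = 0,
                  sample_id: str = "bulk") -> tuple[BulkProfile, dict[str, float]]:
    """Multinomial pseudo-bulk at known mixing proportions.

    The expected gene vector is the proportion-weighted mixture of the
    per-type mean profiles; realized counts are one multinomial draw of
    size ``depth``.
    """
    types = list(proportions)
    p = np.array([proportions[t] for t in types], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ParameterError("proportions must be nonnegative and sum to 1")
    missing = [t for t in types if t not in gt.type_means]
    if missing:
        raise ParameterError(f"unknown types in proportions: {missing}")
    expected = np.zeros(len(gt.genes))
    for t, w in zip(types, p):
        expected += w * gt.type_means[t]
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, expected / expected.sum())
    profile = BulkProfile(sample_id=sample_id, values=counts.astype(float),
                          genes=gt.genes, unit="counts")
    return profile, dict(proportions)
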
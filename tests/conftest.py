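"""Shared fixtures: planted QC matrices and a trained generator.

Everything is generated programmatically and seeded; the expensive pieces
(the 1,278-cell reference and the CVAE trained on it) are session-scoped
and shared between the unit and acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

import scmet


def build_qc_fixture(seed: int = 0):
    """100-cell matrix with 7 planted low-gene cells, 5 high-mito cells
    (1 cell in both sets), and genes expressed in exactly 2 or 3 cells.

    Returns (CellMatrix, expected_retained, low_gene_idx, high_mito_idx,
    two_cell_gene_idx, three_cell_gene_idx).
    """
    rng = np.random.default_rng(seed)
    n_cells, n_genes = 100, 300
    n_mito = 10
    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    # normal cells: 250 detected genes, low mito share
    for i in range(n_cells):
        on = rng.choice(n_genes - n_mito, size=250 - n_mito, replace=False)
        counts[i, on] = rng.integers(1, 6, size=len(on))
        counts[i, n_genes - n_mito:] = 1  # mito well under 10% of depth
    low_gene = np.array([3, 11, 19, 27, 35, 43, 51])
    high_mito = np.array([51, 60, 70, 80, 90])  # cell 51 in both sets
    for i in low_gene:
        counts[i] = 0
        on = rng.choice(n_genes - n_mito, size=150, replace=False)
        counts[i, on] = 1  # 150 detected genes < 200
    for i in high_mito:
        depth = counts[i].sum()
        counts[i, n_genes - n_mito] = int(0.25 * depth)  # mito frac > 10%
    # planted rare genes, in cells that survive the cell filters
    survivors = [c for c in range(n_cells)
                 if c not in set(low_gene) | set(high_mito)]
    two_cell_gene, three_cell_gene = 0, 1
    counts[:, two_cell_gene] = 0
    counts[:, three_cell_gene] = 0
    counts[survivors[:2], two_cell_gene] = 1
    counts[survivors[:3], three_cell_gene] = 1
    genes = np.array(
        [f"GENE{i:04d}" for i in range(n_genes - n_mito)]
        + [f"MT-GENE{i:02d}" for i in range(n_mito)], dtype=object)
    m = scmet.CellMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=np.array([f"C{i:03d}" for i in range(n_cells)], dtype=object),
        genes=genes)
    expected_retained = n_cells - len(set(low_gene) | set(high_mito))
    return m, expected_retained, low_gene, high_mito, two_cell_gene, three_cell_gene


@pytest.fixture(scope="session")
def qc_fixture():
    return build_qc_fixture()


@pytest.fixture(scope="session")
def small_reference():
    """3-type, 200-gene, 300-cell labelled reference with ground truth."""
    cfg = scmet.SimConfig(n_types=3, n_genes=200, cells_per_type=100, seed=11)
    m, gt = scmet.simulate_reference(cfg)
    norm = np.asarray(scmet.normalize_log1p(m.counts).todense())
    return m, gt, norm


@pytest.fixture(scope="session")
def reference_1278():
    """Small-sample training regime: 3 types x 426 cells = 1,278 cells."""
    cfg = scmet.SimConfig(n_types=3, n_genes=200, cells_per_type=426, seed=3)
    m, gt = scmet.simulate_reference(cfg)
    norm = np.asarray(scmet.normalize_log1p(m.counts).todense())
    return m, gt, norm


@pytest.fixture(scope="session")
def trained_model(reference_1278):
    """CVAE trained on the 1,278-cell reference (shared across tests)."""
    m, gt, norm = reference_1278
    model, trace = scmet.train_cvae(norm, m.labels, gene_list=m.genes,
                                    max_epochs=60, random_state=0)
    return model, trace


@pytest.fixture(scope="session")
def tiny_model():
    """Minimal trained model for serialization and API contracts."""
    cfg = scmet.SimConfig(n_types=2, n_genes=50, cells_per_type=30, seed=5)
    m, _ = scmet.simulate_reference(cfg)
    norm = np.asarray(scmet.normalize_log1p(m.counts).todense())
    model, _ = scmet.train_cvae(norm, m.labels, gene_list=m.genes,
                                max_epochs=5, latent_dim=8, hidden1=32,
                                hidden2=16, random_state=2)
    return model
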
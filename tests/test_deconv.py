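"""Marker ranking, signature construction and NNLS proportion recovery."""
import itertools

import numpy as np
import pytest

import scmet
from scmet.deconv import _bulk_to_signature_space


def simplex_grid_residual(S, b, step=0.02):
    """Brute-force oracle: best residual over a simplex grid of proportions."""
    n = S.shape[1]
    best = np.inf
    ticks = int(round(1 / step))
    for combo in itertools.product(range(ticks + 1), repeat=n - 1):
        if sum(combo) > ticks:
            continue
        p = np.array(list(combo) + [ticks - sum(combo)], dtype=float) / ticks
        best = min(best, np.linalg.norm(S @ p - b))
    return best


@pytest.fixture(scope="module")
def fitted(small_reference):
    m, gt, norm = small_reference
    dec = scmet.SignatureDeconvolver(markers_per_type=10)
    dec.fit(norm, m.labels, genes=m.genes)
    return m, gt, norm, dec


class TestRankMarkers:
    def test_planted_markers_top_ranked(self, small_reference):
        m, gt, norm = small_reference
        k = len(next(iter(gt.marker_lists.values())))
        ranked = scmet.rank_markers(norm, m.labels, k=k)
        for t, planted in gt.marker_lists.items():
            assert set(int(g) for g in ranked[t]) == set(int(g) for g in planted)

    def test_k_one_gives_one_marker_per_type(self, small_reference):
        m, _, norm = small_reference
        ranked = scmet.rank_markers(norm, m.labels, k=1)
        assert all(len(v) == 1 for v in ranked.values())

    def test_flat_gene_never_outranks_planted_marker(self, small_reference):
        m, gt, norm = small_reference
        ranked = scmet.rank_markers(norm, m.labels, k=norm.shape[1],
                                    min_frac=0.0)
        for t, planted in gt.marker_lists.items():
            order = list(ranked[t])
            worst_marker = max(order.index(int(g)) for g in planted)
            # every planted marker of the type ranks above any non-marker
            assert worst_marker < len(planted) + 5

    def test_oversized_k_capped_with_warning(self, small_reference):
        m, _, norm = small_reference
        with pytest.warns(UserWarning, match="capping"):
            ranked = scmet.rank_markers(norm, m.labels, k=10 ** 6)
        assert all(len(v) <= norm.shape[1] for v in ranked.values())


class TestSignature:
    def test_cell_order_invariance(self, small_reference):
        m, _, norm = small_reference
        markers = scmet.rank_markers(norm, m.labels, k=5)
        sig1 = scmet.compute_signature(norm, m.labels, markers, genes=m.genes)
        rng = np.random.default_rng(3)
        perm = rng.permutation(norm.shape[0])
        sig2 = scmet.compute_signature(norm[perm], m.labels[perm], markers,
                                       genes=m.genes)
        assert np.allclose(sig1.S, sig2.S)

    def test_shared_marker_appears_once(self, small_reference):
        m, _, norm = small_reference
        markers = {"typeA": np.array([0, 1]), "typeB": np.array([1, 2])}
        sig = scmet.compute_signature(norm, m.labels, markers, genes=m.genes)
        assert len(sig.markers) == 3

    def test_single_type_signature(self, small_reference):
        m, _, norm = small_reference
        sig = scmet.compute_signature(norm, m.labels,
                                      {"typeA": np.array([0, 1, 2])},
                                      genes=m.genes)
        mask = m.labels.astype(str) == "typeA"
        expected = np.expm1(norm[mask][:, :3]).mean(axis=0)
        assert np.allclose(sig.S[:, 0], expected)

    def test_empty_union_rejected(self, small_reference):
        m, _, norm = small_reference
        with pytest.raises(scmet.ParameterError):
            scmet.compute_signature(norm, m.labels, {"typeA": np.array([])})


class TestEstimateProportions:
    def test_signature_column_recovers_one_hot(self, fitted):
        m, gt, norm, dec = fitted
        sig = dec.signature_
        for j, t in enumerate(sig.types):
            bulk = scmet.BulkProfile(f"pure_{t}", sig.S[:, j], sig.markers)
            p = scmet.estimate_proportions(bulk, sig)
            expected = np.zeros(len(sig.types))
            expected[j] = 1.0
            assert np.allclose(p.fractions, expected, atol=1e-8)

    def test_log_space_mixture_recovers_half_half(self, small_reference):
        """Bulk constructed in log space under the log-space solver."""
        m, _, norm = small_reference
        markers = scmet.rank_markers(norm, m.labels, k=10)
        sig = scmet.compute_signature(norm, m.labels, markers, genes=m.genes,
                                      space="log")
        target = 0.5 * sig.S[:, 0] + 0.5 * sig.S[:, 1]
        lin = np.expm1(target)
        filler = 1e4 - lin.sum()
        assert filler > 0
        bulk = scmet.BulkProfile(
            "mix", np.concatenate([lin, [filler]]),
            np.concatenate([sig.markers, ["FILLER"]]))
        b, rows = _bulk_to_signature_space(bulk, sig)
        assert np.allclose(b, target)
        p = scmet.estimate_proportions(bulk, sig)
        expected = np.zeros(len(sig.types))
        expected[:2] = 0.5
        assert np.allclose(p.fractions, expected, atol=1e-6)
        # grid-search oracle agrees on the residual
        assert p.residual <= simplex_grid_residual(sig.S[rows], b) + 1e-6

    def test_nnls_beats_simplex_grid(self, fitted):
        m, gt, norm, dec = fitted
        sig = dec.signature_
        bulk, _ = scmet.simulate_bulk(
            gt, {"typeA": 0.6, "typeB": 0.3, "typeC": 0.1},
            depth=10 ** 6, seed=1)
        p = scmet.estimate_proportions(bulk, sig)
        b, rows = _bulk_to_signature_space(bulk, sig)
        assert p.residual <= simplex_grid_residual(sig.S[rows], b) + 1e-6

    def test_scale_invariance(self, fitted):
        m, gt, norm, dec = fitted
        bulk, _ = scmet.simulate_bulk(
            gt, {"typeA": 0.5, "typeB": 0.25, "typeC": 0.25},
            depth=10 ** 5, seed=2)
        p1 = scmet.estimate_proportions(bulk, dec.signature_)
        scaled = scmet.BulkProfile(bulk.sample_id, bulk.values * 37.5,
                                   bulk.genes)
        p2 = scmet.estimate_proportions(scaled, dec.signature_)
        assert np.allclose(p1.fractions, p2.fractions)

    def test_proportions_on_simplex(self, fitted):
        m, gt, norm, dec = fitted
        for seed in range(5):
            bulk, _ = scmet.simulate_bulk(
                gt, {"typeA": 0.2, "typeB": 0.3, "typeC": 0.5},
                depth=10 ** 5, seed=seed)
            p = scmet.estimate_proportions(bulk, dec.signature_)
            assert np.all(p.fractions >= 0)
            assert p.fractions.sum() == pytest.approx(1.0)

    def test_recovery_mae_under_five_percent(self, fitted):
        m, gt, norm, dec = fitted
        truth = np.array([0.6, 0.3, 0.1])
        errs = []
        for seed in range(20):
            bulk, _ = scmet.simulate_bulk(
                gt, {"typeA": 0.6, "typeB": 0.3, "typeC": 0.1},
                depth=10 ** 6, seed=seed)
            p = scmet.estimate_proportions(bulk, dec.signature_)
            errs.append(np.abs(p.fractions - truth).mean())
        assert np.mean(errs) < 0.05

    def test_all_zero_bulk_rejected(self, fitted):
        sig = fitted[3].signature_
        bulk = scmet.BulkProfile("z", np.zeros(len(sig.markers)), sig.markers)
        with pytest.raises(scmet.ParameterError):
            scmet.estimate_proportions(bulk, sig)

    def test_too_few_shared_genes_rejected(self, fitted):
        sig = fitted[3].signature_
        bulk = scmet.BulkProfile("few", np.array([5.0]),
                                 np.array([sig.markers[0]], dtype=object))
        with pytest.raises(scmet.ConsistencyError):
            scmet.estimate_proportions(bulk, sig)


class TestSweep:
    def test_all_k_under_l1_bound(self, small_reference):
        m, gt, norm = small_reference
        props = [{"typeA": 0.6, "typeB": 0.3, "typeC": 0.1},
                 {"typeA": 0.2, "typeB": 0.5, "typeC": 0.3}]
        bulks, truths = [], []
        for i, pr in enumerate(props):
            b, tr = scmet.simulate_bulk(gt, pr, depth=10 ** 6, seed=30 + i)
            bulks.append(b)
            truths.append(tr)
        table = scmet.sweep_marker_count(norm, m.labels, bulks, truths,
                                         k_values=[5, 10, 25, 50],
                                         genes=m.genes)
        assert len(table) == 4
        assert (table["mean_l1_error"] < 0.10).all()

    def test_single_k_single_row(self, small_reference):
        m, gt, norm = small_reference
        b, tr = scmet.simulate_bulk(
            gt, {"typeA": 1 / 3, "typeB": 1 / 3, "typeC": 1 / 3},
            depth=10 ** 5, seed=0)
        table = scmet.sweep_marker_count(norm, m.labels, [b], [tr],
                                         k_values=[10], genes=m.genes)
        assert len(table) == 1
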
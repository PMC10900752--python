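"""Allocation arithmetic, similarity metrics and the selection hill climb."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scmet


class TestAllocateCounts:
    def test_exact_apportionment(self):
        alloc = scmet.allocate_counts({"A": 0.5, "B": 0.3, "C": 0.2}, 10)
        assert list(alloc.counts) == [5, 3, 2]

    def test_largest_remainder_tie_goes_to_first_type(self):
        alloc = scmet.allocate_counts({"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}, 10)
        assert list(alloc.counts) == [4, 3, 3]

    def test_zero_total(self):
        alloc = scmet.allocate_counts({"A": 0.7, "B": 0.3}, 0)
        assert list(alloc.counts) == [0, 0] and alloc.total == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 500),
           st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    def test_sums_to_n_and_within_one_seat(self, N, weights):
        w = np.array(weights) / np.sum(weights)
        p = {f"T{i}": float(x) for i, x in enumerate(w)}
        alloc = scmet.allocate_counts(p, N)
        assert alloc.total == N
        shares = w * N
        assert np.all(np.abs(alloc.counts - shares) < 1.0)


class TestPseudobulkAndSimilarity:
    def test_single_cell_selection_is_identity(self):
        pool = np.arange(12.0).reshape(3, 4)
        assert np.allclose(scmet.pseudobulk(pool, [1]), pool[1])

    def test_duplicate_selection_same_as_once(self):
        pool = np.arange(12.0).reshape(3, 4)
        assert np.allclose(scmet.pseudobulk(pool, [2, 2]),
                           scmet.pseudobulk(pool, [2]))

    def test_full_selection_equals_column_means(self):
        rng = np.random.default_rng(0)
        pool = rng.random((10, 6))
        assert np.allclose(scmet.pseudobulk(pool, np.arange(10)),
                           pool.mean(axis=0))

    def test_empty_selection_rejected(self):
        with pytest.raises(scmet.ParameterError):
            scmet.pseudobulk(np.ones((3, 2)), [])

    def test_identical_vectors(self):
        b = np.array([1.0, 2.0, 3.0])
        assert scmet.similarity(b, b) == (1.0, 0.0)

    def test_scale_invariance(self):
        b = np.array([1.0, 2.0, 3.0])
        r, d = scmet.similarity(b, 2 * b)
        assert r == pytest.approx(1.0) and d == pytest.approx(0.0)

    def test_perturbation_matches_naive_formulas(self):
        rng = np.random.default_rng(1)
        b = rng.random(50)
        q = b.copy()
        q[7] += 0.5
        r, d = scmet.similarity(b, q)
        # naive oracle computed from the definitions
        r_naive = (np.sum((b - b.mean()) * (q - q.mean()))
                   / np.sqrt(np.sum((b - b.mean()) ** 2)
                             * np.sum((q - q.mean()) ** 2)))
        d_naive = np.sqrt(np.sum(
            (b / np.linalg.norm(b) - q / np.linalg.norm(q)) ** 2))
        assert r == pytest.approx(r_naive) and r < 1
        assert d == pytest.approx(d_naive) and d > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(scmet.ParameterError):
            scmet.similarity(np.ones(5), np.arange(5.0))


def make_attainable_pool(seed=0, n_genes=60):
    """Pool where every type's cells equal the type profile exactly, and the
    bulk is the allocation-weighted mean: the optimum r=1 is attainable."""
    rng = np.random.default_rng(seed)
    profiles = {t: rng.random(n_genes) + 0.1 for t in ("A", "B")}
    alloc = scmet.Allocation(types=["A", "B"], counts=np.array([6, 4]))
    rows, labels = [], []
    for t, n in alloc.as_dict().items():
        for _ in range(5 * n):
            rows.append(profiles[t])
            labels.append(t)
    pool = scmet.GenerationBatch(matrix=np.array(rows),
                                 labels=np.array(labels, dtype=object))
    bulk = 0.6 * profiles["A"] + 0.4 * profiles["B"]
    return bulk, pool, alloc


class TestFitSample:
    def test_attainable_optimum_is_reached(self):
        bulk, pool, alloc = make_attainable_pool()
        fit = scmet.fit_sample(bulk, pool, alloc,
                               scmet.FitConfig(seed=0))
        assert fit.pearson_r >= 0.99

    def test_trace_strictly_increasing_and_composition_kept(self,
                                                            trained_model,
                                                            reference_1278):
        model, _ = trained_model
        m, gt, norm = reference_1278
        alloc = scmet.allocate_counts(
            {"typeA": 0.5, "typeB": 0.3, "typeC": 0.2}, 200)
        pool = scmet.build_pool(model, {t: 10 * c for t, c
                                        in alloc.as_dict().items()}, seed=1)
        bulk, _ = scmet.simulate_bulk(gt, {"typeA": 0.5, "typeB": 0.3,
                                           "typeC": 0.2}, depth=10 ** 6,
                                      seed=2)
        vec, keep = scmet.bulk_to_model_space(bulk, model.gene_list_)
        sub = scmet.GenerationBatch(pool.matrix[:, keep], pool.labels)
        for seed in range(5):
            fit = scmet.fit_sample(vec, sub, alloc,
                                   scmet.FitConfig(seed=seed))
            assert np.all(np.diff(fit.trace) > 0)
            picked = pool.labels[fit.selected]
            for t, c in alloc.as_dict().items():
                assert (picked == t).sum() == c

    def test_final_objective_never_below_initial(self):
        bulk, pool, alloc = make_attainable_pool(seed=3)
        rng = np.random.default_rng(4)
        noisy = scmet.GenerationBatch(
            pool.matrix + 0.3 * rng.random(pool.matrix.shape),
            pool.labels)
        for seed in range(20):
            fit = scmet.fit_sample(bulk, noisy, alloc,
                                   scmet.FitConfig(seed=seed))
            assert fit.trace[-1] >= fit.trace[0]
            assert fit.pearson_r >= -1 and fit.euclid_d >= 0

    def test_seed_determinism(self):
        bulk, pool, alloc = make_attainable_pool(seed=5)
        a = scmet.fit_sample(bulk, pool, alloc, scmet.FitConfig(seed=11))
        b = scmet.fit_sample(bulk, pool, alloc, scmet.FitConfig(seed=11))
        assert np.array_equal(a.selected, b.selected)
        assert a.trace == b.trace

    def test_insufficient_pool_names_type(self):
        bulk, pool, alloc = make_attainable_pool()
        starved = scmet.Allocation(types=["A", "B"],
                                   counts=np.array([10 ** 4, 1]))
        with pytest.raises(scmet.CapacityError, match="'A'"):
            scmet.fit_sample(bulk, pool, starved, scmet.FitConfig(seed=0))


@pytest.fixture(scope="module")
def cohort(trained_model, reference_1278):
    model, _ = trained_model
    m, gt, norm = reference_1278
    props = [{"typeA": 0.6, "typeB": 0.3, "typeC": 0.1},
             {"typeA": 0.2, "typeB": 0.5, "typeC": 0.3},
             {"typeA": 1 / 3, "typeB": 1 / 3, "typeC": 1 / 3}]
    bulks = [scmet.simulate_bulk(gt, p, depth=10 ** 6, seed=40 + i,
                                 sample_id=f"s{i}")[0]
             for i, p in enumerate(props)]
    cfg = scmet.CohortConfig(cells_per_sample=500, pool_factor=10, seed=7)
    return scmet.fit_cohort(bulks, model, norm, m.labels, config=cfg)


class TestFitCohort:
    def test_cohort_shape(self, cohort):
        assert cohort.matrix.shape[0] == 3 * 500
        assert len(cohort.fits) == 3

    def test_per_sample_composition_equals_allocation(self, cohort):
        for fit in cohort.fits:
            sid = fit.sample_id
            mask = cohort.sample_ids == sid
            picked = cohort.cell_types[mask]
            for t, c in fit.allocation.as_dict().items():
                assert (picked == t).sum() == c

    def test_per_sample_correlation_exceeds_point_nine(self, cohort):
        assert all(f.pearson_r >= 0.9 for f in cohort.fits)

    def test_cohort_written_outputs(self, trained_model, reference_1278,
                                    tmp_path):
        model, _ = trained_model
        m, gt, norm = reference_1278
        bulk, _ = scmet.simulate_bulk(gt, {"typeA": 0.5, "typeB": 0.25,
                                           "typeC": 0.25}, depth=10 ** 5,
                                      seed=1, sample_id="w0")
        cfg = scmet.CohortConfig(cells_per_sample=60, pool_factor=5, seed=3)
        scmet.fit_cohort([bulk], model, norm, m.labels, config=cfg,
                         out_dir=tmp_path / "out")
        for name in ("matrix.mtx", "barcodes.tsv", "features.tsv",
                     "cell_metadata.tsv", "fit_report.json"):
            assert (tmp_path / "out" / name).exists()

    def test_empty_cohort_rejected(self, trained_model, reference_1278):
        model, _ = trained_model
        m, _, norm = reference_1278
        with pytest.raises(scmet.ParameterError):
            scmet.fit_cohort([], model, norm, m.labels)
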
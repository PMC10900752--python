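"""Pseudo-bulk matching: select generated cells to reproduce a bulk profile.

Given a bulk sample's estimated cell-type proportions, the target cell
number is apportioned to types by largest remainder, a candidate pool of
generated cells is drawn per type, and a seeded hill climb cyclically
proposes per-type batch swaps (replace a random subset of the current
selection with unused same-type pool cells), accepting a proposal only when
it strictly improves the combined objective

    J = pearson_r(bulk, pseudobulk) - lambda * euclid_d(bulk, pseudobulk)

where the Euclidean distance is taken between L2-normalized vectors so both
terms are scale-free. The accepted-step trace is therefore strictly
increasing, the final selection is never worse than the initial random one,
and per-type counts always equal the allocation.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cvae import CVAEGenerator, GenerationBatch, build_pool
from .deconv import ProportionVector, SignatureDeconvolver, estimate_proportions
from .errors import CapacityError, ConsistencyError, ParameterError
from .qc import DEFAULT_SCALE
from .types import BulkProfile


@dataclass
class Allocation:
    """Integer cells-per-type summing to the requested total."""

    types: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ParameterError("allocation counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, int]:
        return {t: int(c) for t, c in zip(self.types, self.counts)}


@dataclass
class FitConfig:
    """Hill-climb controls for one sample."""

    max_rounds: int = 20
    swap_batch: float = 0.1
    lam: float = 0.1
    patience: int = 3
    seed: int = 0


@dataclass
class FitResult:
    """Outcome of fitting one bulk sample."""

    sample_id: str
    selected: np.ndarray          # indices into the pool
    allocation: Allocation
    pearson_r: float
    euclid_d: float
    trace: list[float] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "sample_id": self.sample_id,
            "selected": [int(i) for i in self.selected],
            "allocation": self.allocation.as_dict(),
            "pearson_r": self.pearson_r,
            "euclid_d": self.euclid_d,
            "objective_trace": self.trace,
            "seed": self.seed,
        }, indent=2)


def allocate_counts(p: ProportionVector | dict[str, float], N: int) -> Allocation:
    """Largest-remainder apportionment of ``p * N`` into integers.

    Floors each share and hands the remaining seats to the largest
    fractional parts, earlier type first on ties.
    """
    if N < 0:
        raise ParameterError(f"N must be >= 0, got {N}")
    if isinstance(p, ProportionVector):
        types, fracs = list(p.types), np.asarray(p.fractions, dtype=float)
    else:
        types = list(p)
        fracs = np.array([p[t] for t in types], dtype=float)
    shares = fracs * N
    counts = np.floor(shares).astype(int)
    leftover = N - counts.sum()
    order = np.argsort(-(shares - counts), kind="stable")
    for i in range(int(leftover)):
        counts[order[i]] += 1
    return Allocation(types=types, counts=counts)


def pseudobulk(pool: GenerationBatch | np.ndarray, selection) -> np.ndarray:
    """Per-gene mean of the selected cells' normalized expression."""
    mat = pool.matrix if isinstance(pool, GenerationBatch) else np.asarray(pool)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ParameterError("selection is empty")
    return mat[selection].mean(axis=0)


def similarity(b: np.ndarray, q: np.ndarray) -> tuple[float, float]:
    """(Pearson r, Euclidean distance of L2-normalized vectors)."""
    b = np.asarray(b, dtype=float)
    q = np.asarray(q, dtype=float)
    if b.shape != q.shape:
        raise ConsistencyError(f"shape mismatch {b.shape} vs {q.shape}")
    if b.std() == 0 or q.std() == 0:
        raise ParameterError("zero-variance vector: correlation undefined")
    r = float(np.corrcoef(b, q)[0, 1])
    bn = b / np.linalg.norm(b)
    qn = q / np.linalg.norm(q)
    return r, float(np.linalg.norm(bn - qn))


def _objective(b, q, lam: float) -> tuple[float, float, float]:
    r, d = similarity(b, q)
    return r - lam * d, r, d


def fit_sample(bulk_vec: np.ndarray, pool: GenerationBatch, alloc: Allocation,
               config: FitConfig | None = None,
               sample_id: str = "sample") -> FitResult:
    """Hill-climb a per-type cell selection whose pseudo-bulk matches ``bulk_vec``.

    ``bulk_vec`` must already be in the pool's normalized gene space.
    """
    cfg = config or FitConfig()
    rng = np.random.default_rng(cfg.seed)
    labels = pool.labels.astype(str)
    by_type = {t: np.flatnonzero(labels == t) for t in alloc.types}
    for t, need in alloc.as_dict().items():
        if need > len(by_type.get(t, ())):
            raise CapacityError(
                f"pool has {len(by_type.get(t, ()))} cells of type {t!r} "
                f"but the allocation needs {need}")

    # seeded initial selection honoring the allocation, in type order
    selected: dict[str, np.ndarray] = {}
    for t in alloc.types:
        need = alloc.as_dict()[t]
        selected[t] = rng.choice(by_type[t], size=need, replace=False) \
            if need else np.array([], dtype=int)

    N = alloc.total
    if N == 0:
        raise ParameterError("allocation is empty; nothing to fit")
    total = pool.matrix[np.concatenate([selected[t] for t in alloc.types])].sum(axis=0)
    J, r, d = _objective(bulk_vec, total / N, cfg.lam)
    trace = [J]

    stall = 0
    for _ in range(cfg.max_rounds):
        improved = False
        for t in alloc.types:
            need = alloc.as_dict()[t]
            if need == 0:
                continue
            unused = np.setdiff1d(by_type[t], selected[t], assume_unique=False)
            if len(unused) == 0:
                continue
            m = min(math.ceil(cfg.swap_batch * need), need, len(unused))
            drop_pos = rng.choice(need, size=m, replace=False)
            add = rng.choice(unused, size=m, replace=False)
            drop = selected[t][drop_pos]
            new_total = total - pool.matrix[drop].sum(axis=0) \
                + pool.matrix[add].sum(axis=0)
            newJ, new_r, new_d = _objective(bulk_vec, new_total / N, cfg.lam)
            if newJ > J:
                sel = selected[t].copy()
                sel[drop_pos] = add
                selected[t] = sel
                total = new_total
                J, r, d = newJ, new_r, new_d
                trace.append(J)
                improved = True
        if improved:
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    final = np.concatenate([selected[t] for t in alloc.types])
    return FitResult(sample_id=sample_id, selected=final, allocation=alloc,
                     pearson_r=r, euclid_d=d, trace=trace, seed=cfg.seed)


@dataclass
class CohortConfig:
    """End-to-end controls for converting a bulk cohort."""

    cells_per_sample: int = 1000
    markers_per_type: int = 25
    pool_factor: int = 10
    sigma_scale: float = 1.0
    max_rounds: int = 20
    swap_batch: float = 0.1
    lam: float = 0.1
    patience: int = 3
    seed: int = 0


@dataclass
class CohortResult:
    """Fitted cohort: one normalized expression matrix with cell metadata."""

    matrix: np.ndarray
    genes: np.ndarray
    sample_ids: np.ndarray
    cell_types: np.ndarray
    fits: list[FitResult]
    proportions: dict[str, dict[str, float]]


def bulk_to_model_space(bulk: BulkProfile, gene_list,
                        scale: float = DEFAULT_SCALE) -> tuple[np.ndarray, np.ndarray]:
    """Log-normalize the bulk vector and align it to the model's gene list.

    Returns the aligned log CP10K vector and the indices of the model genes
    found in the bulk (the shared gene space used for similarity).
    """
    gene_list = np.asarray(gene_list, dtype=object)
    total = bulk.values.sum()
    if total <= 0:
        raise ParameterError(f"bulk sample {bulk.sample_id!r} is all zero")
    logged = np.log1p(scale * bulk.values / total)
    idx = {g: i for i, g in enumerate(bulk.genes)}
    keep = np.array([j for j, g in enumerate(gene_list) if g in idx], dtype=int)
    if keep.size == 0:
        raise ConsistencyError(
            f"no genes shared between bulk {bulk.sample_id!r} and the model")
    vec = np.array([logged[idx[gene_list[j]]] for j in keep])
    return vec, keep


def fit_cohort(bulks: list[BulkProfile], model: CVAEGenerator,
               reference_X, reference_labels,
               config: CohortConfig | None = None,
               out_dir: str | Path | None = None) -> CohortResult:
    """Deconvolve, allocate, generate and fit every bulk sample.

    Selected cells from all samples are concatenated into one normalized
    matrix with per-cell sample and type metadata; with ``out_dir`` the
    matrix is written as an ``.mtx`` bundle plus ``cell_metadata.tsv`` and
    ``fit_report.json``.
    """
    if not bulks:
        raise ParameterError("need at least one bulk sample")
    cfg = config or CohortConfig()
    dec = SignatureDeconvolver(markers_per_type=cfg.markers_per_type)
    dec.fit(reference_X, reference_labels, genes=model.gene_list_)

    children = np.random.SeedSequence(cfg.seed).spawn(len(bulks))
    rows, samples, ctypes, fits = [], [], [], []
    proportions: dict[str, dict[str, float]] = {}
    for bulk, child in zip(bulks, children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        try:
            pv = estimate_proportions(bulk, dec.signature_)
            alloc = allocate_counts(pv, cfg.cells_per_sample)
            sizes = {t: cfg.pool_factor * c for t, c in alloc.as_dict().items()}
            pool = build_pool(model, sizes, sigma_scale=cfg.sigma_scale,
                              seed=sub_seed)
            bulk_vec, keep = bulk_to_model_space(bulk, model.gene_list_)
            sub_pool = GenerationBatch(matrix=pool.matrix[:, keep],
                                       labels=pool.labels,
                                       sigma_scale=pool.sigma_scale)
            fit = fit_sample(
                bulk_vec, sub_pool, alloc,
                FitConfig(max_rounds=cfg.max_rounds, swap_batch=cfg.swap_batch,
                          lam=cfg.lam, patience=cfg.patience, seed=sub_seed),
                sample_id=bulk.sample_id)
        except Exception as exc:
            raise type(exc)(f"sample {bulk.sample_id!r}: {exc}") from exc
        proportions[bulk.sample_id] = pv.as_dict()
        fits.append(fit)
        rows.append(pool.matrix[fit.selected])
        samples.extend([bulk.sample_id] * len(fit.selected))
        ctypes.extend(pool.labels[fit.selected])

    result = CohortResult(
        matrix=np.vstack(rows),
        genes=np.asarray(model.gene_list_, dtype=object),
        sample_ids=np.array(samples, dtype=object),
        cell_types=np.array(ctypes, dtype=object),
        fits=fits, proportions=proportions)
    if out_dir is not None:
        _write_cohort(result, Path(out_dir))
    return result


def _write_cohort(result: CohortResult, out_dir: Path) -> None:
    import scipy.io
    import scipy.sparse as sp

    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"),
                     sp.coo_matrix(result.matrix.T), field="real")
    (out_dir / "barcodes.tsv").write_text(
        "".join(f"CELL{i:07d}\n" for i in range(result.matrix.shape[0])))
    (out_dir / "features.tsv").write_text(
        "".join(f"{g}\n" for g in result.genes))
    with open(out_dir / "cell_metadata.tsv", "w") as fh:
        fh.write("barcode\tsample_id\tcell_type\n")
        for i, (s, t) in enumerate(zip(result.sample_ids, result.cell_types)):
            fh.write(f"CELL{i:07d}\t{s}\t{t}\n")
    report = {f.sample_id: json.loads(f.to_json()) for f in result.fits}
    for sid, props in result.proportions.items():
        report[sid]["proportions"] = props
    (out_dir / "fit_report.json").write_text(json.dumps(report, indent=2))
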
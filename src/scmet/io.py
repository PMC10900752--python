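"""Readers and writers for the formats the pipeline touches.

Single-cell matrices travel as 10x-style Matrix Market bundles
(``matrix.mtx[.gz]`` + ``barcodes.tsv[.gz]`` + ``features.tsv[.gz]``,
genes x cells on disk, 1-based per the Matrix Market standard; cells x genes
and 0-based in memory). Bulk expression travels as gene x sample TSV/CSV
tables. Trained generator models are serialized as an ``.npz`` weight blob
plus a human-readable JSON metadata sidecar; the sidecar stores a SHA-256 of
the blob and a hash of the gene list / label vocabulary so corruption or
tampering is detected on load.
"""
from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConsistencyError, FormatError, IntegrityError, ParseError
from .types import BulkProfile, CellMatrix

_LABELS_FILE = "labels.tsv"


def _find(dir_path: Path, *names: str) -> Path:
    for name in names:
        for cand in (dir_path / name, dir_path / (name + ".gz")):
            if cand.exists():
                return cand
    raise FormatError(f"missing {names[0]}[.gz] in {dir_path}")


def _read_tsv_column(path: Path) -> np.ndarray:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        rows = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return np.array(rows, dtype=object)


def read_mtx_bundle(dir_path: str | Path) -> CellMatrix:
    """Read a Matrix Market bundle into a cells x genes :class:`CellMatrix`.

    The on-disk orientation (10x convention is genes x cells) is detected
    from the barcode/feature table lengths and transposed as needed. A
    ``labels.tsv`` sidecar, if present, is read as per-cell type labels.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    barcodes_path = _find(dir_path, "barcodes.tsv")
    features_path = _find(dir_path, "features.tsv", "genes.tsv")

    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    barcodes = _read_tsv_column(barcodes_path)
    genes = _read_tsv_column(features_path)

    n_bc, n_ft = len(barcodes), len(genes)
    if mat.shape == (n_ft, n_bc):
        mat = sp.csr_matrix(mat.T)
    elif mat.shape != (n_bc, n_ft):
        raise ConsistencyError(
            f"matrix is {mat.shape} but bundle declares {n_bc} barcodes "
            f"and {n_ft} features")

    labels = None
    labels_path = dir_path / _LABELS_FILE
    if not labels_path.exists() and (dir_path / (_LABELS_FILE + ".gz")).exists():
        labels_path = dir_path / (_LABELS_FILE + ".gz")
    if labels_path.exists():
        labels = _read_tsv_column(labels_path)
        if len(labels) != n_bc:
            raise ConsistencyError(
                f"{len(labels)} labels for {n_bc} barcodes in {labels_path}")
    return CellMatrix(counts=mat, barcodes=barcodes, genes=genes, labels=labels)


def write_mtx_bundle(m: CellMatrix, dir_path: str | Path) -> Path:
    """Write ``m`` as a Matrix Market bundle (genes x cells on disk).

    Labels, when present, go to a ``labels.tsv`` sidecar so the bundle
    round-trips through :func:`read_mtx_bundle`.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    # integer field when the data are counts; Matrix Market stays 1-based
    mat = sp.coo_matrix(m.counts.T)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), mat,
                     field="integer" if np.issubdtype(mat.dtype, np.integer) else "real")
    (dir_path / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in m.barcodes))
    (dir_path / "features.tsv").write_text(
        "".join(f"{g}\n" for g in m.genes))
    if m.labels is not None:
        (dir_path / _LABELS_FILE).write_text(
            "".join(f"{x}\n" for x in m.labels))
    return dir_path


def read_bulk_table(path: str | Path, unit: str = "counts") -> list[BulkProfile]:
    """Read a gene x sample expression table into one profile per column.

    The first column carries gene symbols; duplicate symbols are collapsed
    by summation (the usual count-matrix collapse for repeated annotation
    rows). Non-numeric or negative cells raise :class:`ParseError` with the
    offending row/column.
    """
    path = Path(path)
    sep = "," if path.name.rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ParseError(
                f"non-numeric value {df.loc[row, col]!r} at gene {row!r}, "
                f"sample {col!r} in {path}")
        if (converted < 0).any():
            row = (converted < 0).idxmax()
            raise ParseError(
                f"negative value at gene {row!r}, sample {col!r} in {path}")
        numeric[col] = converted.astype(float)
    collapsed = numeric.groupby(level=0, sort=False).sum()
    genes = np.array(collapsed.index, dtype=object)
    return [
        BulkProfile(sample_id=str(col), values=collapsed[col].to_numpy(),
                    genes=genes, unit=unit)
        for col in collapsed.columns
    ]


def write_bulk_table(profiles: list[BulkProfile], path: str | Path) -> Path:
    """Write profiles sharing a gene list back to a gene x sample TSV."""
    path = Path(path)
    genes = profiles[0].genes
    for p in profiles[1:]:
        if not np.array_equal(p.genes, genes):
            raise ConsistencyError("profiles do not share a gene list")
    df = pd.DataFrame({p.sample_id: p.values for p in profiles},
                      index=pd.Index(genes, name="gene"))
    df.to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------------------
# model checkpoints

def _hash_vocab(gene_list, label_vocab) -> str:
    h = hashlib.sha256()
    for g in gene_list:
        h.update(str(g).encode())
        h.update(b"\x00")
    h.update(b"\x01")
    for v in label_vocab:
        h.update(str(v).encode())
        h.update(b"\x00")
    return h.hexdigest()


def save_checkpoint(model, path: str | Path) -> Path:
    """Serialize a trained :class:`~scmet.cvae.CVAEGenerator`.

    Writes ``<path>`` (npz weight blob) and ``<path>.json`` (metadata
    sidecar: gene list, label vocabulary, normalization metadata, training
    config, seed, loss history, blob digest).
    """
    path = Path(path)
    state = model._state_dict()
    vocab_hash = _hash_vocab(model.gene_list_, model.label_vocab_)
    buf = _io.BytesIO()
    np.savez(buf, __vocab_hash__=np.array(vocab_hash),
             **{k: np.asarray(v) for k, v in state.items()})
    blob = buf.getvalue()
    path.write_bytes(blob)
    meta = {
        "format": "scmet-checkpoint-v1",
        "gene_list": [str(g) for g in model.gene_list_],
        "label_vocab": [str(v) for v in model.label_vocab_],
        "norm_meta": model.norm_meta_,
        "train_config": model.get_params(),
        "seed": model.random_state,
        "loss_history": {
            "train": [float(x) for x in model.train_loss_],
            "val": [float(x) for x in model.val_loss_],
        },
        "vocab_hash": vocab_hash,
        "blob_sha256": hashlib.sha256(blob).hexdigest(),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def load_checkpoint(path: str | Path):
    """Load a checkpoint saved by :func:`save_checkpoint`.

    Verifies the blob digest and the gene-list/label-vocabulary hash before
    reconstructing the model; any mismatch raises :class:`IntegrityError`.
    """
    from .cvae import CVAEGenerator  # local import avoids a cycle

    path = Path(path)
    meta_path = Path(str(path) + ".json")
    if not path.exists() or not meta_path.exists():
        raise FormatError(f"checkpoint {path} or its .json sidecar is missing")
    meta = json.loads(meta_path.read_text())
    blob = path.read_bytes()
    if hashlib.sha256(blob).hexdigest() != meta.get("blob_sha256"):
        raise IntegrityError(f"checkpoint blob {path} does not match its sidecar digest")
    try:
        state = dict(np.load(_io.BytesIO(blob), allow_pickle=False))
    except Exception as exc:  # noqa: BLE001
        raise IntegrityError(f"checkpoint blob {path} is unreadable: {exc}") from exc
    blob_hash = str(state.pop("__vocab_hash__"))
    if blob_hash != _hash_vocab(meta["gene_list"], meta["label_vocab"]):
        raise IntegrityError(
            "gene list / label vocabulary in sidecar does not match the blob")
    model = CVAEGenerator(**meta["train_config"])
    model._load_state(state, gene_list=meta["gene_list"],
                      label_vocab=meta["label_vocab"],
                      norm_meta=meta["norm_meta"],
                      loss_history=meta["loss_history"])
    return model
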
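"""Reading sample containers and writing embedding tables.

Two on-disk dialects are accepted per sample:

* an HDF5 single-cell container (``.h5ad``) with the PCA matrix in the
  conventional ``obsm["X_pca"]`` slot and annotations in a named ``obs``
  column;
* plain delimited text: a cells x components CSV/TSV matrix, optionally
  paired with a one-column label file ``<stem>.labels.<ext>`` next to it.

Embeddings are written as CSV tables ``cell_id, x, y, label, provenance``
at full float precision, so a read-back reproduces coordinates exactly.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING_CODE,
    FormatError,
    InconsistentAnnotationError,
    EmbeddingResult,
    SampleCollection,
    SampleData,
    encode_annotations,
)

_TEXT_SUFFIXES = {".csv", ".tsv", ".txt"}


def _read_one(path: Path, annotation_key: str | None):
    """Return (cell_ids, pca, raw_labels_or_None, key_present)."""
    if path.suffix == ".h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if "X_pca" not in adata.obsm:
            raise FormatError(f"{path}: no obsm['X_pca'] slot")
        pca = np.asarray(adata.obsm["X_pca"], dtype=float)
        cell_ids = [str(c) for c in adata.obs_names]
        if annotation_key is not None and annotation_key in adata.obs.columns:
            col = adata.obs[annotation_key]
            raw = [None if pd.isna(v) else str(v) for v in col]
            return cell_ids, pca, raw, True
        return cell_ids, pca, None, False
    if path.suffix in _TEXT_SUFFIXES:
        sep = "\t" if path.suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        pca = df.to_numpy(dtype=float)
        cell_ids = [str(i) for i in df.index]
        label_path = _label_sidecar(path)
        if annotation_key is not None and label_path.exists():
            lab = pd.read_csv(label_path, sep=sep, index_col=0)
            raw = [None if pd.isna(v) else str(v) for v in lab.iloc[:, 0]]
            if len(raw) != len(cell_ids):
                raise FormatError(f"{label_path}: label count != cell count")
            return cell_ids, pca, raw, True
        return cell_ids, pca, None, False
    raise FormatError(f"{path}: unsupported container suffix {path.suffix!r}")


def _label_sidecar(path: Path) -> Path:
    return path.with_suffix(".labels" + path.suffix)


def read_samples(
    paths: Sequence[str | os.PathLike],
    annotation_key: str | None = None,
) -> SampleCollection:
    """Load one sample per path into a :class:`SampleCollection`.

    Labels are populated only when ``annotation_key`` is given *and*
    present in every file; a key present in only some files raises
    :class:`InconsistentAnnotationError`.  The shared vocabulary is the
    sorted union of label names across all samples.
    """
    paths = [Path(p) for p in paths]
    loaded = [_read_one(p, annotation_key) for p in paths]
    present = [has for _, _, _, has in loaded]
    if annotation_key is not None and any(present) and not all(present):
        missing = [str(p) for p, has in zip(paths, present) if not has]
        raise InconsistentAnnotationError(
            f"annotation key {annotation_key!r} missing from: {missing}")
    use_labels = annotation_key is not None and all(present)
    sample_ids = [p.stem for p in paths]
    if use_labels:
        vocabulary, codes = encode_annotations([raw for _, _, raw, _ in loaded])
    else:
        vocabulary, codes = [], [None] * len(loaded)
    samples = [
        SampleData(sid, cell_ids, pca, code)
        for sid, (cell_ids, pca, _, _), code in zip(sample_ids, loaded, codes)
    ]
    return SampleCollection(samples, vocabulary)


def write_embedding(
    result: EmbeddingResult,
    path: str | os.PathLike,
    labels: np.ndarray | None = None,
    vocabulary: Sequence[str] | None = None,
    cell_ids: Sequence[str] | None = None,
) -> None:
    """Write an embedding as a CSV table, lossless for coordinates.

    Columns: ``cell_id, x, y, label, provenance``.  The label column
    holds decoded names when a vocabulary is given, raw codes otherwise,
    and is empty for unlabeled runs.
    """
    n = result.n
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n)]
    if labels is None:
        label_col = [""] * n
    elif vocabulary is not None:
        label_col = ["" if c == MISSING_CODE else vocabulary[c] for c in labels]
    else:
        label_col = [str(int(c)) for c in labels]
    df = pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "x": result.coords[:, 0],
            "y": result.coords[:, 1],
            "label": label_col,
            "provenance": result.provenance,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_embedding(path: str | os.PathLike, seed: int = 0) -> EmbeddingResult:
    """Read back a table written by :func:`write_embedding`."""
    df = pd.read_csv(path, float_precision="round_trip")
    coords = df[["x", "y"]].to_numpy(dtype=float)
    provenance = str(df["provenance"].iloc[0])
    return EmbeddingResult(Path(path).stem, coords, provenance, seed)


def write_sample_h5ad(sample: SampleData, path: str | os.PathLike,
                      vocabulary: Sequence[str] | None = None,
                      annotation_key: str = "cell_type") -> None:
    """Write a sample as an ``.h5ad`` container (PCA in ``obsm['X_pca']``)."""
    import anndata as ad

    n = sample.n
    obs = pd.DataFrame(index=pd.Index([str(c) for c in sample.cell_ids],
                                      name="cell_id"))
    if sample.labels is not None and vocabulary is not None:
        obs[annotation_key] = pd.Categorical(
            [None if c == MISSING_CODE else vocabulary[c]
             for c in sample.labels])
    adata = ad.AnnData(X=np.zeros((n, 1), dtype=np.float32), obs=obs)
    adata.obsm["X_pca"] = sample.pca
    adata.write_h5ad(Path(path))
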
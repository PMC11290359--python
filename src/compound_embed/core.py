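"""Core domain types and categorical annotation encoding.

A *sample* is one single-cell dataset (a patient, a modality, a time
point) already reduced to PCA space.  All alignment operations work on
these PCA coordinates; normalization, feature selection and the PCA
itself are upstream of this package.

Cell-type annotations are integer encoded against a vocabulary shared by
every sample in a collection: code ``i`` always means ``vocabulary[i]``,
in every sample.  Cells with a missing annotation inside an otherwise
annotated sample carry the reserved code :data:`MISSING_CODE`; they are
embedded like any other cell but never contribute to cell-type centroids
or attraction forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Reserved label code for cells with a missing / NA annotation.  Such
#: cells are excluded from every centroid computation and force.
MISSING_CODE: int = -1


class FormatError(ValueError):
    """An input container is missing a required slot or is malformed."""


class DimensionMismatchError(ValueError):
    """Samples disagree on the number of PCA components."""


class InconsistentAnnotationError(ValueError):
    """The annotation key exists in some input files but not all."""


@dataclass
class SampleData:
    """One sample: PCA coordinates plus optional integer-coded labels.

    Parameters
    ----------
    sample_id
        Unique identifier within the collection.
    cell_ids
        Per-cell identifiers, length ``n``.
    pca
        ``(n, P)`` float array of PCA coordinates. Must be finite.
    labels
        Optional ``(n,)`` integer array of cell-type codes into the
        collection vocabulary; :data:`MISSING_CODE` marks unannotated
        cells.
    """

    sample_id: str
    cell_ids: list[str]
    pca: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pca = np.asarray(self.pca, dtype=float)
        if self.pca.ndim != 2:
            raise ValueError("pca must be a 2-D matrix")
        n, P = self.pca.shape
        if n < 1 or P < 2:
            raise ValueError(f"need n >= 1 and P >= 2, got shape {self.pca.shape}")
        if not np.all(np.isfinite(self.pca)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite PCA values")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length must match number of rows in pca")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must match number of cells")

    @property
    def n(self) -> int:
        return self.pca.shape[0]

    @property
    def P(self) -> int:
        return self.pca.shape[1]

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def label_set(self) -> set[int]:
        """Set of real (non-missing) label codes present in this sample."""
        if self.labels is None:
            return set()
        return set(int(c) for c in np.unique(self.labels) if c != MISSING_CODE)

    def with_pca(self, pca: np.ndarray) -> "SampleData":
        """Copy of this sample with a replaced PCA matrix (same cells)."""
        return SampleData(self.sample_id, list(self.cell_ids), pca,
                          None if self.labels is None else self.labels.copy())

    def with_labels(self, labels: np.ndarray) -> "SampleData":
        return SampleData(self.sample_id, list(self.cell_ids), self.pca.copy(),
                          np.asarray(labels, dtype=int))


@dataclass
class SampleCollection:
    """Ordered samples sharing one PCA dimensionality and label vocabulary."""

    samples: list[SampleData]
    vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("collection must contain at least one sample")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        Ps = {s.P for s in self.samples}
        if len(Ps) > 1:
            raise DimensionMismatchError(
                f"samples disagree on PCA dimensionality: {sorted(Ps)}")
        V = len(self.vocabulary)
        for s in self.samples:
            if s.labels is not None:
                bad = [c for c in s.label_set() if not (0 <= c < V)]
                if bad:
                    raise ValueError(
                        f"sample {s.sample_id!r} has codes {bad} outside "
                        f"vocabulary of size {V}")

    @property
    def P(self) -> int:
        return self.samples[0].P

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def all_labeled(self) -> bool:
        return all(s.is_labeled for s in self.samples)

    def __getitem__(self, sample_id: str) -> SampleData:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def all_types(self) -> set[int]:
        out: set[int] = set()
        for s in self.samples:
            out |= s.label_set()
        return out


@dataclass
class EmbeddingResult:
    """2-D embedding of one sample, with provenance.

    ``provenance`` records how the coordinates were produced:
    ``independent`` (plain t-SNE, own initialization), ``primary``
    (plain t-SNE from the Procrustes-aligned initialization) or
    ``force`` (aligned initialization plus center-attraction forces).
    """

    sample_id: str
    coords: np.ndarray
    provenance: str
    seed: int

    _PROVENANCES = ("independent", "primary", "force")

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"provenance must be one of {self._PROVENANCES}")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def encode_annotations(
    raw_labels: Sequence[Sequence[str | None]],
) -> tuple[list[str], list[np.ndarray]]:
    """Integer-encode per-sample string labels against a shared vocabulary.

    The vocabulary is the lexicographically sorted union of label names
    over all samples, so codes are deterministic and identical in every
    sample.  ``None``/NaN entries become :data:`MISSING_CODE`.

    Returns
    -------
    vocabulary, codes
        The sorted name list and one integer vector per input sample.

    Raises
    ------
    ValueError
        If any sample is empty or contains an empty-string label.
    """
    names: set[str] = set()
    cleaned: list[list[str | None]] = []
    for i, labels in enumerate(raw_labels):
        labels = list(labels)
        if not labels:
            raise ValueError(f"sample {i}: empty label list")
        row: list[str | None] = []
        for lab in labels:
            if lab is None or (isinstance(lab, float) and np.isnan(lab)):
                row.append(None)
                continue
            lab = str(lab)
            if lab == "":
                raise ValueError(f"sample {i}: empty-string label")
            row.append(lab)
            names.add(lab)
        cleaned.append(row)
    vocabulary = sorted(names)
    code_of = {name: i for i, name in enumerate(vocabulary)}
    codes = [
        np.array([MISSING_CODE if lab is None else code_of[lab] for lab in row],
                 dtype=int)
        for row in cleaned
    ]
    return vocabulary, codes


def decode_annotations(
    vocabulary: Sequence[str], codes: np.ndarray
) -> list[str | None]:
    """Inverse of :func:`encode_annotations` for one sample."""
    return [None if c == MISSING_CODE else vocabulary[c] for c in codes]
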
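"""Labelled matrix containers for bipartite association data, and CSV/TSV I/O.

The containers are thin frozen dataclasses over dense numpy arrays with
ordered string labels on both axes.  At the scale this tool targets (a few
hundred microbes by a few dozen diseases) dense storage is simpler and
faster than any sparse machinery, and label order fully determines every
downstream index, so results are reproducible from the input file alone.

Two on-disk layouts are supported for association data:

* ``dense`` -- a labelled 0/1 matrix; first row holds disease ids, first
  column microbe ids.
* ``edgelist`` -- two columns ``microbe_id`` ``disease_id``, one row per
  known association; axis ordering is first-appearance order.

The delimiter is inferred from the extension: ``.csv`` is comma separated,
anything else (``.tsv``, ``.txt``) is tab separated.  Lines starting with
``#`` are treated as comments (the CLI writes provenance headers that way).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "FilledMatrix",
    "ScoreMatrix",
    "read_association",
    "write_association",
    "write_scores",
    "read_scores",
]


def _delimiter(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _check_labels(labels: Sequence[str], axis: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(x for x in labels if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {axis} label: {dup!r}")
    return labels


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary microbe-by-disease adjacency matrix with ordered labels.

    ``values[i, j] == 1`` iff microbe ``microbe_ids[i]`` is known to be
    associated with disease ``disease_ids[j]``.
    """

    values: np.ndarray
    microbe_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"non-binary cell at row {i!r}, column {j!r}: {values[i, j]!r}"
            )
        object.__setattr__(self, "values", values.astype(np.int8))
        object.__setattr__(
            self, "microbe_ids", _check_labels(self.microbe_ids, "microbe")
        )
        object.__setattr__(
            self, "disease_ids", _check_labels(self.disease_ids, "disease")
        )
        if values.shape != (len(self.microbe_ids), len(self.disease_ids)):
            raise ValueError("label lengths do not match matrix shape")
        if self.nm < 2 or self.nd < 2:
            raise ValueError("need at least 2 microbes and 2 diseases")

    @property
    def nm(self) -> int:
        return self.values.shape[0]

    @property
    def nd(self) -> int:
        return self.values.shape[1]

    def positives(self) -> np.ndarray:
        """Indices ``(i, j)`` of all known associations, row-major order."""
        return np.argwhere(self.values == 1)

    def with_zeroed(self, pairs: Sequence[tuple[int, int]]) -> "AssociationMatrix":
        """Copy with the given (row, col) entries forced to 0 (for CV masking)."""
        values = self.values.copy()
        for i, j in pairs:
            values[i, j] = 0
        return AssociationMatrix(values, self.microbe_ids, self.disease_ids)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square nonnegative similarity matrix tied to one axis of the data."""

    values: np.ndarray
    axis: str  # "microbe" | "disease"
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.isfinite(values).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if (values < 0).any():
            raise ValueError("similarity matrix contains negative entries")
        if self.axis not in ("microbe", "disease"):
            raise ValueError(f"axis must be 'microbe' or 'disease', got {self.axis!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", _check_labels(self.ids, self.axis))
        if len(self.ids) != values.shape[0]:
            raise ValueError("label length does not match matrix size")


@dataclass(frozen=True)
class FilledMatrix:
    """Real-valued association matrix in [0, 1] after neighbour-based filling."""

    values: np.ndarray
    microbe_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("filled matrix contains non-finite entries")
        if (values < 0).any() or (values > 1).any():
            raise ValueError("filled matrix entries must lie in [0, 1]")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "microbe_ids", _check_labels(self.microbe_ids, "microbe")
        )
        object.__setattr__(
            self, "disease_ids", _check_labels(self.disease_ids, "disease")
        )


@dataclass(frozen=True)
class ScoreMatrix:
    """Predicted association probabilities, strictly inside (0, 1)."""

    values: np.ndarray
    microbe_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size == 0:
            raise ValueError("score matrix is empty")
        if not np.isfinite(values).all():
            raise ValueError("score matrix contains non-finite entries")
        if (values <= 0).any() or (values >= 1).any():
            raise ValueError("scores must lie strictly in (0, 1)")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "microbe_ids", _check_labels(self.microbe_ids, "microbe")
        )
        object.__setattr__(
            self, "disease_ids", _check_labels(self.disease_ids, "disease")
        )


def read_association(path: str | Path, format: str = "dense") -> AssociationMatrix:
    """Read an association matrix from a dense labelled file or an edge list.

    Parameters
    ----------
    path
        Input file.  Delimiter is comma for ``.csv``, tab otherwise.
    format
        ``"dense"`` for a labelled 0/1 matrix, ``"edgelist"`` for two
        columns of (microbe_id, disease_id) pairs.  Duplicate edge-list
        pairs are collapsed (set semantics); edge-list label order is the
        order of first appearance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _delimiter(path)
    if format == "dense":
        frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        microbe_ids = [str(x) for x in frame.index]
        disease_ids = [str(x) for x in frame.columns]
        raw = frame.to_numpy()
        bad = ~np.isin(raw, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"non-binary cell at microbe {microbe_ids[i]!r}, "
                f"disease {disease_ids[j]!r}: {raw[i, j]!r}"
            )
        return AssociationMatrix(raw.astype(np.int8), microbe_ids, disease_ids)
    if format == "edgelist":
        frame = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
        if frame.shape[1] < 2:
            raise ValueError("edge list needs at least two columns")
        microbes = frame.iloc[:, 0].tolist()
        diseases = frame.iloc[:, 1].tolist()
        microbe_ids = list(dict.fromkeys(microbes))  # first-appearance order
        disease_ids = list(dict.fromkeys(diseases))
        m_index = {m: i for i, m in enumerate(microbe_ids)}
        d_index = {d: j for j, d in enumerate(disease_ids)}
        values = np.zeros((len(microbe_ids), len(disease_ids)), dtype=np.int8)
        for m, d in zip(microbes, diseases):
            values[m_index[m], d_index[d]] = 1
        return AssociationMatrix(values, microbe_ids, disease_ids)
    raise ValueError(f"unknown format {format!r}; use 'dense' or 'edgelist'")


def write_association(matrix: AssociationMatrix, path: str | Path) -> None:
    """Write an association matrix as a dense labelled file."""
    path = Path(path)
    frame = pd.DataFrame(
        matrix.values, index=list(matrix.microbe_ids), columns=list(matrix.disease_ids)
    )
    frame.to_csv(path, sep=_delimiter(path))


def write_scores(
    scores: ScoreMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a score matrix as a dense labelled file.

    Values are written with full round-trip precision, so
    ``read_scores(write_scores(P)) == P`` bit for bit.  ``header_lines``
    are emitted first, each prefixed with ``#`` (provenance stamping).
    """
    path = Path(path)
    frame = pd.DataFrame(
        scores.values, index=list(scores.microbe_ids), columns=list(scores.disease_ids)
    )
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep=_delimiter(path), float_format="%.17g")


def read_scores(path: str | Path) -> ScoreMatrix:
    """Read back a score matrix written by :func:`write_scores`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(
        path, sep=_delimiter(path), index_col=0, comment="#",
        float_precision="round_trip",
    )
    return ScoreMatrix(
        frame.to_numpy(dtype=float),
        [str(x) for x in frame.index],
        [str(x) for x in frame.columns],
    )
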
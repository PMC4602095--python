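"""Multiple sequence alignment I/O, filtering, and depth statistics.

Alignments are the substrate of pseudolikelihood Potts fitting. The
preprocessing implemented here mirrors common co-evolution practice:
gap-rich columns (more than 75% gaps by default) are removed, and
redundant sequences are removed HHfilter-style (90% identity, 75%
coverage of the query by default). The retained depth is the ``seq``
statistic consumed by the contact-probability calibration, via
:func:`depth_ratio`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO

from .alphabet import ALPHABET, GAP_STATE, AlphabetError, decode, encode

__all__ = [
    "Alignment",
    "MalformedAlignmentError",
    "read_alignment",
    "write_fasta",
    "filter_gap_columns",
    "filter_redundant_sequences",
    "depth_ratio",
]


class MalformedAlignmentError(ValueError):
    """Rows of unequal length, or an otherwise unusable alignment."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of sequences over the 21-state alphabet.

    Attributes
    ----------
    matrix : (depth, length) int8 array of alphabet state indices.
    ids : one identifier per row, in input order.
    column_map : original (pre-filtering) column index of each retained
        column; strictly increasing.
    """

    matrix: np.ndarray
    ids: tuple[str, ...]
    column_map: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.int8)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
            raise MalformedAlignmentError(
                f"alignment matrix must be 2-D and non-empty, got shape {m.shape}"
            )
        if len(self.ids) != m.shape[0]:
            raise MalformedAlignmentError("one identifier required per row")
        if m.min() < 0 or m.max() >= len(ALPHABET):
            raise AlphabetError("state index outside the 21-letter alphabet")
        if self.column_map is None:
            object.__setattr__(self, "column_map", tuple(range(m.shape[1])))
        cm = tuple(int(c) for c in self.column_map)
        object.__setattr__(self, "column_map", cm)
        if len(cm) != m.shape[1] or any(b <= a for a, b in zip(cm, cm[1:])):
            raise MalformedAlignmentError("column_map must be strictly increasing, one entry per column")
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def depth(self) -> int:
        """Number of rows (the ``seq`` statistic)."""
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        """Number of columns (the ``len`` statistic, L)."""
        return self.matrix.shape[1]

    @property
    def rows(self) -> list[str]:
        return [decode(r) for r in self.matrix]

    @classmethod
    def from_rows(cls, rows: Iterable[str], ids: Iterable[str] | None = None,
                  coerce_ambiguous: bool = False) -> "Alignment":
        rows = list(rows)
        if not rows:
            raise MalformedAlignmentError("no sequences")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise MalformedAlignmentError(
                f"rows have unequal lengths: {sorted(lengths)}"
            )
        if ids is None:
            ids = [f"seq{k}" for k in range(len(rows))]
        mat = np.stack([encode(r, coerce_ambiguous=coerce_ambiguous) for r in rows])
        return cls(mat, tuple(ids))


def _strip_a3m_inserts(seq: str) -> str:
    # lowercase characters are insertions relative to the query and are
    # not alignment columns; drop them before any length check
    return "".join(c for c in seq if not c.islower())


def read_alignment(path: str | Path, format: Literal["fasta", "a3m"] = "fasta",
                   coerce_ambiguous: bool = False) -> Alignment:
    """Read an aligned FASTA or A3M file.

    A3M lowercase insert states are removed; uppercase and gap states are
    retained. Identifiers are preserved in input order. Rows of unequal
    length after insert removal raise :class:`MalformedAlignmentError`;
    unknown characters raise :class:`~coevkit.alphabet.AlphabetError`
    unless ``coerce_ambiguous`` maps them to gaps.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MalformedAlignmentError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    if format == "a3m":
        rows = [_strip_a3m_inserts(r) for r in rows]
    if any(not r for r in rows):
        raise MalformedAlignmentError("empty sequence record")
    return Alignment.from_rows(rows, ids, coerce_ambiguous=coerce_ambiguous)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f">{name}\n{row}\n")


def filter_gap_columns(aln: Alignment, max_gap_frac: float = 0.75) -> Alignment:
    """Remove columns whose gap fraction is strictly above ``max_gap_frac``.

    Depth is unchanged; ``column_map`` tracks the surviving original
    column indices. Raises :class:`MalformedAlignmentError` if nothing
    survives.
    """
    if not 0 < max_gap_frac <= 1:
        raise ValueError("max_gap_frac must be in (0, 1]")
    gap_frac = (aln.matrix == GAP_STATE).mean(axis=0)
    keep = gap_frac <= max_gap_frac
    if not keep.any():
        raise MalformedAlignmentError("all columns exceed the gap threshold")
    cm = tuple(c for c, k in zip(aln.column_map, keep) if k)
    return Alignment(aln.matrix[:, keep], aln.ids, cm)


def _pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Identity over mutually non-gap positions (0.0 when none overlap)."""
    both = (a != GAP_STATE) & (b != GAP_STATE)
    n = int(both.sum())
    if n == 0:
        return 0.0
    return float((a[both] == b[both]).sum()) / n


def filter_redundant_sequences(aln: Alignment, max_identity: float = 0.90,
                               min_coverage: float = 0.75) -> Alignment:
    """HHfilter-like redundancy and coverage filter.

    The first row is the query/reference. Rows covering fewer than
    ``min_coverage`` of the query's non-gap columns are dropped; a greedy
    scan in input order then drops rows at or above ``max_identity``
    pairwise identity (identical over mutually non-gap positions) to a
    row already retained. The query itself is always kept, so the worst
    case returns the query alone. The returned depth is the ``seq``
    statistic used downstream.
    """
    mat = aln.matrix
    query_cols = mat[0] != GAP_STATE
    n_query = max(int(query_cols.sum()), 1)

    kept: list[int] = [0]
    for r in range(1, mat.shape[0]):
        cov = float(((mat[r] != GAP_STATE) & query_cols).sum()) / n_query
        if cov < min_coverage:
            continue
        if any(_pairwise_identity(mat[r], mat[k]) >= max_identity for k in kept):
            continue
        kept.append(r)
    return Alignment(mat[kept], tuple(aln.ids[k] for k in kept), aln.column_map)


def depth_ratio(aln: Alignment, mode: Literal["per_len", "per_sqrt_len"] = "per_sqrt_len") -> float:
    """Alignment depth scaled by length.

    ``per_sqrt_len`` returns depth/sqrt(length), the ratio consumed by the
    contact-probability calibration; ``per_len`` returns depth/length,
    used by the advisory "at least 4 sequences per residue" family
    selection rule.
    """
    if mode == "per_len":
        return aln.depth / aln.length
    if mode == "per_sqrt_len":
        return aln.depth / math.sqrt(aln.length)
    raise ValueError(f"unknown mode {mode!r}")
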
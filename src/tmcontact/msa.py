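"""Multiple sequence alignment I/O, gap filtering, and sequence reweighting.

An :class:`Alignment` keeps the homolog rows as an integer-coded matrix over
a 21-letter alphabet (20 amino acids plus a combined gap/unknown state) and a
``column_map`` that translates retained columns back to 1-based positions in
the original target sequence.  Columns where the target row carries a gap are
dropped at read time, so coordinates always refer to the target.

Reweighting follows the standard co-evolution convention: each sequence gets
weight ``1/n`` where ``n`` is the number of alignment rows (including itself)
that share strictly more than the identity threshold (default 80%) of
identically aligned, non-gap residues.  The sum of weights is the effective
alignment depth ``M_eff``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import AlignIO

#: canonical 20 amino acids, in the fixed state order used throughout
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: alphabet size: 20 amino acids + one gap/unknown state
Q = 21
#: integer code of the gap/unknown state
GAP_STATE = Q - 1
GAP_CHAR = "-"

_CODE = {aa: k for k, aa in enumerate(AMINO_ACIDS)}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned sequence string to integer states.

    Gaps (``-``, ``.``) and ambiguous/unusual residues (X, B, Z, U, O, ...)
    all map to the gap/unknown state.  Lower-case letters are upper-cased.
    """
    return np.fromiter(
        (_CODE.get(c, GAP_STATE) for c in seq.upper()), dtype=np.uint8, count=len(seq)
    )


def decode_row(row: np.ndarray) -> str:
    lut = AMINO_ACIDS + GAP_CHAR
    return "".join(lut[s] for s in row)


@dataclass
class Alignment:
    """An MSA in target coordinates.

    Attributes
    ----------
    target_id : identifier of the target (query) row.
    ids : sequence identifiers, one per row.
    matrix : ``(M, C)`` uint8 state codes; C = number of retained columns.
    target_row : row index of the target sequence.
    column_map : ``(C,)`` strictly increasing 1-based target positions.
    original_length : L, the ungapped target length.
    """

    target_id: str
    ids: list[str]
    matrix: np.ndarray
    target_row: int
    column_map: np.ndarray
    original_length: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.column_map = np.asarray(self.column_map, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("one id per alignment row required")
        if self.column_map.shape[0] != self.matrix.shape[1]:
            raise ValueError("column_map length must equal alignment width")
        if self.column_map.size and (
            np.any(np.diff(self.column_map) <= 0)
            or self.column_map[0] < 1
            or self.column_map[-1] > self.original_length
        ):
            raise ValueError("column_map must be strictly increasing within [1, L]")
        if np.any(self.matrix[self.target_row] == GAP_STATE):
            raise ValueError("target row may not contain gaps in retained columns")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def target_sequence(self) -> str:
        return decode_row(self.matrix[self.target_row])

    def row_gap_fractions(self) -> np.ndarray:
        return (self.matrix == GAP_STATE).mean(axis=1)

    def column_gap_fractions(self) -> np.ndarray:
        return (self.matrix == GAP_STATE).mean(axis=0)


@dataclass
class SequenceWeights:
    """Per-row weights from identity-based down-weighting."""

    weights: np.ndarray
    identity_threshold: float = 0.8
    m_eff: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in (0, 1]")
        self.m_eff = float(self.weights.sum())


def read_alignment(path, format: str = "fasta", target_id: str | None = None) -> Alignment:
    """Read an aligned FASTA or Stockholm file into target coordinates.

    Columns where the target row is gapped (or carries an unknown residue)
    are removed and ``column_map`` records the surviving target positions.
    The target defaults to the first record.
    """
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"could not parse {path} as an alignment: {exc}") from exc

    ids = [rec.id for rec in msa]
    if target_id is None:
        target_row = 0
        target_id = ids[0]
    else:
        try:
            target_row = ids.index(target_id)
        except ValueError:
            raise KeyError(f"target id {target_id!r} not found in {path}") from None

    matrix = np.stack(
        [encode_sequence(str(rec.seq).replace(".", GAP_CHAR)) for rec in msa]
    )
    keep = matrix[target_row] != GAP_STATE
    matrix = matrix[:, keep]
    length = int(keep.sum())
    return Alignment(
        target_id=target_id,
        ids=ids,
        matrix=matrix,
        target_row=target_row,
        column_map=np.arange(1, length + 1),
        original_length=length,
    )


def filter_sequences(aln: Alignment, max_gap_fraction: float = 0.30) -> Alignment:
    """Drop rows whose gap fraction strictly exceeds ``max_gap_fraction``.

    The target row is always retained.  The threshold is strict ("more
    than"), so a row sitting exactly at the threshold survives.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    keep = aln.row_gap_fractions() <= max_gap_fraction
    keep[aln.target_row] = True
    if keep.sum() == 1 and aln.n_rows > 1:
        warnings.warn("sequence gap filter removed every homolog; only the target remains")
    ids = [i for i, k in zip(aln.ids, keep) if k]
    new_target_row = int(keep[: aln.target_row].sum())
    return replace(aln, ids=ids, matrix=aln.matrix[keep], target_row=new_target_row)


def filter_columns(aln: Alignment, max_gap_fraction: float = 0.30) -> Alignment:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_fraction``."""
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    keep = aln.column_gap_fractions() <= max_gap_fraction
    return replace(aln, matrix=aln.matrix[:, keep], column_map=aln.column_map[keep])


def coverage(aln: Alignment) -> float:
    """Fraction of target positions that survive column filtering (Cov)."""
    if aln.original_length <= 0:
        raise ValueError("alignment has no target positions")
    return aln.width / aln.original_length


def sequence_weights(aln: Alignment, identity_threshold: float = 0.8) -> SequenceWeights:
    """Down-weight clusters of near-identical sequences.

    Identity between two rows is the number of columns where both carry the
    same non-gap residue, divided by the alignment width.  A row's weight is
    the reciprocal of the number of rows (itself always included) whose
    identity to it strictly exceeds the threshold.
    """
    if aln.n_rows < 1:
        raise ValueError("alignment has no rows")
    M, C = aln.matrix.shape
    if C == 0:
        weights = np.ones(M)
    else:
        onehot = np.zeros((M, C, Q - 1), dtype=np.float32)
        res = aln.matrix
        mask = res != GAP_STATE
        rows, cols = np.nonzero(mask)
        onehot[rows, cols, res[rows, cols]] = 1.0
        flat = onehot.reshape(M, C * (Q - 1))
        ident = (flat @ flat.T) / C
        np.fill_diagonal(ident, 0.0)
        neighbors = (ident > identity_threshold).sum(axis=1) + 1  # self counted
        weights = 1.0 / neighbors
    return SequenceWeights(weights=weights, identity_threshold=identity_threshold)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.matrix):
            fh.write(f">{sid}\n{decode_row(row)}\n")


def alignment_stats(aln: Alignment, weights: SequenceWeights | None = None) -> dict:
    """Summary statistics: L, alignment depth, effective depth, coverage."""
    if weights is None:
        weights = sequence_weights(aln)
    return {
        "L": aln.original_length,
        "M_align": aln.n_rows,
        "M_eff": weights.m_eff,
        "Cov": coverage(aln),
    }


def write_stats_tsv(stats: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("L\tM_align\tM_eff\tCov\n")
        fh.write(f"{stats['L']}\t{stats['M_align']}\t{stats['M_eff']:.6g}\t{stats['Cov']:.6g}\n")
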
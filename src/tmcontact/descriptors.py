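"""Per-pair descriptor engineering and contact labelling.

A candidate residue pair ``(i, j)`` is described by three groups of values:

* **global** -- the positions themselves, their separation ``|i - j|`` and
  the target length L;
* **sequence information** -- windows of biochemical property values
  (volume, hydrophobicity, steric parameter, polarizability, isoelectric
  point) around each site, with window and whole-sequence aggregates, plus
  alignment statistics (aligned length, depth, effective depth, coverage)
  and optional secondary-structure / membrane-layer probability tracks;
* **correlation** -- statistics of the co-evolution score matrix over the
  9x9 block ``i +/- 4  x  j +/- 4`` (max, mean, SD, sum, and the mean
  normalised by the protein-wide mean score), optionally across several
  score matrices derived from alternative alignments.

Contact labels follow the standard definition: representative atoms
(C-beta; C-alpha for glycine) within 8 Angstrom or less.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa import Alignment, SequenceWeights, alignment_stats
from .structure import StructureCoords
from .topology import TopologyProfile, vertical_separation

# AAindex-style property tables (20 standard amino acids).
_VOLUME = {  # residue volume, A^3 (Zamyatnin-type values)
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}
_HYDROPHOBICITY = {  # Kyte-Doolittle hydropathy
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_STERIC = {  # Charton steric parameter
    "A": 0.52, "R": 0.68, "N": 0.76, "D": 0.76, "C": 0.62,
    "Q": 0.68, "E": 0.68, "G": 0.00, "H": 0.70, "I": 1.02,
    "L": 0.98, "K": 0.68, "M": 0.78, "F": 0.70, "P": 0.36,
    "S": 0.53, "T": 0.50, "W": 0.70, "Y": 0.70, "V": 0.76,
}
_POLARIZABILITY = {  # Charton-Charton polarizability
    "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128,
    "Q": 0.180, "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186,
    "L": 0.186, "K": 0.219, "M": 0.221, "F": 0.290, "P": 0.131,
    "S": 0.062, "T": 0.108, "W": 0.409, "Y": 0.298, "V": 0.140,
}
_ISOELECTRIC = {  # Zimmerman isoelectric point
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.05,
    "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.30,
    "S": 5.68, "T": 5.66, "W": 5.89, "Y": 5.66, "V": 5.96,
}


@dataclass
class PropertyScales:
    """Named per-amino-acid property tables; gap/unknown maps to the table mean."""

    tables: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "volume": dict(_VOLUME),
            "hydrophobicity": dict(_HYDROPHOBICITY),
            "steric": dict(_STERIC),
            "polarizability": dict(_POLARIZABILITY),
            "isoelectric": dict(_ISOELECTRIC),
        }
    )

    def __post_init__(self) -> None:
        for name, table in self.tables.items():
            if len(table) != 20:
                raise ValueError(f"scale {name!r} must cover the 20 standard amino acids")

    @property
    def names(self) -> list[str]:
        return list(self.tables)

    def values(self, sequence: str, scale: str) -> np.ndarray:
        """Per-residue values; unknown residues take the table mean (warned once)."""
        table = self.tables[scale]
        mean = float(np.mean(list(table.values())))
        out = np.empty(len(sequence))
        unknown = False
        for k, aa in enumerate(sequence.upper()):
            v = table.get(aa)
            if v is None:
                v = mean
                unknown = True
            out[k] = v
        if unknown:
            warnings.warn(f"unknown residues mapped to the {scale} table mean")
        return out


def global_descriptors(i: int, j: int, L: int) -> tuple[int, int, int, int]:
    """The four global values ``(i, j, |i - j|, L)`` for ``1 <= i < j <= L``."""
    if not 1 <= i < j <= L:
        raise ValueError(f"require 1 <= i < j <= L, got i={i}, j={j}, L={L}")
    return (i, j, j - i, L)


def property_window(
    seq: str,
    center: int,
    scale: str = "hydrophobicity",
    half_width: int = 4,
    scales: PropertyScales | None = None,
) -> dict:
    """Biochemical-property window around ``center`` (1-based).

    Out-of-range slots are padded with the whole-sequence mean of the
    scale; the window mean/SD aggregate only the in-range slots.
    """
    scales = scales or PropertyScales()
    if not 1 <= center <= len(seq):
        raise ValueError(f"center {center} out of range 1..{len(seq)}")
    arr = scales.values(seq, scale)
    seq_mean = float(arr.mean())
    seq_sd = float(arr.std())
    width = 2 * half_width + 1
    vals = np.full(width, seq_mean)
    valid = []
    for off in range(-half_width, half_width + 1):
        p = center - 1 + off
        if 0 <= p < len(seq):
            vals[off + half_width] = arr[p]
            valid.append(arr[p])
    valid = np.asarray(valid)
    return {
        "values": vals,
        "window_mean": float(valid.mean()),
        "window_sd": float(valid.std()),
        "seq_mean": seq_mean,
        "seq_sd": seq_sd,
    }


def coupling_window_stats(S: np.ndarray, i: int, j: int, window: int = 9) -> dict:
    """Statistics of the score block ``i +/- h  x  j +/- h`` (h = window//2).

    Aggregates run over the valid (in-range, scored) block entries; the raw
    block is returned with invalid slots padded by the protein-wide mean of
    all scored pairs.  The normalised mean is the window mean divided by
    that protein-wide mean (0, with a warning, if the latter is 0).
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    L = S.shape[0]
    h = window // 2
    iu = np.triu_indices(L, k=1)
    scored = S[iu]
    scored = scored[np.isfinite(scored)]
    protein_mean = float(scored.mean()) if scored.size else 0.0

    block = np.full((window, window), np.nan)
    r0, r1 = i - 1 - h, i - 1 + h + 1
    c0, c1 = j - 1 - h, j - 1 + h + 1
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, L), min(c1, L)
    if rr0 < rr1 and cc0 < cc1:
        block[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] = S[rr0:rr1, cc0:cc1]
    valid = block[np.isfinite(block)]
    if valid.size == 0:
        warnings.warn(f"no scored entries in the window around ({i}, {j})")
        w_max = w_mean = w_sd = w_sum = 0.0
    else:
        w_max = float(valid.max())
        w_mean = float(valid.mean())
        w_sd = float(valid.std())
        w_sum = float(valid.sum())
    if protein_mean == 0.0:
        warnings.warn("protein-wide mean score is zero; normalized mean set to 0")
        norm_mean = 0.0
    else:
        norm_mean = w_mean / protein_mean
    raw = np.where(np.isfinite(block), block, protein_mean)
    return {
        "raw": raw,
        "max": w_max,
        "mean": w_mean,
        "sd": w_sd,
        "normalized_mean": norm_mean,
        "sum": w_sum,
        "protein_mean": protein_mean,
    }


def multi_msa_coupling_stats(S_list: list[np.ndarray], i: int, j: int, window: int = 9) -> dict:
    """Window statistics per score source plus cross-source max and mean.

    All matrices must share the target coordinate system.  Cross-source
    aggregates are the element-wise max/mean of the raw ``(i, j)`` scores
    (unscored sources are skipped).
    """
    shapes = {S.shape for S in S_list}
    if len(shapes) != 1:
        raise ValueError("score matrices are not on the same coordinates")
    per_source = [coupling_window_stats(S, i, j, window) for S in S_list]
    raw_ij = np.array([S[i - 1, j - 1] for S in S_list], dtype=float)
    finite = raw_ij[np.isfinite(raw_ij)]
    return {
        "per_source": per_source,
        "cross_max": float(finite.max()) if finite.size else np.nan,
        "cross_mean": float(finite.mean()) if finite.size else np.nan,
    }


def msa_stats_descriptors(aln: Alignment, weights: SequenceWeights) -> tuple:
    """``(aligned length incl. gaps, M_align, M_eff, Cov)`` for a protein."""
    stats = alignment_stats(aln, weights)
    return (aln.width, stats["M_align"], stats["M_eff"], stats["Cov"])


def segment_argmax(probs: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Maximal runs of the per-residue argmax state.

    Returns per-residue segment indices (0-based) and segments as 1-based
    inclusive ``(start, end, state)`` triples.
    """
    states = np.argmax(probs, axis=1)
    seg_idx = np.zeros(len(states), dtype=int)
    segments = []
    start = 0
    seg = 0
    for k in range(1, len(states) + 1):
        if k == len(states) or states[k] != states[start]:
            segments.append((start + 1, k, int(states[start])))
            seg_idx[start:k] = seg
            seg += 1
            start = k
    return seg_idx, segments


def _normalize_rows(probs: np.ndarray, what: str) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        warnings.warn(f"{what} probability rows do not sum to 1; renormalizing")
        probs = probs / sums[:, None]
    return probs


def sse_descriptors(
    sse_probs: np.ndarray,
    mem_probs: np.ndarray,
    i: int,
    j: int,
    half_width: int = 4,
) -> dict:
    """Secondary-structure / membrane-layer descriptors for a pair.

    Segmentation uses maximal runs of the argmax SSE state; the index
    difference counts segment boundaries crossed between ``i`` and ``j``
    (0 in the same element, 1 for neighbours, ...).  Center distances are
    signed offsets from the containing segment's midpoint.
    """
    sse_probs = _normalize_rows(sse_probs, "SSE")
    mem_probs = _normalize_rows(mem_probs, "membrane-layer")
    seg_idx, segments = segment_argmax(sse_probs)
    out = {"sse_index_difference": int(abs(seg_idx[j - 1] - seg_idx[i - 1]))}
    for tag, pos in (("i", i), ("j", j)):
        start, end, _state = segments[seg_idx[pos - 1]]
        out[f"sse_size_{tag}"] = end - start + 1
        out[f"sse_center_dist_{tag}"] = float(pos - (start + end) / 2.0)
        lo, hi = max(pos - 1 - half_width, 0), min(pos - 1 + half_width + 1, len(seg_idx))
        for s, name in enumerate(("helix", "strand", "coil")):
            out[f"sse_{name}_{tag}"] = float(sse_probs[pos - 1, s])
            out[f"sse_{name}_win_{tag}"] = float(sse_probs[lo:hi, s].mean())
        for s, name in enumerate(("membrane", "transition", "solution")):
            out[f"mem_{name}_{tag}"] = float(mem_probs[pos - 1, s])
            out[f"mem_{name}_win_{tag}"] = float(mem_probs[lo:hi, s].mean())
    return out


def contact_label(
    structure: StructureCoords, i: int, j: int, cutoff: float = 8.0
) -> int | None:
    """1 if the representative atoms are within ``cutoff`` (inclusive), else 0.

    Returns ``None`` when either representative atom is missing; such pairs
    are excluded from training.
    """
    a = structure.representative_atom(i)
    b = structure.representative_atom(j)
    if a is None or b is None:
        return None
    return int(np.linalg.norm(a - b) <= cutoff)


@dataclass
class ProteinInputs:
    """Everything needed to build one protein's descriptor records."""

    protein_id: str
    sequence: str
    di: np.ndarray  # (L, L) scores in target coordinates, nan = unscored
    topology: TopologyProfile | None = None
    extra_di: list[np.ndarray] = field(default_factory=list)
    sse_probs: np.ndarray | None = None
    mem_probs: np.ndarray | None = None
    structure: StructureCoords | None = None
    aln_stats: tuple | None = None  # (aligned_len, M_align, M_eff, Cov)


def assemble_dataset(
    proteins: list[ProteinInputs],
    min_separation: int = 1,
    window: int = 9,
    half_width: int = 4,
    scales: PropertyScales | None = None,
) -> pd.DataFrame:
    """One descriptor record per eligible pair, deterministic schema and order.

    Pairs require ``|i - j| >= min_separation`` and a finite score at
    ``(i, j)``.  The schema depends only on which optional inputs are
    present (uniform across the protein list), never on data content; rows
    are sorted by (protein, i, j).
    """
    scales = scales or PropertyScales()
    has_topology = all(p.topology is not None for p in proteins)
    has_sse = all(p.sse_probs is not None and p.mem_probs is not None for p in proteins)
    has_structure = all(p.structure is not None for p in proteins)
    has_extra = all(len(p.extra_di) > 0 for p in proteins)

    records = []
    for prot in sorted(proteins, key=lambda p: p.protein_id):
        L = len(prot.sequence)
        if prot.di.shape != (L, L):
            raise ValueError(f"{prot.protein_id}: score matrix does not match sequence length")
        prop = {
            name: scales.values(prot.sequence, name) for name in scales.names
        }
        seq_stats = {
            name: (float(v.mean()), float(v.std())) for name, v in prop.items()
        }
        stats4 = prot.aln_stats or (L, np.nan, np.nan, np.nan)
        for i in range(1, L):
            for j in range(i + min_separation, L + 1):
                if not np.isfinite(prot.di[i - 1, j - 1]):
                    continue
                rec = {
                    "protein_id": prot.protein_id,
                    "i": i,
                    "j": j,
                    "separation": j - i,
                    "L": L,
                    "aligned_length": stats4[0],
                    "m_align": stats4[1],
                    "m_eff": stats4[2],
                    "coverage": stats4[3],
                }
                w = coupling_window_stats(prot.di, i, j, window)
                rec.update(
                    di_raw=prot.di[i - 1, j - 1],
                    di_win_max=w["max"],
                    di_win_mean=w["mean"],
                    di_win_sd=w["sd"],
                    di_win_norm_mean=w["normalized_mean"],
                    di_win_sum=w["sum"],
                    di_protein_mean=w["protein_mean"],
                )
                if has_extra:
                    multi = multi_msa_coupling_stats(
                        [prot.di] + list(prot.extra_di), i, j, window
                    )
                    rec["di_cross_max"] = multi["cross_max"]
                    rec["di_cross_mean"] = multi["cross_mean"]
                for name in scales.names:
                    for tag, pos in (("i", i), ("j", j)):
                        pw = property_window(
                            prot.sequence, pos, name, half_width, scales
                        )
                        rec[f"{name}_win_mean_{tag}"] = pw["window_mean"]
                        rec[f"{name}_win_sd_{tag}"] = pw["window_sd"]
                    rec[f"{name}_seq_mean"] = seq_stats[name][0]
                    rec[f"{name}_seq_sd"] = seq_stats[name][1]
                if has_topology:
                    rec["depth_i"] = prot.topology.depth[i - 1]
                    rec["depth_j"] = prot.topology.depth[j - 1]
                    rec["vertical_separation"] = vertical_separation(prot.topology, i, j)
                if has_sse:
                    rec.update(
                        sse_descriptors(prot.sse_probs, prot.mem_probs, i, j, half_width)
                    )
                if has_structure:
                    label = contact_label(prot.structure, i, j)
                    rec["label"] = np.nan if label is None else float(label)
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Descriptor columns of an assembled dataset (metadata and label excluded)."""
    return [c for c in df.columns if c not in ("protein_id", "i", "j", "label")]


def write_dataset_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dataset_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
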
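"""Contact ranking, restraint emission, the smooth-step restraint potential,
and evaluation against structures.

Predicted pairs are ranked by score and the top ``round(f * L)`` are kept for
an L-fraction ``f`` (ties broken deterministically by larger sequence
separation, then position).  Selected pairs can be written as CASP RR
restraints.  During folding each restrained pair contributes a smooth-step
score on its C-alpha--C-alpha distance ``d``: the full -1 bonus for
``d <= 8`` Angstrom, zero beyond ``8 + 12 = 20`` Angstrom, and in between the
negative sine ramp ``-sin((pi/2) (20 - d) / 12)`` (a cosine smoothstep with
zero slope at both ends is available as an alternative; both agree on the
plateau values).

Evaluation labels pairs with the usual contact definition (representative
atoms within 8 Angstrom; C-alpha for glycine) and reports precision at each
L-fraction, rank-based ROC AUC, and the precision integral over the
0.01%-0.55% fraction-predicted-positive range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .descriptors import contact_label
from .learning import enrichment_objective, precision_fpp_curve
from .structure import StructureCoords


@dataclass
class ContactSet:
    """Ranked predicted contacts with their selection metadata."""

    pairs: list[tuple[int, int, float]]  # (i, j, score), i < j, score descending
    l_fraction: float
    min_separation: int
    source: str = "di"

    def __post_init__(self) -> None:
        for i, j, _ in self.pairs:
            if i >= j:
                raise ValueError(f"pairs must satisfy i < j, got ({i}, {j})")
            if j - i < self.min_separation:
                raise ValueError(f"pair ({i}, {j}) violates the separation floor")


@dataclass(frozen=True)
class RestraintPotential:
    """Smooth-step distance restraint (score in [full_bonus, 0])."""

    contact_bound: float = 8.0
    transition_width: float = 12.0
    full_bonus: float = -1.0
    form: str = "sine"  # "sine" (flat at the contact bound) or "cosine" (flat at both ends)


def _rank_key(pair):
    i, j, score = pair
    return (-score, -(j - i), i, j)


def select_top_contacts(
    scores: np.ndarray,
    l_fraction: float = 1.0,
    min_separation: int = 12,
    L: int | None = None,
    source: str = "di",
) -> ContactSet:
    """Highest-scoring ``round(l_fraction * L)`` pairs above the separation floor.

    ``scores`` is an ``(L, L)`` matrix in 1-based target coordinates with
    ``nan`` marking unscored pairs.  The requested count rounds half-up and
    is at least 1; if fewer eligible pairs exist, all are returned with a
    warning.
    """
    if l_fraction <= 0:
        raise ValueError("l_fraction must be positive")
    scores = np.asarray(scores, dtype=float)
    if L is None:
        L = scores.shape[0]
    n_req = max(1, int(math.floor(l_fraction * L + 0.5)))
    eligible = [
        (i + 1, j + 1, float(scores[i, j]))
        for i in range(scores.shape[0] - 1)
        for j in range(i + max(1, min_separation), scores.shape[0])
        if np.isfinite(scores[i, j])
    ]
    eligible.sort(key=_rank_key)
    if len(eligible) < n_req:
        warnings.warn(
            f"only {len(eligible)} eligible pairs for a request of {n_req}; returning all"
        )
    return ContactSet(
        pairs=eligible[:n_req],
        l_fraction=l_fraction,
        min_separation=min_separation,
        source=source,
    )


def restraint_score(d, potential: RestraintPotential = RestraintPotential()):
    """Smooth-step restraint score of a C-alpha distance (scalar or array)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    ub = potential.contact_bound
    w = potential.transition_width
    t = np.clip((ub + w - d) / w, 0.0, 1.0)  # 1 at d<=ub, 0 at d>=ub+w
    if potential.form == "sine":
        shape = np.sin(0.5 * np.pi * t)
    elif potential.form == "cosine":
        shape = 0.5 * (1.0 - np.cos(np.pi * t))
    else:
        raise ValueError(f"unknown potential form {potential.form!r}")
    out = potential.full_bonus * shape
    return float(out) if out.ndim == 0 else out


def score_model(
    structure: StructureCoords,
    contact_set: ContactSet,
    potential: RestraintPotential = RestraintPotential(),
) -> tuple[float, pd.DataFrame]:
    """Sum of restraint scores over C-alpha--C-alpha distances.

    Pairs with unresolved residues are excluded and counted; evaluation
    fails if no pair is resolvable.
    """
    rows = []
    for i, j, score in contact_set.pairs:
        a = structure.atom(i, "CA")
        b = structure.atom(j, "CA")
        if a is None or b is None:
            rows.append({"i": i, "j": j, "distance": np.nan, "restraint": np.nan,
                         "resolved": False})
            continue
        d = float(np.linalg.norm(a - b))
        rows.append({"i": i, "j": j, "distance": d,
                     "restraint": float(restraint_score(d, potential)), "resolved": True})
    table = pd.DataFrame(rows)
    if not table["resolved"].any():
        raise ValueError("no restrained pair could be resolved in the structure")
    total = float(table.loc[table["resolved"], "restraint"].sum())
    return total, table


def evaluate_predictions(
    scores: np.ndarray,
    structure: StructureCoords,
    min_separation: int = 12,
    l_fractions: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0, 3.0),
    cutoff: float = 8.0,
    fpp_range: tuple[float, float] = (0.0001, 0.0055),
) -> dict:
    """Precision at each top L-fraction, ROC AUC, and the precision-FPP integral.

    True contacts come from the structure via the representative-atom rule;
    pairs whose label cannot be derived are excluded.
    """
    scores = np.asarray(scores, dtype=float)
    L = scores.shape[0]
    resolved = sum(structure.representative_atom(p + 1) is not None for p in range(L))
    if resolved < 0.8 * L:
        warnings.warn(
            f"structure resolves only {resolved}/{L} positions; metrics cover those"
        )
    pairs, y, s = [], [], []
    for i in range(L - 1):
        for j in range(i + max(1, min_separation), L):
            if not np.isfinite(scores[i, j]):
                continue
            label = contact_label(structure, i + 1, j + 1, cutoff)
            if label is None:
                continue
            pairs.append((i + 1, j + 1))
            y.append(label)
            s.append(scores[i, j])
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(y) == 0:
        raise ValueError("no labelable pairs; cannot evaluate")
    out = {"n_pairs": len(y), "base_rate": float(y.mean())}
    out["auc"] = float(roc_auc_score(y, s)) if 0 < y.sum() < len(y) else np.nan
    label_by_pair = dict(zip(pairs, y))
    labeled_scores = np.full((L, L), np.nan)
    for (i, j), sc in zip(pairs, s):
        labeled_scores[i - 1, j - 1] = sc
    for frac in l_fractions:
        cs = select_top_contacts(labeled_scores, frac, min_separation, L=L)
        hits = sum(label_by_pair[(i, j)] for i, j, _ in cs.pairs)
        out[f"precision_at_{frac:g}L"] = hits / len(cs.pairs) if cs.pairs else np.nan
    if len(y) and 0 < y.sum():
        avg_enr, integral = enrichment_objective(s, y, fpp_range)
        f, prec = precision_fpp_curve(s, y, fpp_range)
        out["precision_integral"] = integral
        out["average_enrichment"] = avg_enr
        out["fpp_grid"] = f
        out["precision_curve"] = prec
    return out


def write_restraints(
    contact_set: ContactSet, path, format: str = "rr", target_id: str = "T0000"
) -> None:
    """Write selected contacts as CASP RR restraints or a plain TSV."""
    if not contact_set.pairs:
        raise ValueError("cannot write an empty contact set")
    pairs = []
    for i, j, score in contact_set.pairs:
        if i >= j:
            warnings.warn(f"normalizing pair ({i}, {j}) to i < j")
            i, j = min(i, j), max(i, j)
        pairs.append((i, j, score))
    with open(path, "w") as fh:
        if format == "rr":
            fh.write("PFRMAT RR\n")
            fh.write(f"TARGET {target_id}\n")
            fh.write("MODEL 1\n")
            for i, j, score in pairs:
                fh.write(f"{i} {j} 0 8 {score:.6f}\n")
            fh.write("END\n")
        elif format == "tsv":
            fh.write("i\tj\tscore\n")
            for i, j, score in pairs:
                fh.write(f"{i}\t{j}\t{score:.6f}\n")
        else:
            raise ValueError(f"unknown restraint format {format!r}")


def read_restraints(path) -> ContactSet:
    """Read a CASP RR (or TSV) restraint file back into a :class:`ContactSet`."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0] in ("PFRMAT", "TARGET", "MODEL", "END", "i"):
                continue
            if len(parts) >= 5:
                i, j, _, _, score = parts[:5]
            else:
                i, j, score = parts[:3]
            pairs.append((int(i), int(j), float(score)))
    sep = min((j - i for i, j, _ in pairs), default=1)
    return ContactSet(pairs=pairs, l_fraction=float("nan"), min_separation=sep, source="rr")


def plot_roc(labels, scores, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_precision_fpp(fpp, precision, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(fpp, precision)
    ax.set_xscale("log")
    ax.set_xlabel("fraction predicted positive")
    ax.set_ylabel("precision")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
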
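"""Membrane topology parsing, the transmembrane-depth descriptor, and the
vertical-separation contact filter.

Topology arrives as a per-residue string over ``i`` (inside/cytoplasmic
loop), ``M`` (transmembrane helix) and ``o`` (outside loop), the three-state
output of helix-bundle topology predictors.  Short re-entrant segments
(``r``/``R``) are treated as part of the flanking loop.

Each residue then receives a depth value in [0, 1]: inner-loop residues 0,
outer-loop residues 1, and residues inside a transmembrane span of length
``n`` the graded values ``k/(n+1)``.  Two orientation conventions are
offered:

``text`` (default)
    the residue closest to the *outside* of the membrane gets ``1/(n+1)``
    and the one closest to the inside ``n/(n+1)`` — i.e. depth measures the
    normalised distance from the outer membrane face, identically for
    up- and down-going helices;

``gradient``
    the loop-continuous variant: depth rises smoothly from the inner side
    (values near 0 adjoin inner loops) to the outer side (values near 1
    adjoin outer loops).

The absolute depth difference of a residue pair is its *vertical
separation*; pairs separated by more than 0.35 units are geometrically
implausible contacts and are discarded by :func:`topology_filter`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

LOOP_STATES = ("i", "o")
TM_STATE = "M"
REENTRANT = ("r", "R")
_KNOWN = set(LOOP_STATES) | {TM_STATE} | set(REENTRANT)


@dataclass
class TopologyProfile:
    """Per-residue topology states, spans, and (optionally) depth values."""

    states: str
    spans: list[tuple[int, int, str]]  # 1-based inclusive (start, end, kind)
    depth: np.ndarray | None = None

    @property
    def length(self) -> int:
        return len(self.states)


def _runs(s: str) -> list[tuple[int, int, str]]:
    spans = []
    start = 0
    for k in range(1, len(s) + 1):
        if k == len(s) or s[k] != s[start]:
            spans.append((start + 1, k, s[start]))
            start = k
    return spans


def parse_topology(s: str) -> TopologyProfile:
    """Parse a topology string into states and spans.

    Re-entrant runs are relabelled with the preceding loop state (or the
    following one when the string starts with them), then adjacent
    same-state runs merge.
    """
    bad = [k + 1 for k, c in enumerate(s) if c not in _KNOWN]
    if bad:
        raise ValueError(f"unknown topology symbols at positions {bad[:10]}")
    chars = list(s)
    for start, end, kind in _runs(s):
        if kind in REENTRANT:
            side = None
            for c in reversed(chars[: start - 1]):
                if c in LOOP_STATES:
                    side = c
                    break
            if side is None:
                for c in chars[end:]:
                    if c in LOOP_STATES:
                        side = c
                        break
            side = side or "i"
            chars[start - 1 : end] = side * (end - start + 1)
    clean = "".join(chars)
    return TopologyProfile(states=clean, spans=_runs(clean))


def encode_membrane_depth(profile: TopologyProfile, orientation: str = "text") -> TopologyProfile:
    """Assign each residue its transmembrane depth value.

    Loop residues get exactly 0 (``i``) or 1 (``o``).  Residues of an
    ``M`` span of length ``n`` get ``k/(n+1)``, ordered according to the
    chosen orientation convention (see module docstring).  The membrane
    side at each span end is taken from the flanking loops; a span flanked
    by same-side loops triggers a warning and the preceding loop wins.
    """
    if orientation not in ("text", "gradient"):
        raise ValueError("orientation must be 'text' or 'gradient'")
    depth = np.zeros(profile.length)
    spans = profile.spans
    for s_idx, (start, end, kind) in enumerate(spans):
        if kind == "i":
            depth[start - 1 : end] = 0.0
        elif kind == "o":
            depth[start - 1 : end] = 1.0
    for s_idx, (start, end, kind) in enumerate(spans):
        if kind != TM_STATE:
            continue
        prev_side = next(
            (k for _, _, k in reversed(spans[:s_idx]) if k in LOOP_STATES), None
        )
        next_side = next((k for _, _, k in spans[s_idx + 1 :] if k in LOOP_STATES), None)
        if prev_side is None and next_side is None:
            warnings.warn("transmembrane span with no flanking loop; assuming it starts inside")
            prev_side = "i"
        elif prev_side is None:
            prev_side = "o" if next_side == "i" else "i"
        elif next_side is not None and prev_side == next_side:
            warnings.warn(
                f"transmembrane span {start}-{end} flanked by same-side loops; "
                "orientation taken from the preceding loop"
            )
        starts_inside = prev_side == "i"
        n = end - start + 1
        k = np.arange(1, n + 1)
        ascending = k / (n + 1.0)  # 1/(n+1) at span start .. n/(n+1) at span end
        if orientation == "text":
            # depth = normalised distance from the outer membrane face
            vals = ascending[::-1] if starts_inside else ascending
        else:  # gradient: continuous with the flanking loops (0 inner .. 1 outer)
            vals = ascending if starts_inside else ascending[::-1]
        depth[start - 1 : end] = vals
    return replace(profile, depth=depth)


def vertical_separation(profile: TopologyProfile, i: int, j: int) -> float:
    """Absolute depth difference of residues ``i`` and ``j`` (1-based)."""
    if profile.depth is None:
        raise ValueError("depth values not computed; call encode_membrane_depth first")
    L = profile.length
    if not (1 <= i <= L and 1 <= j <= L):
        raise ValueError(f"positions ({i}, {j}) out of range 1..{L}")
    return float(abs(profile.depth[i - 1] - profile.depth[j - 1]))


def topology_filter(pairs, profile: TopologyProfile, threshold: float = 0.35):
    """Drop scored pairs whose vertical separation strictly exceeds ``threshold``.

    ``pairs`` is an iterable of ``(i, j, score)`` tuples; survivor order is
    preserved.
    """
    return [
        p for p in pairs if vertical_separation(profile, int(p[0]), int(p[1])) <= threshold
    ]


def filter_di_matrix(di: np.ndarray, profile: TopologyProfile, threshold: float = 0.35) -> np.ndarray:
    """Matrix form of :func:`topology_filter`: implausible pairs become ``nan``."""
    if profile.depth is None:
        raise ValueError("depth values not computed; call encode_membrane_depth first")
    if di.shape[0] != profile.length:
        raise ValueError("DI matrix side must equal topology length")
    sep = np.abs(profile.depth[:, None] - profile.depth[None, :])
    out = di.copy()
    out[sep > threshold] = np.nan
    return out


def read_topology(path) -> str:
    """Read a topology string from a one-line file or a 'pos<TAB>state' TSV."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) == 1 and "\t" not in lines[0]:
        return lines[0]
    states = {}
    for ln in lines:
        pos, state = ln.split("\t")[:2]
        if pos.lower() in ("pos", "position"):
            continue
        states[int(pos)] = state
    return "".join(states[p] for p in sorted(states))


def write_depth_tsv(profile: TopologyProfile, path) -> None:
    if profile.depth is None:
        raise ValueError("depth values not computed")
    with open(path, "w") as fh:
        fh.write("pos\tstate\tdepth\n")
        for k, (state, d) in enumerate(zip(profile.states, profile.depth), start=1):
            fh.write(f"{k}\t{state}\t{d:.10g}\n")
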
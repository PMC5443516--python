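"""Synthetic fixtures: coupled-MSA sampling with planted contacts, topology
strings, idealised helix-bundle coordinates, and a mutually consistent
end-to-end bundle.

The sequence sampler draws from a pairwise (Potts-like) model: independent
per-site fields everywhere, plus a diagonal-favouring coupling ``J(A, B) =
strength * delta(A, B)`` on each planted pair, so planted pairs co-vary while
all other pairs are independent given the fields.  Sampling runs one Gibbs
chain per output sequence, vectorised across chains; sites that carry no
coupling are drawn exactly from their field distribution, coupled sites are
swept ``burn_in`` (+ ``thinning``) times.  Because every output sequence is
its own chain, ``thinning`` only adds decorrelation from the common
initialisation scheme.

Helix bundles are ideal alpha-helices (1.5 Angstrom rise and 100 degrees of
twist per residue, 2.3 Angstrom backbone radius) placed on a regular polygon
with alternating up/down direction; pseudo C-beta atoms sit 1.5 Angstrom
along the outward radial, so residues facing a neighbouring helix form
bona-fide contacts under the 8-Angstrom rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import AMINO_ACIDS, Alignment, GAP_STATE, Q
from .structure import StructureCoords
from .topology import TopologyProfile, encode_membrane_depth, parse_topology

# a bias of -8 makes the gap state effectively unreachable without
# excluding it from the model's alphabet
_GAP_BIAS = -8.0


@dataclass
class PlantedModel:
    """Pairwise sequence model with planted coupled pairs."""

    length: int
    planted_pairs: list[tuple[int, int]]  # 1-based, i < j
    coupling_strength: float = 2.0
    q: int = Q
    field_bias: np.ndarray | None = None  # (L, q)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_strength < 0:
            raise ValueError("coupling strength must be non-negative")
        for i, j in self.planted_pairs:
            if not (1 <= i < j <= self.length) or j - i < 2:
                raise ValueError(f"planted pair ({i}, {j}) must satisfy i < j, |i-j| >= 2")
        if self.field_bias is None:
            bias = np.zeros((self.length, self.q))
            if self.q == Q:
                bias[:, GAP_STATE] = _GAP_BIAS
            self.field_bias = bias
        else:
            self.field_bias = np.asarray(self.field_bias, dtype=float)
            if self.field_bias.shape != (self.length, self.q):
                raise ValueError("field_bias must have shape (L, q)")


def _categorical(rng: np.random.Generator, logits: np.ndarray) -> np.ndarray:
    """One categorical draw per row of ``logits``."""
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(p.shape[0])
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def sample_coupled_msa(
    model: PlantedModel,
    n_sequences: int,
    burn_in: int = 1000,
    thinning: int = 10,
    target_id: str = "synthetic_target",
) -> Alignment:
    """Sample an alignment of ``n_sequences`` from the planted model.

    Deterministic under ``model.seed``.  Row 0 doubles as the target; any
    gap state it sampled (possible only for user-supplied biases) is
    replaced by the column's modal non-gap state so target coordinates stay
    well defined.
    """
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    L, q = model.length, model.q
    rng = np.random.default_rng(model.seed)
    neighbors: dict[int, list[tuple[int, np.ndarray]]] = {k: [] for k in range(L)}
    J = model.coupling_strength * np.eye(q)
    for i, j in model.planted_pairs:
        neighbors[i - 1].append((j - 1, J))
        neighbors[j - 1].append((i - 1, J))
    coupled = [k for k in range(L) if neighbors[k]]

    states = np.empty((n_sequences, L), dtype=np.int64)
    for k in range(L):
        states[:, k] = _categorical(rng, np.broadcast_to(model.field_bias[k], (n_sequences, q)))
    for _sweep in range(burn_in + thinning):
        for k in coupled:
            logits = np.broadcast_to(model.field_bias[k], (n_sequences, q)).copy()
            for nbr, Jmat in neighbors[k]:
                logits += Jmat[:, states[:, nbr]].T
            states[:, k] = _categorical(rng, logits)

    if q < Q:  # reduced alphabets use the first q amino-acid states
        matrix = states.astype(np.uint8)
    else:
        matrix = states.astype(np.uint8)
        target = matrix[0]
        gap_cols = np.flatnonzero(target == GAP_STATE)
        for col in gap_cols:
            counts = np.bincount(matrix[:, col], minlength=Q)[:GAP_STATE]
            matrix[0, col] = int(np.argmax(counts))
    ids = [target_id] + [f"seq{k:05d}" for k in range(1, n_sequences)]
    return Alignment(
        target_id=target_id,
        ids=ids,
        matrix=matrix,
        target_row=0,
        column_map=np.arange(1, L + 1),
        original_length=L,
    )


def make_topology(
    n_helices: int, helix_len: int = 21, loop_len: int = 3, start_side: str = "i"
) -> str:
    """Alternating-loop topology string: loop, helix, loop, helix, ..., loop."""
    if n_helices < 1:
        raise ValueError("need at least one helix")
    if start_side not in ("i", "o"):
        raise ValueError("start_side must be 'i' or 'o'")
    other = "o" if start_side == "i" else "i"
    out = []
    for k in range(n_helices + 1):
        side = start_side if k % 2 == 0 else other
        out.append(side * loop_len)
        if k < n_helices:
            out.append("M" * helix_len)
    return "".join(out)


def make_sse_probs(profile: TopologyProfile, confidence: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (SSE, membrane-layer) probability tracks from a topology.

    Transmembrane residues are helix/membrane-dominant, loops coil/solution-
    dominant; the remaining mass splits 4:1 between the minor states.
    """
    rest = 1.0 - confidence
    L = profile.length
    sse = np.empty((L, 3))
    mem = np.empty((L, 3))
    for k, state in enumerate(profile.states):
        if state == "M":
            sse[k] = (confidence, rest * 0.2, rest * 0.8)
            mem[k] = (confidence, rest * 0.8, rest * 0.2)
        else:
            sse[k] = (rest * 0.8, rest * 0.2, confidence)
            mem[k] = (rest * 0.2, rest * 0.8, confidence)
    return sse, mem


def make_helix_bundle(
    n_helices: int,
    residues_per_helix: int = 21,
    spacing: float = 10.0,
    rise: float = 1.5,
    twist_deg: float = 100.0,
    helix_radius: float = 2.3,
    cb_length: float = 1.5,
    positions: list[list[int]] | None = None,
    resname: str = "ALA",
) -> StructureCoords:
    """Idealised up/down helix bundle with C-alpha and pseudo C-beta atoms.

    Helix axes sit on a regular polygon with the given nearest-neighbour
    axis ``spacing``; successive helices run in opposite z directions.
    ``positions`` optionally assigns residue numbers per helix (default:
    sequential 1..n*m).
    """
    if n_helices < 2:
        raise ValueError("a bundle needs at least two helices")
    m = residues_per_helix
    if positions is None:
        positions = [list(range(h * m + 1, (h + 1) * m + 1)) for h in range(n_helices)]
    if len(positions) != n_helices or any(len(p) != m for p in positions):
        raise ValueError("positions must give one residue number per helix residue")
    if n_helices == 2:
        centers = [np.array([0.0, 0.0]), np.array([spacing, 0.0])]
    else:
        R = spacing / (2.0 * np.sin(np.pi / n_helices))
        centers = [
            R * np.array([np.cos(2 * np.pi * h / n_helices), np.sin(2 * np.pi * h / n_helices)])
            for h in range(n_helices)
        ]
    twist = np.deg2rad(twist_deg)
    height = rise * (m - 1)
    struct = StructureCoords()
    for h in range(n_helices):
        center = centers[h]
        # phase points the first residue toward the bundle centre
        phase = np.arctan2(-center[1], -center[0]) if np.linalg.norm(center) > 0 else 0.0
        up = h % 2 == 0
        for t in range(m):
            theta = phase + twist * t
            radial = np.array([np.cos(theta), np.sin(theta)])
            xy = center + helix_radius * radial
            z = rise * t if up else height - rise * t
            ca = np.array([xy[0], xy[1], z])
            cb = np.array([*(center + (helix_radius + cb_length) * radial), z])
            pos = positions[h][t]
            struct.add_atom(pos, resname, "CA", ca)
            struct.add_atom(pos, resname, "CB", cb)
    return struct


@dataclass
class EndToEndFixture:
    """A mutually consistent bundle of pipeline inputs and planted truth."""

    alignment: Alignment
    profile: TopologyProfile
    sse_probs: np.ndarray
    mem_probs: np.ndarray
    structure: StructureCoords
    planted_true: list[tuple[int, int]]
    planted_false: list[tuple[int, int]]
    model: PlantedModel


def make_end_to_end_fixture(
    seed: int = 0,
    n_helices: int = 3,
    helix_len: int = 21,
    loop_len: int = 4,
    n_sequences: int = 2000,
    coupling_strength: float = 2.0,
    spacing: float = 10.0,
    n_true: int = 8,
    n_false: int = 4,
    burn_in: int = 300,
) -> EndToEndFixture:
    """Build a full synthetic protein for pipeline integration tests.

    Planted *true* pairs are genuine spatial contacts of the helix bundle
    at matching membrane depth; planted *false* pairs couple residues from
    opposite membrane sides of different helices (the classic co-evolution
    overprediction), so a depth-based filter should remove them.
    """
    topo = make_topology(n_helices, helix_len, loop_len, start_side="i")
    profile = encode_membrane_depth(parse_topology(topo))
    L = profile.length
    helix_positions = [
        list(range(start, end + 1)) for start, end, kind in profile.spans if kind == "M"
    ]
    structure = make_helix_bundle(
        n_helices, helix_len, spacing=spacing, positions=helix_positions
    )
    from .descriptors import contact_label  # deferred to avoid an import cycle

    rng = np.random.default_rng(seed)
    candidates = []
    for h1 in range(n_helices):
        for h2 in range(h1 + 1, n_helices):
            for a in helix_positions[h1]:
                for b in helix_positions[h2]:
                    i, j = min(a, b), max(a, b)
                    if j - i >= 12 and contact_label(structure, i, j) == 1:
                        candidates.append((i, j))
    if len(candidates) < n_true:
        raise ValueError("bundle geometry yields too few contacts; decrease spacing")
    pick = np.linspace(0, len(candidates) - 1, n_true).astype(int)
    planted_true = [candidates[k] for k in pick]

    depth = profile.depth
    false_candidates = []
    for h1 in range(n_helices):
        for h2 in range(h1 + 1, n_helices):
            for a in helix_positions[h1]:
                for b in helix_positions[h2]:
                    i, j = min(a, b), max(a, b)
                    if j - i < 12 or (i, j) in set(planted_true):
                        continue
                    if abs(depth[i - 1] - depth[j - 1]) <= 0.6:
                        continue
                    if contact_label(structure, i, j) == 1:
                        continue
                    false_candidates.append((i, j))
    pick = rng.choice(len(false_candidates), size=n_false, replace=False)
    planted_false = [false_candidates[k] for k in sorted(pick)]

    model = PlantedModel(
        length=L,
        planted_pairs=sorted(planted_true + planted_false),
        coupling_strength=coupling_strength,
        seed=seed,
    )
    alignment = sample_coupled_msa(model, n_sequences, burn_in=burn_in)
    sse, mem = make_sse_probs(profile)
    return EndToEndFixture(
        alignment=alignment,
        profile=profile,
        sse_probs=sse,
        mem_probs=mem,
        structure=structure,
        planted_true=planted_true,
        planted_false=planted_false,
        model=model,
    )
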
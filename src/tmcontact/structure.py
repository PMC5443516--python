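"""Minimal coordinate container plus PDB-format reading and writing.

Only what contact labelling and restraint scoring need: per-residue atom
coordinates keyed by residue number, with the residue name retained so the
representative atom rule (C-beta, or C-alpha for glycine) can be applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StructureCoords:
    """Sparse residue -> atom coordinate map (1-based residue numbers)."""

    residues: dict[int, dict] = field(default_factory=dict)
    # each value: {"resname": str, "atoms": {atom_name: np.ndarray(3)}}

    def add_atom(self, pos: int, resname: str, atom: str, coord) -> None:
        entry = self.residues.setdefault(pos, {"resname": resname, "atoms": {}})
        entry["atoms"][atom] = np.asarray(coord, dtype=float)

    def positions(self) -> list[int]:
        return sorted(self.residues)

    def atom(self, pos: int, name: str) -> np.ndarray | None:
        entry = self.residues.get(pos)
        if entry is None:
            return None
        return entry["atoms"].get(name)

    def representative_atom(self, pos: int) -> np.ndarray | None:
        """C-beta coordinate; C-alpha for glycine (even if a CB record exists)."""
        entry = self.residues.get(pos)
        if entry is None:
            return None
        name = "CA" if entry["resname"].upper() == "GLY" else "CB"
        return entry["atoms"].get(name)


def read_pdb(path, chain: str | None = None, model_index: int = 0) -> StructureCoords:
    """Read coordinates from a PDB file (first model, selectable chain)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = list(structure)[model_index]
    chains = list(model)
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise KeyError(f"chain {chain!r} not found")
    out = StructureCoords()
    for ch in chains[:1]:
        for res in ch:
            if res.id[0] != " ":
                continue  # skip heteroatoms and waters
            pos = res.id[1]
            for atom in res:
                out.add_atom(pos, res.get_resname(), atom.get_name(), atom.coord)
    return out


def write_pdb(struct: StructureCoords, path, chain: str = "A") -> None:
    serial = 1
    with open(path, "w") as fh:
        for pos in struct.positions():
            entry = struct.residues[pos]
            for name, xyz in entry["atoms"].items():
                pad = name.ljust(3) if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:5d}  {pad:<3s}{entry['resname']:>4s} {chain}{pos:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           {name[0]}\n"
                )
                serial += 1
        fh.write("END\n")
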
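"""Atomic structure container with named motor-domain selections.

:class:`StructureModel` is a flat column-oriented atom table (chain,
residue number/name, atom name, element, xyz). PDB and mmCIF files are
read through biotite. Named selections are residue-range sets keyed by
functional element; defaults use human Kif5b numbering and are
configurable per species.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

# Default residue ranges (inclusive) in Kif5b numbering. The alignment
# frame used for nucleotide-pocket comparisons is P_LOOP + HELIX_A2A.
DEFAULT_SELECTIONS: dict[str, tuple[int, int]] = {
    "P_LOOP": (85, 92),
    "HELIX_A2A": (93, 100),
    "LOOP9": (190, 204),
    "LOOP11": (232, 245),
    "HELIX_A4": (246, 270),
    "NECK_LINKER": (325, 338),
    "CORE_SHEET": (75, 95),
}

FRAME_SELECTION = ("P_LOOP", "HELIX_A2A")


@dataclass
class StructureModel:
    """Column-oriented atom table. All coordinate units are Å."""

    chain: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    selections: dict = None

    def __post_init__(self):
        n = len(self.coord)
        for name in ("chain", "res_id", "res_name", "atom_name", "element"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")
        if self.selections is None:
            self.selections = dict(DEFAULT_SELECTIONS)
        keys = list(zip(self.chain, self.res_id, self.atom_name))
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, residue, atom) identifiers")

    def __len__(self) -> int:
        return len(self.coord)

    def select(
        self,
        chain=None,
        res_ids=None,
        res_range=None,
        atom_names=None,
        selection_name=None,
    ) -> "StructureModel":
        """Subset atoms; all criteria are ANDed. ``selection_name`` expands a
        named residue-range selection (or tuple of names)."""
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            chains = [chain] if isinstance(chain, str) else list(chain)
            mask &= np.isin(self.chain, chains)
        if selection_name is not None:
            names = (
                [selection_name]
                if isinstance(selection_name, str)
                else list(selection_name)
            )
            sel_mask = np.zeros(len(self), dtype=bool)
            for name in names:
                if name not in self.selections:
                    raise KeyError(
                        f"unknown selection {name!r}; have {sorted(self.selections)}"
                    )
                lo, hi = self.selections[name]
                sel_mask |= (self.res_id >= lo) & (self.res_id <= hi)
            mask &= sel_mask
        if res_range is not None:
            lo, hi = res_range
            mask &= (self.res_id >= lo) & (self.res_id <= hi)
        if res_ids is not None:
            mask &= np.isin(self.res_id, np.asarray(list(res_ids)))
        if atom_names is not None:
            names = [atom_names] if isinstance(atom_names, str) else list(atom_names)
            mask &= np.isin(self.atom_name, names)
        return self.subset(mask)

    def subset(self, mask) -> "StructureModel":
        return replace(
            self,
            chain=self.chain[mask],
            res_id=self.res_id[mask],
            res_name=self.res_name[mask],
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            coord=self.coord[mask],
            selections=dict(self.selections),
        )

    def ca(self) -> "StructureModel":
        return self.select(atom_names="CA")

    def with_coords(self, coord) -> "StructureModel":
        coord = np.asarray(coord, dtype=float)
        if coord.shape != self.coord.shape:
            raise ValueError("coordinate shape mismatch")
        return replace(self, coord=coord, selections=dict(self.selections))

    def transformed(self, rotation, translation) -> "StructureModel":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return self.with_coords(self.coord @ R.T + t)

    def atom_index(self, chain, res_id, atom_name) -> int:
        mask = (
            (self.chain == chain)
            & (self.res_id == res_id)
            & (self.atom_name == atom_name)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"atom {chain}/{res_id}/{atom_name} not found")
        return int(idx[0])

    @classmethod
    def from_arrays(cls, res_id, coord, chain="A", res_name="ALA",
                    atom_name="CA", element="C", selections=None):
        n = len(coord)

        def col(v):
            return np.full(n, v, dtype=object) if isinstance(v, str) else np.asarray(v, dtype=object)

        return cls(
            chain=col(chain),
            res_id=np.asarray(res_id, dtype=int),
            res_name=col(res_name),
            atom_name=col(atom_name),
            element=col(element),
            coord=np.asarray(coord, dtype=float),
            selections=selections,
        )

    @classmethod
    def from_file(cls, path, model: int = 1, altloc: str = "first",
                  selections=None) -> "StructureModel":
        """Load from PDB or mmCIF (extension-dispatched, via biotite)."""
        import biotite.structure.io.pdb as pdb_io
        import biotite.structure.io.pdbx as pdbx_io

        path = Path(path)
        if path.suffix.lower() in (".cif", ".mmcif"):
            f = pdbx_io.CIFFile.read(str(path))
            atoms = pdbx_io.get_structure(f, model=model, altloc=altloc)
        else:
            f = pdb_io.PDBFile.read(str(path))
            atoms = pdb_io.get_structure(f, model=model, altloc=altloc)
        return cls.from_atom_array(atoms, selections=selections)

    @classmethod
    def from_atom_array(cls, atoms, selections=None) -> "StructureModel":
        """Convert a biotite AtomArray."""
        return cls(
            chain=np.asarray(atoms.chain_id, dtype=object),
            res_id=np.asarray(atoms.res_id, dtype=int),
            res_name=np.asarray(atoms.res_name, dtype=object),
            atom_name=np.asarray(atoms.atom_name, dtype=object),
            element=np.asarray(atoms.element, dtype=object),
            coord=np.asarray(atoms.coord, dtype=float),
            selections=selections,
        )
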
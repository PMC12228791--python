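"""Hydrogen-bond network extraction and diffing for atomic models.

Cryo-EM and most crystallographic models lack hydrogens, so the default
criterion is heavy-atom based: donor-acceptor distance within ``d_max``
and the angle at the donor (antecedent-donor-acceptor) at least
``angle_min``. Salt-bridge pairs may optionally be kept on the distance
criterion alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structmodel import StructureModel

# Sidechain donor/acceptor atoms per residue; backbone N (donor) and O
# (acceptor) apply to every amino acid. Nucleotides cover ADP/ATP analogs.
SIDECHAIN_DONORS = {
    "ARG": ["NE", "NH1", "NH2"],
    "ASN": ["ND2"],
    "GLN": ["NE2"],
    "HIS": ["ND1", "NE2"],
    "LYS": ["NZ"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TRP": ["NE1"],
    "TYR": ["OH"],
    "CYS": ["SG"],
}
SIDECHAIN_ACCEPTORS = {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"],
    "GLN": ["OE1"],
    "HIS": ["ND1", "NE2"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "MET": ["SD"],
}
NUCLEOTIDE_RESIDUES = {"ADP", "ATP", "ANP", "AGS", "ADN", "AMP"}
# every O/N of a nucleotide can accept; N6 amine donates
AMINO_RESIDUES = set(SIDECHAIN_DONORS) | set(SIDECHAIN_ACCEPTORS) | {
    "ALA", "GLY", "ILE", "LEU", "PHE", "PRO", "VAL", "MET", "CYS",
}
POSITIVE_RESIDUES = {"ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"], "HIS": ["ND1", "NE2"]}
NEGATIVE_RESIDUES = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}


@dataclass(frozen=True)
class HBond:
    donor: tuple  # (chain, res_id, res_name, atom_name)
    acceptor: tuple
    distance: float  # Å
    angle: float | None  # degrees at the donor; None for distance-only edges

    @property
    def residue_pair(self) -> tuple:
        d = (self.donor[0], int(self.donor[1]), self.donor[2])
        a = (self.acceptor[0], int(self.acceptor[1]), self.acceptor[2])
        return tuple(sorted((d, a)))

    def label(self) -> str:
        d, a = self.residue_pair
        return f"{d[0]}:{d[2]}{d[1]}-{a[0]}:{a[2]}{a[1]}"


@dataclass
class HBondNetwork:
    edges: list = field(default_factory=list)

    def residue_pairs(self) -> set:
        return {e.residue_pair for e in self.edges}

    def labels(self) -> set:
        return {e.label() for e in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


def _donor_acceptor_indices(model: StructureModel):
    donors, acceptors = [], []
    for i in range(len(model)):
        res = model.res_name[i]
        atom = model.atom_name[i]
        if res in AMINO_RESIDUES:
            if atom == "N" and res != "PRO":
                donors.append(i)
            elif atom == "O" or atom == "OXT":
                acceptors.append(i)
            elif atom in SIDECHAIN_DONORS.get(res, ()):
                donors.append(i)
            if atom in SIDECHAIN_ACCEPTORS.get(res, ()):
                acceptors.append(i)
        elif res in NUCLEOTIDE_RESIDUES:
            if atom == "N6":
                donors.append(i)
            if model.element[i] in ("O", "N"):
                acceptors.append(i)
        elif res == "HOH":
            if atom == "O":
                donors.append(i)
                acceptors.append(i)
        else:
            warnings.warn(f"unknown residue chemistry {res!r}; skipped")
    return donors, acceptors


def _antecedent(model: StructureModel, donor_idx: int) -> int | None:
    """Closest heavy atom covalently plausible as the donor's antecedent."""
    same_res = np.flatnonzero(
        (model.chain == model.chain[donor_idx])
        & (model.res_id == model.res_id[donor_idx])
    )
    best, best_d = None, np.inf
    for j in same_res:
        if j == donor_idx or model.element[j] == "H":
            continue
        d = np.linalg.norm(model.coord[j] - model.coord[donor_idx])
        if 0.8 < d < 1.8 and d < best_d:
            best, best_d = int(j), d
    return best


def hbond_network(
    model: StructureModel,
    d_max: float = 3.5,
    angle_min: float = 90.0,
    include_salt_bridges: bool = True,
    salt_bridge_d_max: float = 4.0,
) -> HBondNetwork:
    """Extract donor-acceptor contacts satisfying the geometric criteria.

    Same-residue pairs are excluded. When the donor has no resolvable
    antecedent atom the angle criterion is waived for that donor.
    """
    if len(model) == 0:
        return HBondNetwork()
    donors, acceptors = _donor_acceptor_indices(model)
    if not donors or not acceptors:
        return HBondNetwork()
    tree = cKDTree(model.coord[acceptors])
    edges = []
    seen = set()
    for di in donors:
        ante = _antecedent(model, di)
        for k in tree.query_ball_point(model.coord[di], r=d_max):
            ai = acceptors[k]
            if (model.chain[di], model.res_id[di]) == (
                model.chain[ai],
                model.res_id[ai],
            ):
                continue
            dist = float(np.linalg.norm(model.coord[ai] - model.coord[di]))
            if dist < 1.5:  # clash/covalent, not an H-bond
                continue
            angle = None
            if ante is not None:
                v1 = model.coord[ante] - model.coord[di]
                v2 = model.coord[ai] - model.coord[di]
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2)
                )
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < angle_min:
                    continue
            key = (di, ai)
            if key in seen:
                continue
            seen.add(key)
            edges.append(
                HBond(
                    donor=_atom_id(model, di),
                    acceptor=_atom_id(model, ai),
                    distance=dist,
                    angle=angle,
                )
            )
    if include_salt_bridges:
        edges.extend(_salt_bridges(model, salt_bridge_d_max, seen))
    return HBondNetwork(edges=edges)


def _atom_id(model: StructureModel, i: int) -> tuple:
    return (
        str(model.chain[i]),
        int(model.res_id[i]),
        str(model.res_name[i]),
        str(model.atom_name[i]),
    )


def _salt_bridges(model: StructureModel, d_max: float, seen: set):
    pos, neg = [], []
    for i in range(len(model)):
        res, atom = model.res_name[i], model.atom_name[i]
        if atom in POSITIVE_RESIDUES.get(res, ()):
            pos.append(i)
        if atom in NEGATIVE_RESIDUES.get(res, ()):
            neg.append(i)
    if not pos or not neg:
        return []
    tree = cKDTree(model.coord[neg])
    out = []
    for pi in pos:
        for k in tree.query_ball_point(model.coord[pi], r=d_max):
            ni = neg[k]
            if (pi, ni) in seen:
                continue
            seen.add((pi, ni))
            dist = float(np.linalg.norm(model.coord[ni] - model.coord[pi]))
            if dist < 1.5:
                continue
            out.append(
                HBond(
                    donor=_atom_id(model, pi),
                    acceptor=_atom_id(model, ni),
                    distance=dist,
                    angle=None,
                )
            )
    return out


def network_diff(net_a: HBondNetwork, net_b: HBondNetwork) -> dict:
    """Residue-pair level set difference between two networks.

    Returns ``{"lost": ..., "gained": ...}``: pairs present in A but not B
    and vice versa, as sorted label strings.
    """
    pairs_a = {e.residue_pair: e for e in net_a.edges}
    pairs_b = {e.residue_pair: e for e in net_b.edges}
    lost = sorted(pairs_a[p].label() for p in set(pairs_a) - set(pairs_b))
    gained = sorted(pairs_b[p].label() for p in set(pairs_b) - set(pairs_a))
    return {"lost": lost, "gained": gained}
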
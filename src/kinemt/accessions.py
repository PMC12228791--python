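"""Helpers for working with deposited coordinate files.

Deposited models mix tubulin, motor and accessory chains; the motor-domain
chains are identified by scoring each chain against conserved nucleotide-
pocket residues (Kif5b numbering, shared by the chimeras). Coordinate
files are looked up in a local directory (default ``data/accessions``)
since the analysis never downloads anything itself.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .structmodel import StructureModel

# conserved motor-domain markers in Kif5b numbering
MOTOR_SIGNATURE = {
    87: "THR",
    88: "SER",
    91: "LYS",
    92: "THR",
    190: "ARG",
    199: "GLU",
    231: "ASP",
    236: "GLU",
}


def accession_path(code: str, directory="data/accessions") -> Path | None:
    """Local coordinate file for an accession, or None when absent."""
    directory = Path(directory)
    for suffix in (".cif", ".mmcif", ".pdb", ".ent"):
        for name in (code.lower(), code.upper()):
            p = directory / f"{name}{suffix}"
            if p.exists():
                return p
    return None


def load_accession(code: str, directory="data/accessions") -> StructureModel:
    path = accession_path(code, directory)
    if path is None:
        raise FileNotFoundError(
            f"no local coordinate file for {code} under {directory}"
        )
    return StructureModel.from_file(path)


def motor_signature_score(model: StructureModel, chain: str) -> int:
    sub = model.select(chain=chain, atom_names="CA")
    score = 0
    for res_id, res_name in MOTOR_SIGNATURE.items():
        hit = sub.res_name[sub.res_id == res_id]
        if hit.size and hit[0] == res_name:
            score += 1
    return score


def motor_chains(model: StructureModel, min_score: int = 5) -> list[str]:
    """Chain ids that look like kinesin motor domains, best first."""
    scored = []
    for chain in sorted(set(model.chain)):
        s = motor_signature_score(model, chain)
        if s >= min_score:
            n_ca = int(np.sum((model.chain == chain) & (model.atom_name == "CA")))
            scored.append((-s, -n_ca, chain))
    return [c for _, _, c in sorted(scored)]
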
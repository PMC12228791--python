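"""Quantitative comparison of motor-domain atomic models.

Selection-restricted Kabsch superposition, global and per-residue RMSD,
single-residue CA displacement after frame alignment, and rigid-rotation
decomposition of the distal head in two-headed complexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch, rmsd, rotation_angle_axis
from .structmodel import FRAME_SELECTION, StructureModel


@dataclass
class SuperpositionResult:
    """Outcome of a rigid least-squares superposition."""

    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,), Å
    selection: str
    rmsd_global: float  # Å, over the scoring set
    rmsd_per_residue: dict  # residue id -> Å
    rotation_angle: float  # degrees, in [0, 180]
    rotation_axis: np.ndarray | None  # unit vector, None if angle ~ 0
    n_fit_atoms: int

    def apply(self, model: StructureModel) -> StructureModel:
        return model.transformed(self.rotation, self.translation)


def _pair_atoms(
    mobile: StructureModel,
    reference: StructureModel,
    ignore_chain: bool,
):
    """Match atoms across two models by identifier; returns index arrays."""

    def keys(m):
        if ignore_chain:
            return list(zip(m.res_id, m.atom_name))
        return list(zip(m.chain, m.res_id, m.atom_name))

    ref_lookup = {k: i for i, k in enumerate(keys(reference))}
    mob_idx, ref_idx = [], []
    for i, k in enumerate(keys(mobile)):
        j = ref_lookup.get(k)
        if j is not None:
            mob_idx.append(i)
            ref_idx.append(j)
    return np.asarray(mob_idx, dtype=int), np.asarray(ref_idx, dtype=int)


def _collinear(points: np.ndarray) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] < 1e-8 * max(s[0], 1.0)


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection=None,
    atom_subset: str | None = "CA",
    score_selection=None,
    ignore_chain: bool = True,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    ``selection`` restricts the atoms used to *fit* the transform (a named
    selection, tuple of names, or ``(lo, hi)`` residue range); the global
    RMSD is scored over ``score_selection`` (default: all matched atoms of
    ``atom_subset``). Atoms pair by (residue number, atom name), ignoring
    chain by default — chimeras keep the wild-type numbering.
    """

    def restrict(model, sel):
        out = model
        if atom_subset is not None:
            out = out.select(atom_names=atom_subset)
        if sel is not None:
            if (
                isinstance(sel, tuple)
                and len(sel) == 2
                and all(isinstance(x, (int, np.integer)) for x in sel)
            ):
                out = out.select(res_range=sel)
            elif isinstance(sel, (list, np.ndarray, set, frozenset)):
                out = out.select(res_ids=sel)
            else:
                out = out.select(selection_name=sel)
        return out

    fit_mobile = restrict(mobile, selection)
    fit_reference = restrict(reference, selection)
    mob_idx, ref_idx = _pair_atoms(fit_mobile, fit_reference, ignore_chain)
    if mob_idx.size == 0 and selection is not None:
        raise ValueError(
            f"selection {selection!r} matched no atom pairs between models"
        )
    if mob_idx.size < 3:
        raise ValueError(
            f"need >= 3 paired atoms to superpose, got {mob_idx.size}"
        )
    P = fit_mobile.coord[mob_idx]
    Q = fit_reference.coord[ref_idx]
    if _collinear(P) or _collinear(Q):
        raise ValueError("fit atoms are collinear; superposition underdetermined")
    R, t = kabsch(P, Q)
    angle, axis = rotation_angle_axis(R)

    score_mobile = restrict(mobile, score_selection)
    score_reference = restrict(reference, score_selection)
    smob, sref = _pair_atoms(score_mobile, score_reference, ignore_chain)
    moved = score_mobile.coord[smob] @ R.T + t
    target = score_reference.coord[sref]
    global_rmsd = rmsd(moved, target)

    per_res: dict = {}
    res_ids = score_mobile.res_id[smob]
    sq = np.sum((moved - target) ** 2, axis=1)
    for rid in np.unique(res_ids):
        per_res[int(rid)] = float(np.sqrt(np.mean(sq[res_ids == rid])))

    return SuperpositionResult(
        rotation=R,
        translation=t,
        selection=str(selection) if selection is not None else "all",
        rmsd_global=global_rmsd,
        rmsd_per_residue=per_res,
        rotation_angle=angle,
        rotation_axis=axis,
        n_fit_atoms=int(mob_idx.size),
    )


def per_residue_rmsd(
    result: SuperpositionResult,
    mobile: StructureModel,
    reference: StructureModel,
    atom_subset: str | None = "CA",
    ignore_chain: bool = True,
) -> dict:
    """Per-residue deviation after applying a computed superposition.

    The quadratic mean of the per-residue values over the scored residues
    equals the global RMSD when the scoring sets coincide (CA subset).
    """
    mob = mobile if atom_subset is None else mobile.select(atom_names=atom_subset)
    ref = (
        reference
        if atom_subset is None
        else reference.select(atom_names=atom_subset)
    )
    mob_idx, ref_idx = _pair_atoms(mob, ref, ignore_chain)
    moved = mob.coord[mob_idx] @ result.rotation.T + result.translation
    sq = np.sum((moved - ref.coord[ref_idx]) ** 2, axis=1)
    res_ids = mob.res_id[mob_idx]
    return {
        int(rid): float(np.sqrt(np.mean(sq[res_ids == rid])))
        for rid in np.unique(res_ids)
    }


def ca_displacement(
    mobile: StructureModel,
    reference: StructureModel,
    residue: int,
    frame_selection=FRAME_SELECTION,
    chain_mobile=None,
    chain_reference=None,
) -> float:
    """CA displacement (Å) of one residue after frame alignment.

    The mobile model is superposed on ``frame_selection`` and the Euclidean
    distance between the residue's CA positions is returned.
    """
    mob = mobile if chain_mobile is None else mobile.select(chain=chain_mobile)
    ref = (
        reference
        if chain_reference is None
        else reference.select(chain=chain_reference)
    )
    result = superpose(mob, ref, selection=frame_selection)
    moved = result.apply(mob)
    try:
        i = np.flatnonzero((moved.res_id == residue) & (moved.atom_name == "CA"))[0]
        j = np.flatnonzero((ref.res_id == residue) & (ref.atom_name == "CA"))[0]
    except IndexError:
        raise KeyError(f"residue {residue} CA missing from one of the models")
    return float(np.linalg.norm(moved.coord[i] - ref.coord[j]))


def rotation_between_heads(
    complex_a: StructureModel,
    complex_b: StructureModel,
    anchor_a: str,
    anchor_b: str,
    distal_a: str,
    distal_b: str,
    res_range=None,
):
    """Rigid rotation of the distal head between two two-headed complexes.

    ``anchor_*`` / ``distal_*`` are chain ids. Complex B is first aligned
    onto complex A through the anchor heads; the residual rigid transform
    mapping A's distal head onto B's aligned distal head is then decomposed
    into (angle degrees, axis). Axis is None when the angle is degenerate.
    """
    a_anchor = complex_a.select(chain=anchor_a, res_range=res_range)
    b_anchor = complex_b.select(chain=anchor_b, res_range=res_range)
    anchor_fit = superpose(b_anchor, a_anchor)
    b_aligned = anchor_fit.apply(complex_b)

    a_distal = complex_a.select(chain=distal_a, res_range=res_range)
    b_distal = b_aligned.select(chain=distal_b, res_range=res_range)
    distal_fit = superpose(a_distal, b_distal)
    return distal_fit.rotation_angle, distal_fit.rotation_axis
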
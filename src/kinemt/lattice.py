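"""Microtubule pseudo-helical lattice parameters and seam/register hypotheses.

A B-lattice microtubule with N protofilaments has a single seam, so a
filament's lateral register is ambiguous among N seam positions, each of
which additionally admits a one-monomer (~41 Å) axial shift swapping the
alpha/beta assignment — 2N hypotheses in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class HelicalLattice:
    """Helical symmetry bookkeeping for an N-protofilament microtubule.

    Defaults correspond to the canonical 13-protofilament 3-start B-lattice:
    -27.69 degrees twist and 9.46 Å rise per tubulin monomer, with an 82 Å
    dimer repeat along a protofilament.
    """

    n_pf: int = 13
    twist_per_subunit: float = field(default=None)  # degrees
    rise_per_subunit: float = 9.46  # Å
    dimer_repeat: float = 82.0  # Å
    monomer_repeat: float = field(default=None)  # Å

    def __post_init__(self):
        if self.n_pf < 1:
            raise ValueError(f"n_pf must be >= 1, got {self.n_pf}")
        if self.twist_per_subunit is None:
            object.__setattr__(self, "twist_per_subunit", -360.0 / self.n_pf)
        if self.monomer_repeat is None:
            object.__setattr__(self, "monomer_repeat", self.dimer_repeat / 2.0)
        if abs(self.dimer_repeat - 2.0 * self.monomer_repeat) > 0.1:
            raise ValueError(
                "dimer_repeat must equal 2 x monomer_repeat within 0.1 Å "
                f"(got {self.dimer_repeat} vs 2x{self.monomer_repeat})"
            )

    @property
    def n_registers(self) -> int:
        """Number of distinct seam/register hypotheses (2N)."""
        return 2 * self.n_pf


@dataclass(frozen=True)
class SeamHypothesis:
    """One seam-position/axial-register hypothesis.

    ``index`` runs over [0, 2N); indices >= N are the one-monomer axial
    counterparts of indices [0, N).
    """

    index: int
    delta_phi: float  # degrees, rotation about the helical axis
    delta_z: float  # Å, translation along the helical axis
    description: str = ""


def enumerate_seam_references(lattice: HelicalLattice) -> list[SeamHypothesis]:
    """Enumerate all 2N seam/register hypotheses for a lattice.

    The k-th seam position carries a rotation of ``k * 360/N`` degrees and an
    axial rise of ``k * rise_per_subunit``; each is paired with a counterpart
    translated one further monomer along the helical axis.
    """
    if lattice.n_pf < 1:
        raise ValueError("lattice must have n_pf >= 1")
    n = lattice.n_pf
    hypotheses = []
    for register in range(2):
        for k in range(n):
            dz = k * lattice.rise_per_subunit + register * lattice.monomer_repeat
            hypotheses.append(
                SeamHypothesis(
                    index=register * n + k,
                    delta_phi=k * (360.0 / n),
                    delta_z=dz,
                    description=(
                        f"seam position {k}"
                        + (", +1 monomer axial register" if register else "")
                    ),
                )
            )
    return hypotheses
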
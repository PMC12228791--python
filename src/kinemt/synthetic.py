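"""Synthetic fixtures with known ground truth.

Three generators back the test suite and acceptance checks:

* filament segment tables with smooth true orientations, additive angular
  and shift noise, replacement outliers, and register class votes drawn
  from a row-stochastic confusion model;
* toy structure pairs related by a known rigid transform plus optional
  per-residue displacement vectors;
* overdamped-Langevin ligand-in-well trajectories with a tunable escape
  bias, standing in for nucleotide-release simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .filament import FilamentTable
from .geometry import kabsch, wrap_deg
from .lattice import HelicalLattice
from .mdobs import TrajectorySeries
from .structmodel import StructureModel


# ---------------------------------------------------------------------------
# filament tables


@dataclass
class FilamentSimSpec:
    """Parameters for synthetic microtubule segment tables."""

    n_filaments: int = 10
    segments_per_filament: int = 20
    lattice: HelicalLattice = field(default_factory=HelicalLattice)
    angle_noise_sd: float = 2.0  # degrees
    shift_noise_sd: float = 1.0  # Å
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 60.0  # degrees
    class_confusion: np.ndarray | None = None  # (2N, 2N) row-stochastic
    true_registers: np.ndarray | None = None  # per-filament, in [0, 2N)
    drift_order: int = 2  # 0 constant, 1 linear, 2 quadratic true tracks
    seed: int = 0

    def __post_init__(self):
        n_reg = self.lattice.n_registers
        if self.segments_per_filament < 1:
            raise ValueError("segments_per_filament must be >= 1")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.class_confusion is None:
            self.class_confusion = np.eye(n_reg)
        self.class_confusion = np.asarray(self.class_confusion, dtype=float)
        if self.class_confusion.shape != (n_reg, n_reg):
            raise ValueError(
                f"confusion matrix must be ({n_reg}, {n_reg}) for this lattice"
            )
        rowsums = self.class_confusion.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9) or np.any(self.class_confusion < 0):
            raise ValueError("confusion matrix rows must be >= 0 and sum to 1")
        if self.true_registers is not None:
            self.true_registers = np.asarray(self.true_registers, dtype=int)
            if self.true_registers.shape != (self.n_filaments,):
                raise ValueError("true_registers must have one entry per filament")
            if np.any((self.true_registers < 0) | (self.true_registers >= n_reg)):
                raise ValueError("true_registers must lie in [0, 2N)")


def uniform_confusion(n_classes: int, p_true: float) -> np.ndarray:
    """Row-stochastic confusion with ``p_true`` on the diagonal and the
    remainder spread uniformly over the other classes."""
    off = (1.0 - p_true) / (n_classes - 1) if n_classes > 1 else 0.0
    M = np.full((n_classes, n_classes), off)
    np.fill_diagonal(M, p_true if n_classes > 1 else 1.0)
    return M


def make_filament_table(spec: FilamentSimSpec):
    """Generate a noisy segment table plus its ground-truth record.

    True psi/rot/shift tracks are per-filament quadratics in segment index
    (slowly bending filaments); observations add Gaussian noise, and an
    ``outlier_fraction`` of rows have the noisy value *replaced* by a
    uniform draw within +/- outlier_magnitude of truth. Class votes are
    i.i.d. from the confusion row of the filament's true register.
    """
    rng = np.random.default_rng(spec.seed)
    n_reg = spec.lattice.n_registers
    true_registers = spec.true_registers
    if true_registers is None:
        true_registers = rng.integers(0, n_reg, size=spec.n_filaments)

    rows = []
    truth_rows = []
    s = np.arange(spec.segments_per_filament, dtype=float)
    for f in range(spec.n_filaments):
        # quadratic drift: gentle bending, coefficients in fixed ranges
        def quad(scale_lin, scale_quad, offset_range):
            a0 = rng.uniform(*offset_range)
            a1 = rng.uniform(-scale_lin, scale_lin)
            a2 = rng.uniform(-scale_quad, scale_quad)
            if spec.drift_order < 2:
                a2 = 0.0
            if spec.drift_order < 1:
                a1 = 0.0
            return a0 + a1 * s + a2 * s**2

        true_psi = wrap_deg(quad(0.5, 0.01, (-180.0, 180.0)))
        true_rot = np.full_like(s, wrap_deg(rng.uniform(-180.0, 180.0)))
        true_tilt = np.clip(90.0 + quad(0.1, 0.002, (-3.0, 3.0)), 1.0, 179.0)
        true_x = quad(0.2, 0.005, (-5.0, 5.0))
        true_y = quad(0.2, 0.005, (-5.0, 5.0))

        obs_psi = true_psi + rng.normal(0.0, spec.angle_noise_sd, size=s.size)
        obs_rot = true_rot + rng.normal(0.0, spec.angle_noise_sd, size=s.size)
        obs_tilt = true_tilt + rng.normal(0.0, spec.angle_noise_sd, size=s.size)
        obs_x = true_x + rng.normal(0.0, spec.shift_noise_sd, size=s.size)
        obs_y = true_y + rng.normal(0.0, spec.shift_noise_sd, size=s.size)

        is_outlier = rng.random(s.size) < spec.outlier_fraction
        n_out = int(is_outlier.sum())
        if n_out:
            # outliers replace the noisy value (misalignment to a wrong site)
            obs_psi[is_outlier] = true_psi[is_outlier] + rng.uniform(
                -spec.outlier_magnitude, spec.outlier_magnitude, size=n_out
            )
            obs_x[is_outlier] = true_x[is_outlier] + rng.uniform(
                -spec.outlier_magnitude, spec.outlier_magnitude, size=n_out
            )
            obs_y[is_outlier] = true_y[is_outlier] + rng.uniform(
                -spec.outlier_magnitude, spec.outlier_magnitude, size=n_out
            )

        votes = rng.choice(
            n_reg, size=s.size, p=spec.class_confusion[true_registers[f]]
        )

        for i in range(s.size):
            rows.append(
                dict(
                    filament_id=f + 1,
                    segment_index=i,
                    rot=float(wrap_deg(obs_rot[i])),
                    tilt=float(wrap_deg(obs_tilt[i])),
                    psi=float(wrap_deg(obs_psi[i])),
                    origin_x=float(obs_x[i]),
                    origin_y=float(obs_y[i]),
                    class_id=int(votes[i]),
                )
            )
            truth_rows.append(
                dict(
                    filament_id=f + 1,
                    segment_index=i,
                    rot=float(wrap_deg(true_rot[i])),
                    tilt=float(wrap_deg(true_tilt[i])),
                    psi=float(wrap_deg(true_psi[i])),
                    origin_x=float(true_x[i]),
                    origin_y=float(true_y[i]),
                    register=int(true_registers[f]),
                    outlier=bool(is_outlier[i]),
                )
            )

    table = FilamentTable(pd.DataFrame(rows))
    truth = {
        "registers": {int(f + 1): int(r) for f, r in enumerate(true_registers)},
        "table": pd.DataFrame(truth_rows),
    }
    return table, truth


def write_truth_sidecar(truth: dict, path) -> None:
    """JSON sidecar for a synthetic table's ground truth."""
    payload = {
        "registers": truth["registers"],
        "table": truth["table"].to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# toy structure pairs


@dataclass
class ToyStructurePair:
    """A reference/mobile pair related by a known rigid transform.

    Applying ``rotation @ x + translation`` to the mobile's undisplaced
    residues reproduces the reference coordinates exactly; residues in
    ``displaced_residues`` carry an extra displacement (Å) on top.
    """

    reference: StructureModel
    mobile: StructureModel
    rotation: np.ndarray
    translation: np.ndarray
    displaced_residues: dict


def _rotation_about_random_axis(angle_deg: float, rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def make_toy_structure_pair(
    n_residues: int = 20,
    rotation_angle: float = 0.0,
    displaced: dict | None = None,
    seed: int = 0,
    chain: str = "A",
) -> ToyStructurePair:
    """Build a CA-only pair with a constructed rigid transform.

    ``displaced`` maps residue number to either a scalar displacement
    magnitude (direction drawn at random) or a 3-vector (Å).
    """
    if n_residues < 3:
        raise ValueError("need >= 3 residues for a well-posed superposition")
    displaced = displaced or {}
    rng = np.random.default_rng(seed)
    # non-collinear cloud: random walk with jitter
    coords = np.cumsum(rng.normal(0.0, 2.0, size=(n_residues, 3)), axis=0)
    coords += rng.normal(0.0, 0.5, size=coords.shape)
    res_ids = np.arange(1, n_residues + 1)

    R = (
        np.eye(3)
        if rotation_angle == 0.0
        else _rotation_about_random_axis(rotation_angle, rng)
    )
    t = rng.uniform(-10.0, 10.0, size=3) if rotation_angle != 0.0 else np.zeros(3)

    disp_vectors = {}
    ref_coords = coords.copy()
    for rid, d in displaced.items():
        if rid not in res_ids:
            raise ValueError(f"displaced residue {rid} not in 1..{n_residues}")
        v = np.asarray(d, dtype=float)
        if v.ndim == 0:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            v = float(v) * direction
        disp_vectors[int(rid)] = v

    # mobile such that R @ mobile + t == reference (+ displacement)
    target = ref_coords.copy()
    for rid, v in disp_vectors.items():
        target[rid - 1] += v
    mobile_coords = (target - t) @ R  # == R.T @ (target - t)

    def model(xyz):
        n = len(xyz)
        return StructureModel(
            chain=np.full(n, chain, dtype=object),
            res_id=res_ids.copy(),
            res_name=np.full(n, "ALA", dtype=object),
            atom_name=np.full(n, "CA", dtype=object),
            element=np.full(n, "C", dtype=object),
            coord=np.asarray(xyz, dtype=float),
        )

    return ToyStructurePair(
        reference=model(ref_coords),
        mobile=model(mobile_coords),
        rotation=R,
        translation=t,
        displaced_residues=disp_vectors,
    )


def make_toy_dimer_pair(
    n_residues: int = 30,
    distal_rotation: float = 25.0,
    seed: int = 0,
):
    """Two two-headed complexes whose distal heads differ by a known rotation.

    Returns ``(complexA, complexB, angle)``: both share an identical anchor
    head (chain A); complex B's distal head (chain B) is rotated by
    ``distal_rotation`` degrees about a random axis through its centroid.
    """
    rng = np.random.default_rng(seed)
    pair = make_toy_structure_pair(n_residues=n_residues, seed=seed)
    anchor = pair.reference
    distal_coords = pair.reference.coord + np.array([40.0, 0.0, 0.0])
    R = _rotation_about_random_axis(distal_rotation, rng)
    center = distal_coords.mean(axis=0)
    distal_b = (distal_coords - center) @ R.T + center

    def two_headed(distal_xyz):
        n = n_residues
        return StructureModel(
            chain=np.array(["A"] * n + ["B"] * n, dtype=object),
            res_id=np.concatenate([anchor.res_id, anchor.res_id]),
            res_name=np.full(2 * n, "ALA", dtype=object),
            atom_name=np.full(2 * n, "CA", dtype=object),
            element=np.full(2 * n, "C", dtype=object),
            coord=np.vstack([anchor.coord, distal_xyz]),
        )

    return two_headed(distal_coords), two_headed(distal_b), distal_rotation


# ---------------------------------------------------------------------------
# ligand escape trajectories


@dataclass
class EscapeTrajectorySpec:
    """Overdamped ligand-in-well walk with a tunable outward escape bias."""

    well_depth: float = 0.5  # restoring spring constant, kT-like scale
    noise_scale: float = 0.5  # Å per sqrt(step)
    n_frames: int = 10_000
    timestep: float = 0.1  # ns-equivalent, bookkeeping only
    escape_bias: float = 0.0  # outward drift per step
    well_radius: float = 6.0  # Å, beyond which the restoring force vanishes
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_scale <= 0:
            raise ValueError("noise scale must be > 0")


def stationary_sd(spec: EscapeTrajectorySpec) -> float:
    """Analytic stationary SD of the bound walk (discrete AR(1) form).

    The Euler step with unit dt gives an AR(1) process with coefficient
    ``1 - well_depth``; requires ``0 < well_depth < 2`` for stationarity.
    """
    phi = 1.0 - spec.well_depth
    if not -1.0 < phi < 1.0:
        raise ValueError("no stationary regime for this well_depth")
    return spec.noise_scale / np.sqrt(1.0 - phi**2)


def make_escape_trajectory(spec: EscapeTrajectorySpec) -> TrajectorySeries:
    """Simulate the ligand distance-from-site series.

    Inside ``well_radius`` the radial coordinate relaxes toward 1 Å with
    spring constant ``well_depth``; outside, only the escape bias acts, so
    with sufficient bias the distance grows without return. Reflecting
    boundary at r = 0. The ligand RMSD series is the distance series
    itself (single-particle ligand).
    """
    rng = np.random.default_rng(spec.seed)
    r = np.empty(spec.n_frames)
    r[0] = 1.0
    dt = 1.0
    for i in range(1, spec.n_frames):
        x = r[i - 1]
        drift = spec.escape_bias
        if x < spec.well_radius:
            drift -= spec.well_depth * (x - 1.0)
        x = x + drift * dt + spec.noise_scale * np.sqrt(dt) * rng.normal()
        r[i] = abs(x)
    times = np.arange(spec.n_frames) * spec.timestep
    return TrajectorySeries(
        replica_id="synthetic",
        level=0,
        times=times,
        distances=pd.DataFrame({"ligand_site": r}),
        ligand_rmsd=r.copy(),
    )
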
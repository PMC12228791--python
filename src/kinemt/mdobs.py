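"""Trajectory observables and the adaptive restart-seeding protocol.

Trajectories are neutral coordinate streams: a :class:`Trajectory` holds a
``(n_frames, n_atoms, 3)`` array plus string atom identifiers, and derived
:class:`TrajectorySeries` objects carry time-indexed scalar observables
(pair distances, ligand RMSD) per replica and protocol level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import kabsch

# Monitored atom-pair presets. The fifth monitored distance is reported
# with two different partner residues in different places of the source
# protocol; both presets are shipped and neither is privileged.
PRESET_PAIRS = {
    "s88_e199": [
        ("ADP:PB", "T87:OG1"),
        ("ADP:PB", "S88:OG"),
        ("ADP:PB", "S89:OG"),
        ("ADP:PB", "K91:NZ"),
        ("S88:OG", "E199:OE1"),
    ],
    "s98_e199": [
        ("ADP:PB", "T87:OG1"),
        ("ADP:PB", "S88:OG"),
        ("ADP:PB", "S89:OG"),
        ("ADP:PB", "K91:NZ"),
        ("S98:OG", "E199:OE1"),
    ],
}


@dataclass
class MonitoredPairs:
    """List of (atom_id, atom_id) specifiers to track through a trajectory."""

    pairs: list = field(default_factory=lambda: list(PRESET_PAIRS["s88_e199"]))

    @classmethod
    def preset(cls, name: str) -> "MonitoredPairs":
        return cls(pairs=list(PRESET_PAIRS[name]))

    def names(self) -> list:
        return [f"{a}--{b}" for a, b in self.pairs]


@dataclass
class Trajectory:
    """Coordinate stream: (n_frames, n_atoms, 3) plus atom identifiers."""

    coords: np.ndarray
    atom_ids: list
    times: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.atom_ids) != self.coords.shape[1]:
            raise ValueError("atom_ids length must match n_atoms")
        if self.times is None:
            self.times = np.arange(self.coords.shape[0], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def index_of(self, atom_id: str) -> int:
        try:
            return self.atom_ids.index(atom_id)
        except ValueError:
            raise KeyError(f"atom {atom_id!r} not in trajectory topology")


@dataclass
class TrajectorySeries:
    """Time-indexed observables for one replica."""

    replica_id: str
    level: int
    times: np.ndarray
    distances: pd.DataFrame  # one column per monitored pair, Å
    ligand_rmsd: np.ndarray | None = None  # Å

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.distances) != len(self.times):
            raise ValueError("distance series length mismatch")
        if self.ligand_rmsd is not None:
            self.ligand_rmsd = np.asarray(self.ligand_rmsd, dtype=float)
            if self.ligand_rmsd.size != self.times.size:
                raise ValueError("ligand_rmsd length mismatch")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        df = self.distances.copy()
        df.insert(0, "time", self.times)
        if self.ligand_rmsd is not None:
            df["ligand_rmsd"] = self.ligand_rmsd
        return df


@dataclass
class ProtocolLevel:
    n_seed_frames: int
    replicas_per_seed: int
    replica_length_ns: float

    def __post_init__(self):
        if self.n_seed_frames < 0 or self.replicas_per_seed < 0:
            raise ValueError("protocol counts must be >= 0")
        if self.replica_length_ns <= 0:
            raise ValueError("replica length must be > 0")


@dataclass
class ProtocolPlan:
    """Adaptive seeding plan: a list of restart levels."""

    levels: list = field(default_factory=list)

    @classmethod
    def adaptive_release_protocol(cls) -> "ProtocolPlan":
        """Level 1: 1x3x1000 ns, Level 2: 2x5x150 ns, Level 3: 7x5x150 ns."""
        return cls(
            levels=[
                ProtocolLevel(1, 3, 1000.0),
                ProtocolLevel(2, 5, 150.0),
                ProtocolLevel(7, 5, 150.0),
            ]
        )


def pair_distance_series(
    trajectory: Trajectory,
    pairs: MonitoredPairs,
    replica_id: str = "r0",
    level: int = 1,
) -> TrajectorySeries:
    """Per-frame Euclidean distances (Å) for each monitored pair."""
    columns = {}
    for a, b in pairs.pairs:
        ia, ib = trajectory.index_of(a), trajectory.index_of(b)
        d = np.linalg.norm(
            trajectory.coords[:, ia, :] - trajectory.coords[:, ib, :], axis=1
        )
        columns[f"{a}--{b}"] = d
    return TrajectorySeries(
        replica_id=replica_id,
        level=level,
        times=trajectory.times,
        distances=pd.DataFrame(columns),
    )


def distance_fluctuation_sd(series_set: list) -> pd.DataFrame:
    """Per-pair distance SD per replica, with cross-replica mean and s.e.m.

    Returns a DataFrame indexed by pair name with one column per replica
    plus ``mean`` and ``sem`` columns (s.e.m. = SD of replica SDs / sqrt(n)).
    """
    if not series_set:
        raise ValueError("need at least one replica")
    per_replica = {}
    for s in series_set:
        if s.n_frames < 2:
            raise ValueError(f"replica {s.replica_id} has a single frame")
        per_replica[s.replica_id] = s.distances.std(ddof=1)
    table = pd.DataFrame(per_replica)
    n = table.shape[1]
    table["mean"] = table.iloc[:, :n].mean(axis=1)
    if n > 1:
        table["sem"] = table.iloc[:, :n].std(axis=1, ddof=1) / np.sqrt(n)
    else:
        table["sem"] = np.nan
    return table


def ligand_rmsd_series(
    trajectory: Trajectory,
    ligand_ids: list,
    align_ids: list,
    reference_frame: int = 0,
    reference_coords: np.ndarray | None = None,
) -> np.ndarray:
    """Ligand RMSD per frame after rigid alignment on a CA set.

    Each frame is superposed onto the reference frame using ``align_ids``
    only; the RMSD is then computed over ``ligand_ids`` without further
    fitting. Invariant to any global rigid motion of a frame.
    """
    lig = [trajectory.index_of(a) for a in ligand_ids]
    ali = [trajectory.index_of(a) for a in align_ids]
    if len(ali) < 3:
        raise ValueError("need >= 3 alignment atoms")
    ref = (
        trajectory.coords[reference_frame]
        if reference_coords is None
        else np.asarray(reference_coords, dtype=float)
    )
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        R, t = kabsch(trajectory.coords[f][ali], ref[ali])
        moved = trajectory.coords[f][lig] @ R.T + t
        out[f] = np.sqrt(np.mean(np.sum((moved - ref[lig]) ** 2, axis=1)))
    return out


def density2d(x, y, bins=50):
    """Normalized 2D histogram of two observables.

    Returns ``(masses, x_edges, y_edges)`` with ``masses.sum() == 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    if x.size != y.size:
        raise ValueError("series lengths differ")
    H, xe, ye = np.histogram2d(x, y, bins=bins)
    return H / H.sum(), xe, ye


def restart_scores(series: TrajectorySeries) -> np.ndarray:
    """Combined per-frame progress score used for restart-frame selection.

    z-score of the ligand RMSD plus the mean over monitored pairs of the
    z-score of the absolute deviation from the starting distance. z-scores
    use the replica's own mean/SD; constant observables contribute zero,
    which makes the score invariant to affine rescaling of any observable.
    """

    def zscore(v):
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd

    parts = []
    if series.ligand_rmsd is not None:
        parts.append(zscore(series.ligand_rmsd))
    dev_z = [
        zscore(np.abs(series.distances[c].to_numpy() - series.distances[c].iloc[0]))
        for c in series.distances.columns
    ]
    if dev_z:
        parts.append(np.mean(dev_z, axis=0))
    if not parts:
        raise ValueError("series has neither ligand RMSD nor distances")
    return np.sum(parts, axis=0)


def select_restart_frames(series: TrajectorySeries, k: int) -> list:
    """Indices of the k highest-scoring frames (ties -> earlier frame)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > series.n_frames:
        raise ValueError(f"k={k} exceeds {series.n_frames} frames")
    scores = restart_scores(series)
    order = np.lexsort((np.arange(scores.size), -scores))
    return sorted(int(i) for i in order[:k])


def detect_release(
    series: TrajectorySeries,
    threshold: float = 20.0,
    dwell: int = 100,
) -> int | None:
    """First frame of sustained ligand release, or None.

    A release at frame t requires the ligand RMSD to exceed ``threshold``
    for at least ``dwell`` consecutive frames starting at t, with no later
    return below ``threshold / 2``.
    """
    if series.ligand_rmsd is None:
        raise ValueError("series has no ligand RMSD")
    r = series.ligand_rmsd
    n = r.size
    if not np.isfinite(threshold):
        return None
    above = r > threshold
    rebound_ok = np.empty(n, dtype=bool)  # no future dip below threshold/2
    ok = True
    for i in range(n - 1, -1, -1):
        ok = ok and (r[i] >= threshold / 2.0)
        rebound_ok[i] = ok
    run = 0
    for i in range(n):
        run = run + 1 if above[i] else 0
        if run >= dwell:
            start = i - dwell + 1
            if rebound_ok[start]:
                return start
    return None


def ion_coordination_count(
    trajectory: Trajectory,
    ion_ids: list,
    site_ids: list,
    cutoff: float = 3.5,
):
    """Per-frame count of ions within ``cutoff`` of any site atom, and mean."""
    ions = [trajectory.index_of(a) for a in ion_ids]
    sites = [trajectory.index_of(a) for a in site_ids]
    counts = np.zeros(trajectory.n_frames, dtype=int)
    if cutoff <= 0 or not ions or not sites:
        return counts, 0.0
    for f in range(trajectory.n_frames):
        ion_xyz = trajectory.coords[f][ions]
        site_xyz = trajectory.coords[f][sites]
        d = np.linalg.norm(ion_xyz[:, None, :] - site_xyz[None, :, :], axis=2)
        counts[f] = int(np.sum(d.min(axis=1) <= cutoff))
    return counts, float(counts.mean())


def sim_time_ledger(plan: ProtocolPlan) -> dict:
    """Total simulation time (μs) and per-level breakdown of a plan."""
    breakdown = []
    total_ns = 0.0
    for i, level in enumerate(plan.levels, start=1):
        ns = level.n_seed_frames * level.replicas_per_seed * level.replica_length_ns
        total_ns += ns
        breakdown.append(
            {
                "level": i,
                "n_seed_frames": level.n_seed_frames,
                "replicas_per_seed": level.replicas_per_seed,
                "replica_length_ns": level.replica_length_ns,
                "total_ns": ns,
                "total_us": ns / 1000.0,
            }
        )
    return {"total_us": total_ns / 1000.0, "levels": breakdown}
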
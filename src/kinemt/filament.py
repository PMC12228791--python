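"""Per-filament metadata consensus for microtubule segment tables.

Implements the bookkeeping applied between alignment rounds of helical
processing: modal class voting per filament, smoothing of in-plane angles
and shifts along each filament, circular-median phi assignment, signal
averaging over adjacent segments, seam/register assignment against the 2N
lattice hypotheses, symmetry expansion into per-protofilament asymmetric
units, and focused sub-particle re-centering.

A :class:`FilamentTable` wraps a :class:`pandas.DataFrame` with internal
column names; the mapping to/from the Relion STAR dialect lives in
:func:`read_filament_star` / :func:`write_filament_star`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import star as star_io
from .geometry import (
    circ_distance_deg,
    circ_mean_deg,
    circ_median_deg,
    euler_zyz_to_matrix,
    matrix_to_euler_zyz,
    pose_to_matrix,
    rot_z_matrix,
    wrap_deg,
)
from .lattice import HelicalLattice, SeamHypothesis, enumerate_seam_references

ANGLE_COLUMNS = ("rot", "tilt", "psi")
CORE_COLUMNS = (
    "filament_id",
    "segment_index",
    "rot",
    "tilt",
    "psi",
    "origin_x",
    "origin_y",
    "class_id",
)

# internal name -> Relion particle-star name
STAR_COLUMN_MAP = {
    "filament_id": "rlnHelicalTubeID",
    "segment_index": "rlnHelicalSegmentIndex",
    "rot": "rlnAngleRot",
    "tilt": "rlnAngleTilt",
    "psi": "rlnAnglePsi",
    "origin_x": "rlnOriginXAngst",
    "origin_y": "rlnOriginYAngst",
    "class_id": "rlnClassNumber",
    "signal": "rlnSignalValue",
    "axial_offset": "rlnHelicalAxialOffset",
    "subunit_index": "rlnSymmetryIndex",
}


@dataclass
class FilamentTable:
    """Segment-level metadata for a set of microtubule filaments."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"FilamentTable missing columns: {missing}")
        if self.df["filament_id"].isna().any():
            raise ValueError("every row needs a filament_id")
        for fid, grp in self.df.groupby("filament_id"):
            idx = grp["segment_index"].to_numpy()
            if not np.all(np.diff(idx) > 0):
                raise ValueError(
                    f"segment_index not strictly increasing in filament {fid}"
                )
        for col in ANGLE_COLUMNS:
            vals = self.df[col].to_numpy(dtype=float)
            if np.any(vals < -180.0) or np.any(vals >= 180.0):
                raise ValueError(f"angle column {col!r} outside [-180, 180)")

    def copy(self) -> "FilamentTable":
        return FilamentTable(self.df.copy())

    @property
    def n_filaments(self) -> int:
        return self.df["filament_id"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def groupby_filament(self):
        return self.df.groupby("filament_id", sort=True)


@dataclass
class OccupancyReport:
    """Counts and fractions of asymmetric units per motor-state class."""

    counts: dict
    fractions: dict = field(init=False)

    def __post_init__(self):
        total = sum(self.counts.values())
        if total <= 0:
            raise ValueError("occupancy report needs at least one labeled unit")
        self.fractions = {k: v / total for k, v in self.counts.items()}

    def as_dict(self) -> dict:
        return {"counts": dict(self.counts), "fractions": dict(self.fractions)}


def _modal(votes, valid_range=None):
    votes = [int(v) for v in votes]
    if not votes:
        raise ValueError("no votes")
    if valid_range is not None:
        lo, hi = valid_range
        bad = [v for v in votes if not (lo <= v < hi)]
        if bad:
            raise ValueError(f"votes outside [{lo}, {hi}): {sorted(set(bad))}")
    counts = Counter(votes)
    top = max(counts.values())
    # tie-break: smallest class index
    return min(v for v, c in counts.items() if c == top)


def modal_class_vote(table: FilamentTable):
    """Assign each filament's modal class to all of its segments.

    Returns ``(votes, new_table)`` where ``votes`` maps filament_id to the
    winning class. Ties resolve to the smallest class id.
    """
    df = table.df.copy()
    if df["class_id"].isna().any():
        bad = df.loc[df["class_id"].isna(), "filament_id"].unique()
        raise ValueError(f"filaments with missing class votes: {list(bad)}")
    votes = {
        fid: _modal(grp["class_id"]) for fid, grp in table.groupby_filament()
    }
    df["class_id"] = df["filament_id"].map(votes)
    return votes, FilamentTable(df)


def _running_median(values, window, circular):
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)  # symmetric truncation at filament ends
        chunk = values[i - k : i + k + 1]
        out[i] = circ_median_deg(chunk) if circular else float(np.median(chunk))
    return out

def _running_mean(values, window, circular):
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        chunk = values[i - k : i + k + 1]
        out[i] = circ_mean_deg(chunk) if circular else float(np.mean(chunk))
    return out


def smooth_inplane(
    table: FilamentTable,
    window: int = 5,
    outlier_threshold_deg: float = 8.0,
    outlier_threshold_shift: float = 8.0,
) -> FilamentTable:
    """Smooth psi and the x/y origin shifts along each filament.

    Per filament and per column, values deviating from the running
    (circular for psi) median by more than the outlier threshold are
    replaced by that median; the corrected series is then replaced by a
    centred moving (circular) mean. Windows are truncated symmetrically at
    filament ends so that linear drifts are exact fixed points.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    df = table.df.copy()
    specs = [
        ("psi", True, outlier_threshold_deg),
        ("origin_x", False, outlier_threshold_shift),
        ("origin_y", False, outlier_threshold_shift),
    ]
    for fid, grp in table.groupby_filament():
        order = grp.index
        for col, circular, threshold in specs:
            vals = grp[col].to_numpy(dtype=float)
            med = _running_median(vals, window, circular)
            dev = circ_distance_deg(vals, med) if circular else np.abs(vals - med)
            corrected = np.where(dev > threshold, med, vals)
            smoothed = _running_mean(corrected, window, circular)
            if circular:
                smoothed = wrap_deg(smoothed)
            df.loc[order, col] = smoothed
    return FilamentTable(df)


def assign_phi_median(table: FilamentTable) -> FilamentTable:
    """Assign each filament's circular-median rot (phi) to all its rows."""
    df = table.df.copy()
    medians = {
        fid: circ_median_deg(grp["rot"].to_numpy(dtype=float))
        for fid, grp in table.groupby_filament()
    }
    df["rot"] = df["filament_id"].map(medians)
    return FilamentTable(df)


def segment_average(
    table: FilamentTable, partners: int = 7, column: str = "signal"
) -> FilamentTable:
    """Average each segment's signal with its nearest partners in the filament.

    Each segment is averaged with itself plus its `partners` nearest
    segments by index distance within the same filament (distance ties take
    the lower index); shorter filaments average over all available rows.
    """
    if column not in table.df.columns:
        raise ValueError(f"table has no {column!r} column to average")
    df = table.df.copy()
    for fid, grp in table.groupby_filament():
        idx = grp["segment_index"].to_numpy(dtype=float)
        vals = grp[column].to_numpy(dtype=float)
        n = len(grp)
        take = min(partners + 1, n)
        out = np.empty(n)
        for i in range(n):
            # sort by (index distance, segment index): ties -> lower index
            order = np.lexsort((idx, np.abs(idx - idx[i])))
            out[i] = vals[order[:take]].mean()
        df.loc[grp.index, column] = out
    return FilamentTable(df)


def assign_seam_register(
    table: FilamentTable,
    lattice: HelicalLattice,
    vote_column: str = "class_id",
):
    """Assign each filament the modal seam/register hypothesis of its votes.

    Votes are indices into :func:`enumerate_seam_references` (range
    ``[0, 2N)``); ties go to the smallest index. Rows of each filament are
    updated by composing the winning hypothesis with their pose: delta_phi
    is added to rot and delta_z is recorded in an ``axial_offset`` column.

    Returns ``(assignments, new_table)`` with ``assignments`` mapping
    filament_id to the winning :class:`SeamHypothesis`.
    """
    hypotheses = enumerate_seam_references(lattice)
    df = table.df.copy()
    assignments = {}
    for fid, grp in table.groupby_filament():
        k = _modal(grp[vote_column], valid_range=(0, lattice.n_registers))
        hyp = hypotheses[k]
        assignments[fid] = hyp
        df.loc[grp.index, "rot"] = wrap_deg(
            grp["rot"].to_numpy(dtype=float) + hyp.delta_phi
        )
        df.loc[grp.index, "axial_offset"] = hyp.delta_z
        df.loc[grp.index, vote_column] = k
    return assignments, FilamentTable(df)


def _pose_matrix_from_row(row) -> np.ndarray:
    shift = (row["origin_x"], row["origin_y"], row.get("axial_offset", 0.0))
    return pose_to_matrix(row["rot"], row["tilt"], row["psi"], shift)


def symmetry_expand(table: FilamentTable, lattice: HelicalLattice) -> FilamentTable:
    """Expand each segment pose by the n_pf lattice symmetry operators.

    The j-th copy composes the row's pose with a rotation of ``j * 360/N``
    about the helical axis plus a ``j * rise_per_subunit`` axial offset, in
    the ZYZ Euler / Å shift parameterization. Output has ``n_pf x`` the
    input rows and a ``subunit_index`` column; ``j = 0`` rows are identical
    to the input.
    """
    records = []
    df = table.df
    for (_, row), fid in zip(df.iterrows(), df["filament_id"]):
        T = _pose_matrix_from_row(row)
        for j in range(lattice.n_pf):
            if j == 0:
                new = row.to_dict()
                new.setdefault("axial_offset", 0.0)
                if pd.isna(new["axial_offset"]):
                    new["axial_offset"] = 0.0
            else:
                G = rot_z_matrix(j * 360.0 / lattice.n_pf)
                G[2, 3] = j * lattice.rise_per_subunit
                Tj = T @ G
                rot, tilt, psi = matrix_to_euler_zyz(Tj[:3, :3])
                new = row.to_dict()
                new.update(
                    rot=rot,
                    tilt=tilt,
                    psi=psi,
                    origin_x=Tj[0, 3],
                    origin_y=Tj[1, 3],
                    axial_offset=Tj[2, 3],
                )
            new["subunit_index"] = j
            # re-key so the per-filament segment_index invariant survives:
            # (filament, subunit) becomes the grouping identity
            new["filament_id"] = f"{fid}/pf{j}"
            records.append(new)
    out = pd.DataFrame.from_records(records)
    out = out.sort_values(["filament_id", "segment_index"], kind="stable")
    out = out.reset_index(drop=True)
    return FilamentTable(out)


def subparticle_coords(table: FilamentTable, focus_offset) -> FilamentTable:
    """Re-center 2D origins on a focused sub-particle.

    ``focus_offset`` is a 3-vector in the reference frame (Å). Each row's
    origin is shifted by the in-plane projection of the rotated offset;
    calling again with the negated offset restores the original origins.
    """
    offset = np.asarray(focus_offset, dtype=float)
    if offset.shape != (3,):
        raise ValueError("focus_offset must be a 3-vector")
    df = table.df.copy()
    rots = df["rot"].to_numpy(dtype=float)
    tilts = df["tilt"].to_numpy(dtype=float)
    psis = df["psi"].to_numpy(dtype=float)
    dx = np.empty(len(df))
    dy = np.empty(len(df))
    for i, (r, t, p) in enumerate(zip(rots, tilts, psis)):
        v = euler_zyz_to_matrix(r, t, p) @ offset
        dx[i], dy[i] = v[0], v[1]
    df["origin_x"] = df["origin_x"].to_numpy(dtype=float) - dx
    df["origin_y"] = df["origin_y"].to_numpy(dtype=float) - dy
    return FilamentTable(df)


def occupancy_stats(labels) -> OccupancyReport:
    """Count motor-state classes over asymmetric units.

    ``labels`` is either an iterable of per-unit labels or a mapping of
    label -> count.
    """
    if isinstance(labels, dict):
        counts = {k: int(v) for k, v in labels.items()}
    else:
        counts = dict(Counter(labels))
    if not counts or sum(counts.values()) == 0:
        raise ValueError("occupancy_stats needs at least one labeled unit")
    return OccupancyReport(counts=counts)


def read_filament_star(path, block: str = "particles") -> FilamentTable:
    """Read a Relion particle STAR file into a FilamentTable."""
    blocks = star_io.read_star(path)
    if block not in blocks:
        # Relion 3.0 files use a single unnamed/data_ block
        block = next(iter(blocks))
    df = blocks[block]
    reverse = {v: k for k, v in STAR_COLUMN_MAP.items()}
    df = df.rename(columns=reverse)
    if "segment_index" not in df.columns:
        df = df.sort_values("filament_id", kind="stable")
        df["segment_index"] = df.groupby("filament_id").cumcount()
    return FilamentTable(df.reset_index(drop=True))


def write_filament_star(table: FilamentTable, path) -> None:
    """Write a FilamentTable as a Relion particle STAR file."""
    df = table.df.rename(
        columns={k: v for k, v in STAR_COLUMN_MAP.items() if k in table.df.columns}
    )
    star_io.write_star({"particles": df}, path)
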
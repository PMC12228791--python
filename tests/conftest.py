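import numpy as np
import pandas as pd
import pytest

from kinemt.filament import FilamentTable
from kinemt.lattice import HelicalLattice


@pytest.fixture
def lattice13():
    return HelicalLattice(n_pf=13)


def build_table(per_filament: dict, **extra_cols) -> FilamentTable:
    """Build a FilamentTable from {filament_id: {column: list}} specs.

    Unspecified angle/shift columns default to zero; class_id defaults to 1.
    """
    rows = []
    for fid, cols in per_filament.items():
        n = max(len(v) for v in cols.values())
        for i in range(n):
            row = dict(
                filament_id=fid,
                segment_index=i,
                rot=0.0,
                tilt=90.0,
                psi=0.0,
                origin_x=0.0,
                origin_y=0.0,
                class_id=1,
            )
            for col, values in cols.items():
                row[col] = values[i]
            for col, values in extra_cols.items():
                row[col] = values[i]
            rows.append(row)
    return FilamentTable(pd.DataFrame(rows))


def quaternion_superpose(mobile, reference):
    """Independent superposition oracle (Horn's quaternion method).

    Returns (R, t, rmsd) for the transform mapping mobile onto reference.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    Sxx, Sxy, Sxz = (P0[:, 0] * Q0[:, 0]).sum(), (P0[:, 0] * Q0[:, 1]).sum(), (P0[:, 0] * Q0[:, 2]).sum()
    Syx, Syy, Syz = (P0[:, 1] * Q0[:, 0]).sum(), (P0[:, 1] * Q0[:, 1]).sum(), (P0[:, 1] * Q0[:, 2]).sum()
    Szx, Szy, Szz = (P0[:, 2] * Q0[:, 0]).sum(), (P0[:, 2] * Q0[:, 1]).sum(), (P0[:, 2] * Q0[:, 2]).sum()
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = qc - R @ pc
    moved = P @ R.T + t
    return R, t, float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
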
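import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinemt.filament import (
    FilamentTable,
    assign_phi_median,
    assign_seam_register,
    modal_class_vote,
    occupancy_stats,
    segment_average,
    smooth_inplane,
    subparticle_coords,
    symmetry_expand,
)
from kinemt.geometry import circ_distance_deg, circ_mean_deg, wrap_deg
from kinemt.lattice import HelicalLattice
from tests.conftest import build_table


def homogeneous_pose(rot, tilt, psi, shift):
    """4x4 oracle built from explicit cos/sin matrices (independent of scipy)."""

    def rz(a):
        a = np.deg2rad(a)
        return np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )

    def ry(a):
        a = np.deg2rad(a)
        return np.array(
            [[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]]
        )

    T = np.eye(4)
    T[:3, :3] = rz(rot) @ ry(tilt) @ rz(psi)
    T[:3, 3] = shift
    return T


class TestModalClassVote:
    def test_unambiguous_mode(self):
        table = build_table({1: {"class_id": [2, 2, 3]}})
        votes, out = modal_class_vote(table)
        assert votes == {1: 2}
        assert set(out.df["class_id"]) == {2}

    def test_tie_breaks_to_smallest(self):
        table = build_table({1: {"class_id": [1, 1, 2, 2]}})
        votes, _ = modal_class_vote(table)
        assert votes[1] == 1

    def test_single_segment(self):
        table = build_table({1: {"class_id": [5]}})
        votes, _ = modal_class_vote(table)
        assert votes[1] == 5

    def test_missing_votes_error(self):
        table = build_table({1: {"class_id": [1, 2]}})
        table.df.loc[0, "class_id"] = np.nan
        with pytest.raises(ValueError, match="missing class votes"):
            modal_class_vote(table)

    @given(
        st.lists(
            st.lists(st.integers(1, 4), min_size=1, max_size=6),
            min_size=1,
            max_size=3,
        )
    )
    @settings(max_examples=60)
    def test_agrees_with_exhaustive_counting(self, filaments):
        table = build_table(
            {f + 1: {"class_id": votes} for f, votes in enumerate(filaments)}
        )
        result, _ = modal_class_vote(table)
        for f, votes in enumerate(filaments):
            # full enumeration oracle
            counts = {c: votes.count(c) for c in set(votes)}
            best = max(counts.values())
            assert result[f + 1] == min(c for c in counts if counts[c] == best)


class TestSmoothInplane:
    def test_outlier_replaced(self):
        table = build_table({1: {"psi": [10.0] * 4 + [170.0] + [10.0] * 4}})
        out = smooth_inplane(table, window=5, outlier_threshold_deg=8.0)
        np.testing.assert_allclose(out.df["psi"], 10.0, atol=1e-9)

    def test_circular_mean_across_wrap(self):
        table = build_table({1: {"psi": [-1.0, 1.0, -2.0]}})  # 359, 1, 358
        out = smooth_inplane(table, window=3, outlier_threshold_deg=30.0)
        expected_center = circ_mean_deg([359.0, 1.0, 358.0])
        assert expected_center == pytest.approx(wrap_deg(359.3333), abs=1e-3)
        assert out.df["psi"].iloc[1] == pytest.approx(expected_center, abs=1e-9)

    def test_linear_drift_fixed_point(self):
        drift = [float(i) for i in range(11)]
        table = build_table({1: {"psi": drift, "origin_x": drift}})
        out = smooth_inplane(table, window=5, outlier_threshold_deg=10.0,
                             outlier_threshold_shift=10.0)
        np.testing.assert_allclose(out.df["psi"], drift, atol=1e-9)
        np.testing.assert_allclose(out.df["origin_x"], drift, atol=1e-9)

    def test_shift_outlier(self):
        table = build_table({1: {"origin_y": [1.0] * 3 + [40.0] + [1.0] * 3}})
        out = smooth_inplane(table, window=3, outlier_threshold_shift=8.0)
        np.testing.assert_allclose(out.df["origin_y"], 1.0, atol=1e-9)

    @pytest.mark.parametrize("window", [2, 4, 1, 0])
    def test_bad_window_rejected(self, window):
        table = build_table({1: {"psi": [0.0, 0.0, 0.0]}})
        with pytest.raises(ValueError, match="window"):
            smooth_inplane(table, window=window)


class TestAssignPhiMedian:
    def test_odd_plain(self):
        table = build_table({1: {"rot": [10.0, 12.0, 14.0]}})
        out = assign_phi_median(table)
        assert set(out.df["rot"]) == {12.0}

    def test_wraparound(self):
        table = build_table({1: {"rot": [-10.0, 0.0, 10.0]}})  # 350, 0, 10
        out = assign_phi_median(table)
        assert set(out.df["rot"]) == {0.0}

    def test_single_row(self):
        table = build_table({1: {"rot": [33.0]}})
        out = assign_phi_median(table)
        assert out.df["rot"].iloc[0] == 33.0


class TestSegmentAverage:
    def test_single_segment(self):
        table = build_table({1: {"signal": [5.0]}})
        out = segment_average(table, partners=7)
        assert out.df["signal"].iloc[0] == 5.0

    def test_nearest_index_set_with_tie_rule(self):
        values = [float(v) for v in range(1, 11)]
        table = build_table({1: {"signal": values}})
        out = segment_average(table, partners=7)
        # oracle: enumerate the 8-member set for segment value 5 (index 4):
        # distances 1..3 give indices {3,5},{2,6},{1,7}; the 8th member is
        # the distance-4 tie {0, 8}, broken toward the lower index -> 0.
        chosen = [4, 3, 5, 2, 6, 1, 7, 0]
        expected = np.mean([values[i] for i in chosen])
        assert expected == 4.5
        assert out.df["signal"].iloc[4] == pytest.approx(expected)

    def test_constant_signal(self):
        table = build_table({1: {"signal": [3.14] * 12}})
        out = segment_average(table, partners=7)
        np.testing.assert_allclose(out.df["signal"], 3.14)

    def test_short_filament_uses_all(self):
        table = build_table({1: {"signal": [1.0, 2.0, 3.0]}})
        out = segment_average(table, partners=7)
        np.testing.assert_allclose(out.df["signal"], 2.0)

    def test_missing_signal_column(self):
        table = build_table({1: {"psi": [0.0, 0.0]}})
        with pytest.raises(ValueError, match="signal"):
            segment_average(table)


class TestAssignSeamRegister:
    def test_modal_hypothesis(self, lattice13):
        table = build_table({1: {"class_id": [3, 3, 3, 7]}})
        assignments, _ = assign_seam_register(table, lattice13)
        assert assignments[1].index == 3

    def test_all_identical(self, lattice13):
        table = build_table({1: {"class_id": [11] * 5}})
        assignments, out = assign_seam_register(table, lattice13)
        hyp = assignments[1]
        assert hyp.index == 11
        np.testing.assert_allclose(
            out.df["rot"], wrap_deg(0.0 + hyp.delta_phi), atol=1e-9
        )
        np.testing.assert_allclose(out.df["axial_offset"], hyp.delta_z)

    def test_vote_out_of_range(self, lattice13):
        table = build_table({1: {"class_id": [3, 26]}})
        with pytest.raises(ValueError, match="outside"):
            assign_seam_register(table, lattice13)

    def test_monte_carlo_recovery(self, lattice13):
        from kinemt.synthetic import (
            FilamentSimSpec,
            make_filament_table,
            uniform_confusion,
        )

        spec = FilamentSimSpec(
            n_filaments=50,
            segments_per_filament=20,
            lattice=lattice13,
            class_confusion=uniform_confusion(26, 0.6),
            seed=11,
        )
        table, truth = make_filament_table(spec)
        assignments, _ = assign_seam_register(table, lattice13)
        hits = sum(
            assignments[f].index == truth["registers"][f]
            for f in truth["registers"]
        )
        assert hits / len(truth["registers"]) >= 0.95


class TestSymmetryExpand:
    def test_row_count(self, lattice13):
        table = build_table(
            {i: {"psi": [float(i)] * 2} for i in range(1, 6)}
        )  # 10 rows
        out = symmetry_expand(table, lattice13)
        assert len(out) == 130

    def test_identity_copy(self, lattice13):
        table = build_table({1: {"psi": [12.0], "rot": [30.0], "tilt": [80.0]}})
        out = symmetry_expand(table, lattice13)
        j0 = out.df[out.df["subunit_index"] == 0].iloc[0]
        for col in ("rot", "tilt", "psi", "origin_x", "origin_y"):
            assert j0[col] == pytest.approx(table.df.iloc[0][col])

    def test_matches_homogeneous_matrix_oracle(self, lattice13):
        rng = np.random.default_rng(7)
        rows = {}
        n_rows = 20
        for f in range(n_rows):
            rows[f + 1] = {
                "rot": [float(rng.uniform(-180, 180))],
                "tilt": [float(rng.uniform(5, 175))],
                "psi": [float(rng.uniform(-180, 180))],
                "origin_x": [float(rng.uniform(-20, 20))],
                "origin_y": [float(rng.uniform(-20, 20))],
            }
        table = build_table(rows)
        out = symmetry_expand(table, lattice13)
        for f in range(n_rows):
            base = table.df.iloc[f]
            T = homogeneous_pose(
                base["rot"], base["tilt"], base["psi"],
                [base["origin_x"], base["origin_y"], 0.0],
            )
            for j in range(lattice13.n_pf):
                G = homogeneous_pose(j * 360.0 / 13, 0.0, 0.0,
                                     [0.0, 0.0, j * lattice13.rise_per_subunit])
                expected = T @ G
                row = out.df[
                    (out.df["subunit_index"] == j)
                    & (out.df["filament_id"].astype(str).str.split("/").str[0] == str(f + 1))
                ].iloc[0]
                got = homogeneous_pose(
                    row["rot"], row["tilt"], row["psi"],
                    [row["origin_x"], row["origin_y"], row.get("axial_offset", 0.0)],
                )
                np.testing.assert_allclose(got, expected, atol=1e-6)


class TestSubparticleCoords:
    def test_zero_offset_noop(self, lattice13):
        table = build_table({1: {"origin_x": [1.0, 2.0], "origin_y": [3.0, 4.0]}})
        out = subparticle_coords(table, (0.0, 0.0, 0.0))
        np.testing.assert_allclose(out.df["origin_x"], table.df["origin_x"])
        np.testing.assert_allclose(out.df["origin_y"], table.df["origin_y"])

    def test_axial_offset_projects_out(self):
        # identity pose: offset along the projection (z) axis leaves xy alone
        table = build_table({1: {"origin_x": [1.0], "tilt": [0.0]}})
        out = subparticle_coords(table, (0.0, 0.0, 7.0))
        assert out.df["origin_x"].iloc[0] == pytest.approx(1.0)
        assert out.df["origin_y"].iloc[0] == pytest.approx(0.0)

    def test_roundtrip_random_poses(self):
        rng = np.random.default_rng(3)
        rows = {
            f + 1: {
                "rot": [float(rng.uniform(-180, 180))],
                "tilt": [float(rng.uniform(1, 179))],
                "psi": [float(rng.uniform(-180, 180))],
                "origin_x": [float(rng.uniform(-10, 10))],
                "origin_y": [float(rng.uniform(-10, 10))],
            }
            for f in range(30)
        }
        table = build_table(rows)
        offset = np.array([3.0, -4.0, 5.0])
        forward = subparticle_coords(table, offset)
        back = subparticle_coords(forward, -offset)
        np.testing.assert_allclose(
            back.df["origin_x"], table.df["origin_x"], atol=1e-6
        )
        np.testing.assert_allclose(
            back.df["origin_y"], table.df["origin_y"], atol=1e-6
        )


class TestOccupancyStats:
    def test_two_state_fractions(self):
        report = occupancy_stats({"two-headed": 47, "one-headed": 53})
        assert report.fractions["two-headed"] == pytest.approx(0.47)
        assert report.fractions["one-headed"] == pytest.approx(0.53)
        assert sum(report.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_class(self):
        report = occupancy_stats(["decorated"] * 10)
        assert report.fractions == {"decorated": 1.0}

    def test_empty_error(self):
        with pytest.raises(ValueError):
            occupancy_stats([])

    def test_multinomial_within_binomial_bounds(self):
        rng = np.random.default_rng(21)
        probs = {"one": 0.5, "two": 0.3, "none": 0.2}
        n = 5000
        labels = rng.choice(list(probs), size=n, p=list(probs.values()))
        report = occupancy_stats(list(labels))
        for state, p in probs.items():
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(report.fractions[state] - p) <= 3 * sigma


class TestTableInvariants:
    def test_nonmonotonic_segment_index_rejected(self):
        df = pd.DataFrame(
            {
                "filament_id": [1, 1],
                "segment_index": [1, 0],
                "rot": [0.0, 0.0],
                "tilt": [90.0, 90.0],
                "psi": [0.0, 0.0],
                "origin_x": [0.0, 0.0],
                "origin_y": [0.0, 0.0],
                "class_id": [1, 1],
            }
        )
        with pytest.raises(ValueError, match="strictly increasing"):
            FilamentTable(df)

    def test_angle_range_enforced(self):
        df = pd.DataFrame(
            {
                "filament_id": [1],
                "segment_index": [0],
                "rot": [200.0],
                "tilt": [90.0],
                "psi": [0.0],
                "origin_x": [0.0],
                "origin_y": [0.0],
                "class_id": [1],
            }
        )
        with pytest.raises(ValueError, match="rot"):
            FilamentTable(df)
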
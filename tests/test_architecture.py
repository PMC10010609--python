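"""Root architectures: reading, reconstruction from cut segments,
discretization into REVs, virtual cutting, synthesis."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rootflow import (
    Axis,
    CutSegmentSet,
    RootSystem,
    cut_at_distance,
    discretize,
    generate_synthetic_rsa,
    read_architecture,
    reconstruct_from_cuts,
    write_architecture,
)
from rootflow.architecture import ArchitectureError


def _frame(rows):
    return pd.DataFrame(
        rows, columns=["axis_id", "parent_axis", "insertion_position_m", "length_m", "order", "diameter_m"]
    )


class TestReadArchitecture:
    def test_simple_tree(self):
        df = _frame([
            ("p", "", 0.0, 0.30, 0, 1.0e-3),
            ("l1", "p", 0.10, 0.05, 1, 0.4e-3),
            ("l2", "p", 0.20, 0.03, 1, 0.4e-3),
        ])
        rs = read_architecture(df)
        assert len(rs) == 3
        assert rs.primary.length == 0.30
        assert {a.axis_id for a in rs.laterals} == {"l1", "l2"}

    def test_diameter_defaults_by_condition(self):
        df = _frame([("p", "", 0.0, 0.30, 0, np.nan), ("l1", "p", 0.10, 0.05, 1, np.nan)])
        rs_ctr = read_architecture(df, condition="CTR")
        assert rs_ctr.primary.diameter == pytest.approx(1.05e-3)
        assert rs_ctr.laterals[0].diameter == pytest.approx(0.36e-3)
        rs_peg = read_architecture(df, condition="PEG")
        assert rs_peg.primary.diameter == pytest.approx(1.03e-3)
        assert rs_peg.laterals[0].diameter == pytest.approx(0.39e-3)

    def test_orphan_lateral(self):
        df = _frame([("p", "", 0.0, 0.30, 0, 1e-3), ("l1", "ghost", 0.10, 0.05, 1, 4e-4)])
        with pytest.raises(ArchitectureError):
            read_architecture(df)

    def test_insertion_beyond_parent(self):
        df = _frame([("p", "", 0.0, 0.30, 0, 1e-3), ("l1", "p", 0.35, 0.05, 1, 4e-4)])
        with pytest.raises(ArchitectureError):
            read_architecture(df)

    def test_csv_round_trip(self, tmp_path, small_rs):
        path = tmp_path / "arch.csv"
        write_architecture(small_rs, path)
        rs2 = read_architecture(path)
        for aid, ax in small_rs.axes.items():
            bx = rs2.axes[aid]
            assert bx.length == ax.length
            assert bx.insertion_position == ax.insertion_position
            assert bx.diameter == ax.diameter


class TestReconstructFromCuts:
    def test_primary_additivity(self):
        remainder = RootSystem([Axis("p", None, 0.0, 0.05, 1e-3, 0)])
        cuts = [CutSegmentSet(0.04), CutSegmentSet(0.08)]
        rs = reconstruct_from_cuts(cuts, remainder)
        assert rs.primary.length == pytest.approx(0.17, abs=1e-12)

    def test_lateral_offsets(self):
        remainder = RootSystem([
            Axis("p", None, 0.0, 0.05, 1e-3, 0),
            Axis("lb", "p", 0.02, 0.01, 4e-4, 1),
        ])
        cuts = [
            CutSegmentSet(0.04, laterals=[(0.01, 0.02)]),  # most distal piece
            CutSegmentSet(0.08, laterals=[(0.03, 0.02)]),
        ]
        rs = reconstruct_from_cuts(cuts, remainder)
        pos = sorted(a.insertion_position for a in rs.laterals)
        # distal-piece lateral keeps its distance to the true tip; the
        # others are offset by the primary length pasted distal to them
        assert pos == pytest.approx([0.01, 0.03 + 0.04, 0.02 + 0.12])

    def test_missing_primary_piece(self):
        with pytest.raises(ArchitectureError):
            CutSegmentSet(0.0)

    def test_round_trip_through_virtual_cutting(self, reference_rs):
        """Cutting a known root into pieces and pasting them back must
        recover every axis length and insertion position."""
        L = reference_rs.primary.length
        blades = [0.083, 0.126, 0.169, 0.212]  # distances from the tip
        edges = [0.0] + blades  # piece j spans [edges[j], edges[j+1])
        pieces = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            lats = [
                (a.insertion_position - lo, a.length)
                for a in reference_rs.laterals
                if lo < a.insertion_position <= hi
            ]
            pieces.append(CutSegmentSet(hi - lo, laterals=lats))
        rem_lats = [
            Axis(a.axis_id, "p", a.insertion_position - blades[-1], a.length, a.diameter, 1)
            for a in reference_rs.laterals
            if a.insertion_position > blades[-1]
        ]
        remainder = RootSystem([Axis("p", None, 0.0, L - blades[-1], 1.05e-3, 0)] + rem_lats)
        rs = reconstruct_from_cuts(pieces, remainder)
        assert rs.primary.length == pytest.approx(L, abs=1e-9)
        got = sorted((a.insertion_position, a.length) for a in rs.laterals)
        want = sorted((a.insertion_position, a.length) for a in reference_rs.laterals)
        assert np.allclose(got, want, atol=1e-9)


class TestDiscretize:
    def test_exact_division(self):
        rs = RootSystem([Axis("p", None, 0.0, 0.010, 1e-3, 0)])
        g = discretize(rs, 1e-3)
        assert g.n_revs == 10
        assert np.allclose(g.length, 1e-3)

    def test_ceil_rule(self):
        rs = RootSystem([Axis("p", None, 0.0, 0.0104, 1e-3, 0)])
        g = discretize(rs, 1e-3)
        assert g.n_revs == 11
        assert np.allclose(g.length, 0.0104 / 11)
        assert g.length[0] == pytest.approx(0.9455e-3, abs=1e-7)

    def test_conservation(self, small_rs):
        g = discretize(small_rs, 1e-3)
        assert g.total_length == pytest.approx(small_rs.total_length, rel=1e-12)
        want_surface = sum(np.pi * a.diameter * a.length for a in small_rs.axes.values())
        assert g.total_surface == pytest.approx(want_surface, rel=1e-10)

    def test_distance_to_tip_monotone_along_axes(self, small_graph):
        for ai in range(len(small_graph.axis_meta)):
            dtt = small_graph.dist_to_tip[small_graph.axis_index == ai]
            assert np.all(np.diff(dtt) < 0)  # base -> apex ordering

    def test_lateral_attachment_rev(self):
        rs = RootSystem([
            Axis("p", None, 0.0, 0.010, 1e-3, 0),
            Axis("l", "p", 0.0035, 0.002, 4e-4, 1),
        ])
        g = discretize(rs, 1e-3)
        lat_base = int(np.flatnonzero(g.order == 1)[0])
        j = g.parent[lat_base]
        # the parent REV's span must contain the insertion point
        lo = g.dist_to_tip[j] - g.length[j] / 2
        hi = g.dist_to_tip[j] + g.length[j] / 2
        assert lo <= 0.0035 <= hi

    def test_surface_is_pi_d_l(self, small_graph):
        assert np.allclose(small_graph.surface, np.pi * small_graph.diameter * small_graph.length, rtol=1e-14)


@pytest.fixture(scope="module")
def branched():
    rs = RootSystem([
        Axis("p", None, 0.0, 0.30, 1e-3, 0),
        Axis("near_tip", "p", 0.08, 0.02, 4e-4, 1),  # removed by blade at 0.10
        Axis("long", "p", 0.15, 0.12, 4e-4, 1),  # partially cut
        Axis("short", "p", 0.15, 0.03, 4e-4, 1),  # untouched
    ])
    return discretize(rs, 1e-3)


class TestCutAtDistance:

    def test_lateral_rules(self, branched):
        g = branched.cut_at_distance(0.10)
        meta = g.axis_meta
        for ai in range(len(meta)):
            kept = g.length[g.axis_index == ai].sum()
            name = meta.at[ai, "axis_id"]
            if name == "near_tip":
                assert kept == 0.0
            elif name == "long":
                # stretched tipward: keeps its basal p - x_blade = 5 cm
                assert kept == pytest.approx(0.05, abs=1e-3)
                on_axis = g.axis_index == ai
                assert g.is_cut_face[on_axis].sum() == 1
            elif name == "short":
                assert kept == pytest.approx(0.03, abs=1e-12)
            else:  # primary keeps its basal 20 cm and is flagged
                assert kept == pytest.approx(0.20, abs=1e-3)
        assert g.is_cut_face.sum() == 2  # primary face + long-lateral face

    def test_idempotent(self, branched):
        g1 = branched.cut_at_distance(0.10)
        g2 = g1.cut_at_distance(0.10)
        assert g2.n_revs == g1.n_revs
        assert np.array_equal(g2.is_cut_face, g1.is_cut_face)
        assert np.allclose(g2.dist_to_tip, g1.dist_to_tip)

    def test_deeper_cut_removes_more(self, branched):
        lengths = [branched.cut_at_distance(x).total_length for x in (0.05, 0.10, 0.20)]
        assert lengths[0] > lengths[1] > lengths[2]

    def test_blade_beyond_root(self, branched):
        with pytest.raises(ValueError):
            branched.cut_at_distance(0.30)
        with pytest.raises(ValueError):
            branched.cut_at_distance(0.0)

    @given(st.floats(0.02, 0.27))
    @settings(max_examples=20, deadline=None)
    def test_cut_keeps_anatomical_coordinates(self, x):
        rs = generate_synthetic_rsa(0.30, 50.0, seed=7)
        g = discretize(rs, 2e-3)
        gc = g.cut_at_distance(x)
        # surviving primary REV centres all lie basal of the blade and
        # keep the distances they had in the intact root
        prim = gc.order == 0
        assert np.all(gc.dist_to_tip[prim] >= x)
        assert gc.total_length < g.total_length


class TestGenerateSyntheticRsa:
    def test_density_zero(self):
        rs = generate_synthetic_rsa(0.3, 0.0, seed=0)
        assert len(rs) == 1

    def test_determinism(self):
        a = generate_synthetic_rsa(0.3, 70.0, seed=42)
        b = generate_synthetic_rsa(0.3, 70.0, seed=42)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_poisson_count(self):
        # density 100/m on a 0.28 m branchable zone: mean 28, sd ~5.3
        rs = generate_synthetic_rsa(0.30, 100.0, seed=3)
        n = len(rs.laterals)
        assert abs(n - 28) <= 3 * np.sqrt(28)

    def test_apical_zone_unbranched(self):
        rs = generate_synthetic_rsa(0.30, 100.0, seed=3)
        assert min(a.insertion_position for a in rs.laterals) >= 0.02


class TestAlternativeCutConvention:
    def test_own_distance_mode(self, branched):
        """Alternative geometry: lateral REVs are excised by their own
        distance to their own tip rather than by the stretched-tipward
        alignment."""
        g = branched.cut_at_distance(0.10, lateral_mode="own_distance")
        meta = g.axis_meta
        for ai in range(len(meta)):
            kept = g.length[g.axis_index == ai].sum()
            name = meta.at[ai, "axis_id"]
            if name == "near_tip":  # attachment at 0.08 < blade: gone
                assert kept == 0.0
            elif name == "long":  # keeps the part with own dtt >= 0.10
                assert kept == pytest.approx(0.02, abs=1e-3)
            elif name == "short":  # entirely within 0.03 m of its tip
                assert kept == 0.0
        with pytest.raises(ValueError):
            branched.cut_at_distance(0.10, lateral_mode="sideways")
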
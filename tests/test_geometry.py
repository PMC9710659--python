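"""Distance-only dihedral cosines against the coordinate oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geosec.errors import (
    DegenerateGeometryError,
    GeometryInconsistencyError,
    InsufficientStructureError,
    ValidationError,
)
from geosec.geometry import (
    QuadDistances,
    ca_pseudo_dihedral,
    cos_dihedral_from_coords,
    cos_dihedral_from_distances,
    generalized_phi_psi,
    planar_cos,
    trihedron_angles,
)
from geosec.structure_io import Atom, ProteinStructure, Residue


def random_quad(rng, scale=3.0):
    """A random non-degenerate 4-point configuration."""
    while True:
        pts = rng.normal(size=(4, 3)) * scale
        try:
            cos_dihedral_from_coords(*pts)
        except DegenerateGeometryError:
            continue
        return pts


class TestPlanarCos:
    @settings(max_examples=200, derandomize=True)
    @given(
        x=st.floats(0.1, 10.0),
        y=st.floats(0.1, 10.0),
        frac=st.floats(1e-6, 1.0 - 1e-6),
    )
    def test_triangle_sides_give_valid_cosine(self, x, y, frac):
        # any z strictly inside the triangle-inequality band [|x-y|, x+y]
        # yields a cosine in [-1, 1]
        z = abs(x - y) + frac * ((x + y) - abs(x - y))
        assert -1.0 - 1e-9 <= planar_cos(x, y, z) <= 1.0 + 1e-9

    @pytest.mark.parametrize(
        "xyz,expected",
        [((1, 1, 1), 0.5), ((3, 4, 5), 0.0), ((1, 1, 2), -1.0)],
    )
    def test_known_triangles(self, xyz, expected):
        assert planar_cos(*xyz) == pytest.approx(expected, abs=1e-12)

    def test_zero_side_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            planar_cos(0.0, 1.0, 1.0)


class TestDistanceDihedral:
    def test_planar_square_is_cis(self):
        q = QuadDistances(1, 1, 1, np.sqrt(2), np.sqrt(2), 1)
        assert cos_dihedral_from_distances(q) == pytest.approx(1.0, abs=1e-9)

    def test_planar_zigzag_is_trans(self):
        q = QuadDistances(1, 1, 1, np.sqrt(2), np.sqrt(2), np.sqrt(5))
        assert cos_dihedral_from_distances(q) == pytest.approx(-1.0, abs=1e-9)

    def test_matches_coordinate_oracle(self, rng):
        for _ in range(200):
            pts = random_quad(rng)
            expected = cos_dihedral_from_coords(*pts)
            got = cos_dihedral_from_distances(QuadDistances.from_points(*pts))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_trihedron_identity(self, rng):
        # cos gamma = cos alpha cos beta + sin alpha sin beta cos omega
        for _ in range(200):
            pts = random_quad(rng)
            q = QuadDistances.from_points(*pts)
            ang = trihedron_angles(q)
            cw = cos_dihedral_from_distances(q)
            sa = np.sqrt(1 - ang.cos_alpha ** 2)
            sb = np.sqrt(1 - ang.cos_beta ** 2)
            lhs = ang.cos_gamma
            rhs = ang.cos_alpha * ang.cos_beta + sa * sb * cw
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_invariant_under_quadruple_reversal(self, rng):
        for _ in range(100):
            pts = random_quad(rng)
            q = QuadDistances.from_points(*pts)
            assert cos_dihedral_from_distances(q) == pytest.approx(
                cos_dihedral_from_distances(q.reversed()), abs=1e-9
            )

    def test_collinear_middle_triple_degenerate(self):
        pts = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)]
        with pytest.raises(DegenerateGeometryError):
            cos_dihedral_from_distances(QuadDistances.from_points(*pts))

    def test_non_euclidean_distances_rejected(self):
        # unit square distances with an impossible d03
        q = QuadDistances(1, 1, 1, np.sqrt(2), np.sqrt(2), 3.5)
        with pytest.raises(GeometryInconsistencyError):
            cos_dihedral_from_distances(q)

    def test_nonpositive_distances_rejected(self):
        with pytest.raises(ValidationError):
            QuadDistances(0.0, 1, 1, 1, 1, 1)


class TestCoordinateDihedral:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], 1.0),
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)], -1.0),
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)], 0.0),
        ],
    )
    def test_known_configurations(self, pts, expected):
        assert cos_dihedral_from_coords(*pts) == pytest.approx(expected, abs=1e-9)

    def test_collinear_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            cos_dihedral_from_coords((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 1))


class TestGeneralizedPhiPsi:
    def test_adjacent_pair_reduces_to_classical_angles(self, helix):
        s, _ = helix
        cos_phi, cos_psi = generalized_phi_psi(s.residues[4], s.residues[5])
        assert cos_phi == pytest.approx(np.cos(np.radians(57.0)), abs=1e-6)
        assert cos_psi == pytest.approx(np.cos(np.radians(47.0)), abs=1e-6)

    def test_self_pair_degenerate(self, helix):
        s, _ = helix
        with pytest.raises(DegenerateGeometryError):
            generalized_phi_psi(s.residues[0], s.residues[0])

    def test_missing_nitrogen_masks_both_angles(self, helix):
        s, _ = helix
        rk = s.residues[2]
        rl_full = s.residues[3]
        rl = Residue(
            chain_id="A",
            seq_index=99,
            res_type="ALA",
            atoms=[a for a in rl_full.atoms if a.name != "N"],
        )
        cos_phi, cos_psi = generalized_phi_psi(rk, rl)
        assert cos_phi is None  # needs N of l
        assert cos_psi is None  # needs N of l


def _ca_structure(coords):
    residues = [
        Residue("A", i + 1, "ALA", [Atom("CA", "C", c)])
        for i, c in enumerate(coords)
    ]
    return ProteinStructure(residues=residues, mode="ca-only")


class TestCaPseudoDihedral:
    def test_square_trace_resolves_anchors(self):
        s = _ca_structure(
            [(0, 0, 0), (3.8, 0, 0), (3.8, 3.8, 0), (0, 3.8, 0)]
        )
        # a = third residue, b = second: i -> residue 4, i-3 -> residue 1,
        # giving the planar square quadruple (cis, cos = 1)
        c = ca_pseudo_dihedral(s.residues[2], s.residues[1], s)
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_too_few_residues(self):
        s = _ca_structure([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
        with pytest.raises(InsufficientStructureError):
            ca_pseudo_dihedral(s.residues[0], s.residues[1], s)

    def test_nearest_tie_broken_by_lower_index(self):
        # residues 3 and 4 are equidistant from a; lower index (3) must win
        coords = [
            (0.0, 0.0, 0.0),      # a
            (10.0, 0.0, 0.0),     # b
            (3.8, 0.0, 1.0),      # candidate i, index 2
            (-3.8, 0.0, 1.0),     # same distance to a, index 3
            (10.0, 3.8, 0.0),     # nearest to b
        ]
        s = _ca_structure(coords)
        got = ca_pseudo_dihedral(s.residues[0], s.residues[1], s)
        # oracle: quadruple (i-3, b, a, i) with i = index 2 by the tie rule
        expected = cos_dihedral_from_coords(
            coords[4], coords[1], coords[0], coords[2]
        )
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(
            ca_pseudo_dihedral(s.residues[0], s.residues[1], s), abs=0
        )
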
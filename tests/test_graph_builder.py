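"""Residue graph construction, edge features, ablation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from geosec.errors import InsufficientStructureError, ValidationError
from geosec.graph_builder import (
    ablate_residues,
    aggregate_node_features,
    attach_edge_features,
    build_knn_graph,
    build_threshold_graph,
    featurize,
    residue_distance,
    write_graph_tsv,
)
from geosec.structure_io import Atom, ProteinStructure, Residue
from geosec.synthetic_data import to_ca_only


def _res(atom_coords, chain="A", idx=1):
    atoms = [Atom("CA", "C", c) for i, c in enumerate(atom_coords[:1])]
    atoms += [Atom(f"C", "C", c) for c in atom_coords[1:2]]
    atoms += [Atom(f"N", "N", c) for c in atom_coords[2:3]]
    return Residue(chain, idx, "ALA", atoms)


def _ca_chain(coords):
    residues = [
        Residue("A", i + 1, "GLY", [Atom("CA", "C", c)])
        for i, c in enumerate(coords)
    ]
    return ProteinStructure(residues=residues, mode="ca-only")


class TestResidueDistance:
    def test_single_atoms(self):
        r1, r2 = _res([(0, 0, 0)]), _res([(3, 0, 0)], idx=2)
        assert residue_distance(r1, r2, "all-atom") == pytest.approx(3.0)

    def test_minimum_rule_over_atom_pairs(self):
        r1 = _res([(0, 0, 0), (1, 0, 0)])
        r2 = _res([(4, 0, 0)], idx=2)
        assert residue_distance(r1, r2, "all-atom") == pytest.approx(3.0)

    def test_identical_residue_zero(self):
        r = _res([(1, 2, 3)])
        assert residue_distance(r, r, "all-atom") == 0.0


class TestKnnGraph:
    def test_k_equals_n_minus_one_gives_complete_graph(self):
        s = _ca_chain([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
        g = build_knn_graph(s, k=2)
        assert g.undirected_edges() == {(0, 1), (0, 2), (1, 2)}

    def test_collinear_chain_k1_matches_brute_force(self):
        coords = [(i * 3.8, 0.0, 0.0) for i in range(4)]
        s = _ca_chain(coords)
        g = build_knn_graph(s, k=1)
        # brute-force directed nearest neighbor, union-symmetrized
        pts = np.array(coords)
        expected = set()
        for i in range(4):
            d = np.linalg.norm(pts - pts[i], axis=1)
            d[i] = np.inf
            j = int(np.argmin(d))  # argmin takes the lowest index on ties
            expected.add((min(i, j), max(i, j)))
        assert g.undirected_edges() == expected

    def test_k_zero_rejected(self):
        s = _ca_chain([(0, 0, 0), (3.8, 0, 0)])
        with pytest.raises(ValidationError):
            build_knn_graph(s, k=0)

    def test_single_residue_rejected(self):
        s = _ca_chain([(0, 0, 0)])
        with pytest.raises(InsufficientStructureError):
            build_knn_graph(s, k=1)

    def test_oversized_k_clamped(self):
        s = _ca_chain([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
        g = build_knn_graph(s, k=50)
        assert g.meta["k"] == 2

    def test_min_degree_after_symmetrization(self, mixed):
        s, _ = mixed
        for k in (1, 2, 3):
            g = build_knn_graph(s, k=k)
            degree = np.zeros(g.n_nodes, dtype=int)
            for u, v in g.undirected_edges():
                degree[u] += 1
                degree[v] += 1
            assert degree.min() >= min(k, g.n_nodes - 1)


class TestThresholdGraph:
    def test_edge_below_threshold(self):
        s = _ca_chain([(0, 0, 0), (2.9, 0, 0)])
        assert build_threshold_graph(s, tau=3.0).undirected_edges() == {(0, 1)}

    def test_strict_inequality_at_threshold(self):
        s = _ca_chain([(0, 0, 0), (3.0, 0, 0)])
        assert build_threshold_graph(s, tau=3.0).undirected_edges() == set()

    def test_all_isolated_nodes(self):
        s = _ca_chain([(0, 0, 0), (10, 0, 0), (20, 0, 0)])
        g = build_threshold_graph(s, tau=3.0)
        assert g.n_edges == 0 and g.n_nodes == 3

    def test_nonpositive_tau_rejected(self):
        s = _ca_chain([(0, 0, 0), (2, 0, 0)])
        with pytest.raises(ValidationError):
            build_threshold_graph(s, tau=0.0)


class TestEdgeFeatures:
    def test_helix_adjacent_edge_carries_classical_angles(self, helix):
        s, _ = helix
        g = attach_edge_features(build_knn_graph(s, k=2))
        # find the directed edge 4 -> 5 (sender k=4, receiver l=5)
        e = next(
            i
            for i in range(g.edge_index.shape[1])
            if g.edge_index[0, i] == 4 and g.edge_index[1, i] == 5
        )
        assert g.edge_mask[e].all()
        assert g.edge_attr[e, 1] == pytest.approx(np.cos(np.radians(57)), abs=1e-6)
        assert g.edge_attr[e, 2] == pytest.approx(np.cos(np.radians(47)), abs=1e-6)

    def test_missing_backbone_masks_angles_not_distance(self, helix):
        s, _ = helix
        stripped = [
            Residue(
                r.chain_id, r.seq_index, r.res_type,
                [a for a in r.atoms if a.name in ("CA",) or r.seq_index != 3],
            )
            for r in s.residues
        ]
        s2 = ProteinStructure(residues=stripped, mode=s.mode)
        g = attach_edge_features(build_knn_graph(s2, k=2))
        touched = [
            e
            for e in range(g.edge_index.shape[1])
            if 2 in (g.edge_index[0, e], g.edge_index[1, e])
        ]
        assert touched
        for e in touched:
            assert g.edge_mask[e, 0]  # distance always available
            assert not g.edge_mask[e, 1:].all()

    def test_ca_mode_features_have_length_two(self, helix):
        s, _ = helix
        g = attach_edge_features(build_knn_graph(to_ca_only(s), k=2))
        assert g.edge_attr.shape[1] == 2
        assert g.edge_mask[:, 0].all()

    def test_rigid_motion_invariance(self, mixed, rng):
        s, _ = mixed
        g1 = attach_edge_features(build_knn_graph(s, k=2))
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.normal(size=3) * 10
        moved = [
            Residue(
                r.chain_id, r.seq_index, r.res_type,
                [Atom(a.name, a.element, R @ a.coords + t) for a in r.atoms],
            )
            for r in s.residues
        ]
        s2 = ProteinStructure(residues=moved, mode=s.mode)
        g2 = attach_edge_features(build_knn_graph(s2, k=2))
        assert g1.undirected_edges() == g2.undirected_edges()
        np.testing.assert_allclose(g1.edge_attr, g2.edge_attr, atol=1e-8)

    def test_sequence_agnosticism_under_residue_permutation(self, mixed):
        s, _ = mixed
        g1 = attach_edge_features(build_knn_graph(s, k=2))
        perm = np.random.default_rng(3).permutation(len(s))
        s2 = ProteinStructure(
            residues=[s.residues[i] for i in perm], mode=s.mode
        )
        g2 = attach_edge_features(build_knn_graph(s2, k=2))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))

        def edge_multiset(g, relabel=None):
            out = []
            for e in range(g.edge_index.shape[1]):
                u, v = int(g.edge_index[0, e]), int(g.edge_index[1, e])
                if relabel is not None:
                    u, v = int(relabel[u]), int(relabel[v])
                out.append((u, v) + tuple(np.round(g.edge_attr[e], 9)))
            return sorted(out)

        assert edge_multiset(g1) == edge_multiset(g2, relabel=perm)


class TestNodeAggregation:
    def test_mean_of_incident_features(self):
        s = _ca_chain([(0, 0, 0), (3, 0, 0), (8, 0, 0), (16, 0, 0)])
        g = build_knn_graph(s, k=1)
        attach_edge_features(g)
        aggregate_node_features(g, include_res_type=False)
        incoming = g.edge_index[1] == 0
        expected = g.edge_attr[incoming].mean(axis=0)
        np.testing.assert_allclose(g.node_attr[0], expected)

    def test_distance_channel_mean(self):
        # node 0 has incident edges with distances 3 and 5
        s = _ca_chain([(0, 0, 0), (3, 0, 0), (0, 5, 0), (50, 0, 0), (53, 0, 0)])
        g = build_threshold_graph(s, tau=6.0)
        attach_edge_features(g)
        aggregate_node_features(g, include_res_type=False)
        assert g.node_attr[0, 0] == pytest.approx(4.0)

    def test_isolated_node_zero_with_mask(self):
        s = _ca_chain([(0, 0, 0), (2, 0, 0), (30, 0, 0), (60, 0, 0)])
        g = build_threshold_graph(s, tau=3.0)
        attach_edge_features(g)
        aggregate_node_features(g, include_res_type=False)
        assert not g.node_mask[2].any()
        np.testing.assert_allclose(g.node_attr[2], 0.0)

    def test_one_hot_appended(self, mixed_graph):
        assert mixed_graph.node_attr.shape[1] == 3 + 21
        assert mixed_graph.node_attr[:, 3:].sum(axis=1).tolist() == [1.0] * (
            mixed_graph.n_nodes
        )


class TestAblation:
    def test_zero_fraction_is_identity(self, mixed):
        s, _ = mixed
        assert ablate_residues(s, 0.0) is s

    def test_seeded_reproducibility(self, mixed):
        s, _ = mixed
        _, kept1 = ablate_residues(s, 0.5, seed=42, return_indices=True)
        _, kept2 = ablate_residues(s, 0.5, seed=42, return_indices=True)
        assert kept1.tolist() == kept2.tolist()
        assert len(kept1) == len(s) - int(np.ceil(0.5 * len(s)))

    def test_full_ablation_rejected(self, mixed):
        s, _ = mixed
        with pytest.raises(ValidationError):
            ablate_residues(s, 1.0)


class TestSerialization:
    def test_graph_tsv_row_count(self, tmp_path, mixed_graph):
        path = tmp_path / "graph.tsv"
        write_graph_tsv(mixed_graph, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# feature_mode=all-atom")
        assert len(lines) == 2 + mixed_graph.edge_index.shape[1]


def test_methods_a_and_b_overlap_reported(mixed, capsys):
    """Methods A (k=2) and B (tau=3) give similar edge sets; the Jaccard
    index is reported, not asserted."""
    s, _ = mixed
    a = build_knn_graph(s, k=2).undirected_edges()
    b = build_threshold_graph(s, tau=3.0).undirected_edges()
    jaccard = len(a & b) / max(1, len(a | b))
    print(f"method A/B edge Jaccard: {jaccard:.3f}")
    assert 0.0 <= jaccard <= 1.0
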
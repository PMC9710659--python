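"""Sequence-agnostic residue graphs and their geometric features.

Residues become nodes; edges connect spatially close residues under one of
two constructions:

* method A — a k-nearest-neighbors relation (default k=2), symmetrized by
  union so the modeled graph is undirected;
* method B — a distance threshold (edge iff residue distance < tau,
  default tau = 3 Angstrom).

Residue distance is the minimum distance over the retained atoms of the
two residues (CA-CA in ca mode).  Each undirected edge carries one
feature vector per direction, because the generalized phi/psi angles are
direction-dependent: the directed edge (w -> v) holds
(d_wv, cos phi_wv, cos psi_wv) in all-atom mode, or (d_ab, cos Phi_ab) in
ca mode.  Unavailable angles are masked (sentinel 0 plus a mask bit), not
errors, so partial structures featurize cleanly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateGeometryError,
    InsufficientStructureError,
    ValidationError,
)
from .geometry import ca_pseudo_dihedral, generalized_phi_psi
from .structure_io import (
    MODE_CA,
    ProteinStructure,
    Residue,
    UNK_INDEX,
)

logger = logging.getLogger(__name__)

FEATURE_MODE_ALL_ATOM = "all-atom"
FEATURE_MODE_CA = "ca"

#: edge feature dimensionality per feature mode
EDGE_DIMS = {FEATURE_MODE_ALL_ATOM: 3, FEATURE_MODE_CA: 2}


@dataclass
class ResidueGraph:
    """A residue graph with directed feature storage on undirected edges.

    ``edge_index`` is (2, m) with both directions of every undirected edge
    present; row 0 is the source (sender) node, row 1 the destination
    (receiver).  ``edge_attr``/``edge_mask`` are (m, F): masked entries are
    0 with mask bit False.  ``node_attr``/``node_mask`` are filled by
    :func:`aggregate_node_features`.
    """

    structure: ProteinStructure
    edge_index: np.ndarray  # (2, m) int, directed
    meta: dict = field(default_factory=dict)
    edge_attr: np.ndarray | None = None
    edge_mask: np.ndarray | None = None
    node_attr: np.ndarray | None = None
    node_mask: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.structure)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return self.edge_index.shape[1] // 2

    def undirected_edges(self) -> set[tuple[int, int]]:
        return {
            (min(u, v), max(u, v))
            for u, v in zip(self.edge_index[0], self.edge_index[1])
        }

    @property
    def feature_mode(self) -> str:
        return self.meta["feature_mode"]


def _feature_mode_for(s: ProteinStructure) -> str:
    return FEATURE_MODE_CA if s.mode == MODE_CA else FEATURE_MODE_ALL_ATOM


def residue_distance(r1: Residue, r2: Residue, mode: str) -> float:
    """Distance between residues: min over atom pairs, or CA-CA in ca mode."""
    if mode == FEATURE_MODE_CA:
        a1, a2 = r1.get_atom("CA"), r2.get_atom("CA")
        if a1 is None or a2 is None:
            raise ValidationError("residue lacks a CA atom")
        return float(np.linalg.norm(a1.coords - a2.coords))
    if not r1.atoms or not r2.atoms:
        raise ValidationError("residue has no atoms")
    c1 = np.array([a.coords for a in r1.atoms])
    c2 = np.array([a.coords for a in r2.atoms])
    return float(cdist(c1, c2).min())


def _distance_matrix(s: ProteinStructure, mode: str) -> np.ndarray:
    """Full residue-residue distance matrix (min-atom-pair or CA-CA)."""
    n = len(s)
    if mode == FEATURE_MODE_CA:
        ca = s.ca_coords()
        return cdist(ca, ca)
    coords = np.concatenate([[a.coords for a in r.atoms] for r in s.residues])
    owner = np.concatenate(
        [[i] * len(r.atoms) for i, r in enumerate(s.residues)]
    ).astype(int)
    full = cdist(coords, coords)
    out = np.full((n, n), np.inf)
    # reduce the atom-level matrix to per-residue minima
    np.minimum.at(out, (owner[:, None], owner[None, :]), full)
    np.fill_diagonal(out, 0.0)
    return out


def _directed_to_symmetric(pairs: set[tuple[int, int]]) -> np.ndarray:
    und = {(min(u, v), max(u, v)) for u, v in pairs}
    src, dst = [], []
    for u, v in sorted(und):
        src += [u, v]
        dst += [v, u]
    return np.array([src, dst], dtype=int).reshape(2, -1)


def build_knn_graph(s: ProteinStructure, k: int = 2) -> ResidueGraph:
    """Method A: k-nearest-neighbor graph, symmetrized by union.

    Each residue selects its k nearest residues (ties broken by residue
    list index, lower first); an undirected edge exists if either endpoint
    selected the other.  k is clamped to n-1 with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = len(s)
    if n < 2:
        raise InsufficientStructureError("k-NN graph needs at least 2 residues")
    if k > n - 1:
        logger.warning("k=%d clamped to n-1=%d", k, n - 1)
        k = n - 1
    mode = _feature_mode_for(s)
    D = _distance_matrix(s, mode)
    pairs: set[tuple[int, int]] = set()
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        order = np.lexsort((others, D[i, others]))  # distance, then index
        for j in others[order[:k]]:
            pairs.add((i, int(j)))
    return ResidueGraph(
        structure=s,
        edge_index=_directed_to_symmetric(pairs),
        meta={"method": "A", "k": k, "feature_mode": mode},
    )


def build_threshold_graph(s: ProteinStructure, tau: float = 3.0) -> ResidueGraph:
    """Method B: undirected edge iff residue distance is strictly below tau."""
    if tau <= 0:
        raise ValidationError("tau must be positive")
    n = len(s)
    mode = _feature_mode_for(s)
    D = _distance_matrix(s, mode)
    pairs = {
        (i, j) for i in range(n) for j in range(i + 1, n) if D[i, j] < tau
    }
    return ResidueGraph(
        structure=s,
        edge_index=_directed_to_symmetric(pairs),
        meta={"method": "B", "tau": tau, "feature_mode": mode},
    )


def attach_edge_features(g: ResidueGraph, s: ProteinStructure | None = None) -> ResidueGraph:
    """Attach per-direction geometric features to every edge of ``g``.

    All-atom mode: the directed edge (w -> v) carries
    (d_wv, cos phi_wv, cos psi_wv) with w in the sender role, so the
    message arriving at v describes v's generalized phi seen from w.
    Ca mode: (d_ab, cos Phi_ab) with a = receiver, b = sender.
    """
    s = s if s is not None else g.structure
    if s is not g.structure:
        raise ValidationError("graph was not built from this structure")
    mode = g.feature_mode
    dim = EDGE_DIMS[mode]
    m = g.edge_index.shape[1]
    attr = np.zeros((m, dim))
    mask = np.zeros((m, dim), dtype=bool)
    for e in range(m):
        w, v = int(g.edge_index[0, e]), int(g.edge_index[1, e])
        rw, rv = s.residues[w], s.residues[v]
        attr[e, 0] = residue_distance(rw, rv, mode)
        mask[e, 0] = True
        if mode == FEATURE_MODE_ALL_ATOM:
            try:
                cos_phi, cos_psi = generalized_phi_psi(rw, rv)
            except DegenerateGeometryError:
                cos_phi = cos_psi = None
            if cos_phi is not None:
                attr[e, 1], mask[e, 1] = cos_phi, True
            if cos_psi is not None:
                attr[e, 2], mask[e, 2] = cos_psi, True
        else:
            try:
                cos_big_phi = ca_pseudo_dihedral(rv, rw, s)
            except (DegenerateGeometryError, InsufficientStructureError):
                cos_big_phi = None
            if cos_big_phi is not None:
                attr[e, 1], mask[e, 1] = cos_big_phi, True
    g.edge_attr = attr
    g.edge_mask = mask
    return g


def aggregate_node_features(
    g: ResidueGraph, include_res_type: bool = True
) -> ResidueGraph:
    """Node features: mean of unmasked incoming edge features per channel.

    Optionally concatenates a 21-way one-hot of the residue type (20 amino
    acids + UNK).  Isolated nodes (or channels with no unmasked incident
    edge) get 0 with mask bit False.
    """
    if g.edge_attr is None:
        raise ValidationError("attach_edge_features must run first")
    n, dim = g.n_nodes, g.edge_attr.shape[1]
    sums = np.zeros((n, dim))
    counts = np.zeros((n, dim))
    dst = g.edge_index[1]
    np.add.at(sums, dst, np.where(g.edge_mask, g.edge_attr, 0.0))
    np.add.at(counts, dst, g.edge_mask.astype(float))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    mask = counts > 0
    if include_res_type:
        onehot = np.zeros((n, UNK_INDEX + 1))
        for i, r in enumerate(g.structure.residues):
            onehot[i, r.type_index()] = 1.0
        g.node_attr = np.concatenate([means, onehot], axis=1)
        g.node_mask = np.concatenate([mask, np.ones_like(onehot, dtype=bool)], axis=1)
    else:
        g.node_attr = means
        g.node_mask = mask
    g.meta["include_res_type"] = include_res_type
    return g


def ablate_residues(
    s: ProteinStructure,
    fraction: float,
    seed: int | np.random.Generator = 0,
    return_indices: bool = False,
):
    """Remove a uniform random subset of ceil(fraction * n) residues.

    Models partially observed structures (unmodelled loops, incomplete
    traces).  Reproducible for a fixed seed; the graph must be rebuilt
    from the reduced structure downstream.  With ``return_indices`` the
    kept residue list indices are returned too (e.g. to subset reference
    labels for scoring).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValidationError("ablation fraction must lie in [0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(s)
    if fraction == 0.0:
        return (s, np.arange(n)) if return_indices else s
    n_remove = int(np.ceil(fraction * n))
    removed = set(rng.choice(n, size=n_remove, replace=False).tolist())
    kept_idx = np.array([i for i in range(n) if i not in removed], dtype=int)
    kept = [s.residues[i] for i in kept_idx]
    out = ProteinStructure(residues=kept, source=s.source, mode=s.mode)
    return (out, kept_idx) if return_indices else out


def featurize(
    s: ProteinStructure,
    method: str = "A",
    k: int = 2,
    tau: float = 3.0,
    include_res_type: bool = True,
) -> ResidueGraph:
    """Build the graph, attach edge features, and aggregate node features."""
    if method == "A":
        g = build_knn_graph(s, k=k)
    elif method == "B":
        g = build_threshold_graph(s, tau=tau)
    else:
        raise ValidationError(f"unknown graph method {method!r}")
    attach_edge_features(g)
    aggregate_node_features(g, include_res_type=include_res_type)
    return g


def write_graph_tsv(g: ResidueGraph, path) -> None:
    """Serialize directed edges as TSV (src, dst, mask bits, features)."""
    if g.edge_attr is None:
        raise ValidationError("graph has no edge features to serialize")
    dim = g.edge_attr.shape[1]
    with open(path, "w") as fh:
        fh.write(f"# feature_mode={g.feature_mode}\tn_nodes={g.n_nodes}\n")
        cols = ["src", "dst"] + [f"mask{i}" for i in range(dim)] + [
            f"feat{i}" for i in range(dim)
        ]
        fh.write("\t".join(cols) + "\n")
        for e in range(g.edge_index.shape[1]):
            row = [str(int(g.edge_index[0, e])), str(int(g.edge_index[1, e]))]
            row += [str(int(b)) for b in g.edge_mask[e]]
            row += [f"{v:.6f}" for v in g.edge_attr[e]]
            fh.write("\t".join(row) + "\n")
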
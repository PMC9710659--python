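"""Dihedral-angle cosines from distances alone.

The central primitive: for four points {i-3, i-2, i-1, i} the cosine of
the dihedral angle omega between the planes (i-3, i-2, i-1) and
(i-2, i-1, i) is a closed-form function of the six pairwise distances.
Writing alpha, beta, gamma for the face angles at vertex i-2 (between the
vectors toward i-3/i-1, i-1/i and i-3/i respectively), the trihedron
cosine law

    cos gamma = cos alpha cos beta + sin alpha sin beta cos omega

inverts to

    cos omega = (cos gamma - cos alpha cos beta) / (sin alpha sin beta),

and each face cosine follows from the planar law of cosines
f(x, y, z) = (x^2 + y^2 - z^2) / (2xy).  Because only cosines survive,
the *sign* of omega is unrecoverable — all downstream features are
cosines by construction.

On top of this the module defines the two residue-pair angle features:

* generalized phi/psi for an ordered residue pair (k, l), which for
  sequence-adjacent residues reduce to the classical backbone phi of l and
  psi of k, but are defined for *any* spatially close pair;
* the C-alpha pseudo-dihedral for a residue pair (a, b) on CA-only
  traces, whose outer two atoms are chosen by spatial proximity.

Degenerate geometry (collinear triples, missing atoms) yields ``None`` —
a masked feature — rather than an exception, so partial structures
survive featurization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateGeometryError,
    GeometryInconsistencyError,
    InsufficientStructureError,
    ValidationError,
)
from .structure_io import ProteinStructure, Residue

#: |cos| closer than this to 1 marks a collinear (degenerate) triple.
_COLLINEAR_TOL = 1e-12
#: |cos omega| may exceed 1 by at most this before the distances are
#: declared non-Euclidean; values inside the band are clamped.
_CLAMP_TOL = 1e-9


@dataclass
class QuadDistances:
    """The six pairwise distances among an ordered atom quadruple.

    Index 0 is atom i-3 and index 3 is atom i, so ``d01`` is the distance
    between atoms i-3 and i-2, and so on.
    """

    d01: float
    d12: float
    d23: float
    d02: float
    d13: float
    d03: float

    def __post_init__(self) -> None:
        for name in ("d01", "d12", "d23", "d02", "d13", "d03"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be strictly positive and finite")
            setattr(self, name, v)

    @classmethod
    def from_points(cls, p0, p1, p2, p3) -> "QuadDistances":
        pts = [np.asarray(p, dtype=float) for p in (p0, p1, p2, p3)]
        d = lambda a, b: float(np.linalg.norm(pts[a] - pts[b]))
        return cls(d(0, 1), d(1, 2), d(2, 3), d(0, 2), d(1, 3), d(0, 3))

    @classmethod
    def from_matrix(cls, D: np.ndarray) -> "QuadDistances":
        D = np.asarray(D, dtype=float)
        if D.shape != (4, 4):
            raise ValidationError("expected a 4x4 distance matrix")
        return cls(D[0, 1], D[1, 2], D[2, 3], D[0, 2], D[1, 3], D[0, 3])

    def to_matrix(self) -> np.ndarray:
        D = np.zeros((4, 4))
        D[0, 1] = D[1, 0] = self.d01
        D[1, 2] = D[2, 1] = self.d12
        D[2, 3] = D[3, 2] = self.d23
        D[0, 2] = D[2, 0] = self.d02
        D[1, 3] = D[3, 1] = self.d13
        D[0, 3] = D[3, 0] = self.d03
        return D

    def reversed(self) -> "QuadDistances":
        """Distances of the quadruple traversed in the opposite order."""
        return QuadDistances(
            d01=self.d23, d12=self.d12, d23=self.d01,
            d02=self.d13, d13=self.d02, d03=self.d03,
        )


@dataclass
class TrihedronAngles:
    """Cosines of the three face angles at the central vertex i-2."""

    cos_alpha: float
    cos_beta: float
    cos_gamma: float

    def __post_init__(self) -> None:
        for name in ("cos_alpha", "cos_beta", "cos_gamma"):
            v = float(getattr(self, name))
            if not (-1.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [-1, 1]")


def planar_cos(x: float, y: float, z: float) -> float:
    """Law-of-cosines cosine of the angle opposite side ``z``.

    Returns (x^2 + y^2 - z^2) / (2xy), unclamped — the caller decides
    whether a value outside [-1, 1] is a geometry inconsistency.
    """
    if x <= 0 or y <= 0:
        raise DegenerateGeometryError("planar_cos requires strictly positive x, y")
    return (x * x + y * y - z * z) / (2.0 * x * y)


def trihedron_angles(q: QuadDistances) -> TrihedronAngles:
    """Face-angle cosines alpha, beta, gamma of the quadruple's trihedron."""
    ca = planar_cos(q.d12, q.d01, q.d02)
    cb = planar_cos(q.d12, q.d13, q.d23)
    cg = planar_cos(q.d01, q.d13, q.d03)
    for name, v in (("alpha", ca), ("beta", cb), ("gamma", cg)):
        if abs(v) > 1.0 + _CLAMP_TOL:
            raise GeometryInconsistencyError(
                f"cos {name} = {v}: distances are not Euclidean"
            )
    clamp = lambda v: float(np.clip(v, -1.0, 1.0))
    return TrihedronAngles(clamp(ca), clamp(cb), clamp(cg))


def cos_dihedral_from_distances(q: QuadDistances) -> float:
    """cos omega of the ordered quadruple, from its six distances only."""
    ang = trihedron_angles(q)
    ca, cb, cg = ang.cos_alpha, ang.cos_beta, ang.cos_gamma
    sa2 = 1.0 - ca * ca
    sb2 = 1.0 - cb * cb
    if sa2 <= _COLLINEAR_TOL or sb2 <= _COLLINEAR_TOL:
        raise DegenerateGeometryError(
            "collinear atom triple: dihedral undefined (sin alpha/beta = 0)"
        )
    c = (cg - ca * cb) / np.sqrt(sa2 * sb2)
    if abs(c) > 1.0 + _CLAMP_TOL:
        raise GeometryInconsistencyError(
            f"cos omega = {c}: distances are not Euclidean"
        )
    return float(np.clip(c, -1.0, 1.0))


def cos_dihedral_from_coords(p0, p1, p2, p3) -> float:
    """Coordinate-based dihedral cosine (the oracle for the distance route).

    Cosine of the angle between the plane normals b1 x b2 and b2 x b3,
    where b1 = p1 - p0, b2 = p2 - p1, b3 = p3 - p2.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    if n1n < 1e-10 or n2n < 1e-10:
        raise DegenerateGeometryError("collinear triple: plane normal vanishes")
    return float(np.clip(np.dot(n1, n2) / (n1n * n2n), -1.0, 1.0))


def _quad_cos(atoms) -> float | None:
    """Masked distance-only dihedral cosine over four Atom objects."""
    if any(a is None for a in atoms):
        return None
    try:
        q = QuadDistances.from_points(*(a.coords for a in atoms))
        return cos_dihedral_from_distances(q)
    except (DegenerateGeometryError, GeometryInconsistencyError, ValidationError):
        return None


def generalized_phi_psi(
    rk: Residue, rl: Residue
) -> tuple[float | None, float | None]:
    """Generalized (cos phi_kl, cos psi_kl) for the ordered pair (k, l).

    phi_kl is the dihedral cosine over (C of k, N of l, CA of l, C of l);
    psi_kl over (N of k, CA of k, C of k, N of l).  With k = l-1 in
    sequence these are exactly the classical backbone phi of l and psi of
    k; for arbitrary spatially close pairs they extend that definition
    without using sequence connectivity.  Missing atoms or degenerate
    geometry yield ``None`` entries (masked features).
    """
    if rk is rl:
        raise DegenerateGeometryError("generalized phi/psi of a residue with itself")
    cos_phi = _quad_cos(
        (rk.get_atom("C"), rl.get_atom("N"), rl.get_atom("CA"), rl.get_atom("C"))
    )
    cos_psi = _quad_cos(
        (rk.get_atom("N"), rk.get_atom("CA"), rk.get_atom("C"), rl.get_atom("N"))
    )
    return cos_phi, cos_psi


def ca_pseudo_dihedral(
    ra: Residue, rb: Residue, s: ProteinStructure
) -> float | None:
    """cos of the C-alpha pseudo-dihedral Phi_ab for residues a, b of s.

    The inner two atoms are CA(a) (role i-1) and CA(b) (role i-2); the
    outer atom i is the CA nearest to CA(a) among the remaining residues,
    and i-3 the CA nearest to CA(b) among those remaining after that.
    Distance ties are broken by residue list index (lower wins), making
    the choice deterministic.
    """
    if len(s) < 4:
        raise InsufficientStructureError(
            "C-alpha pseudo-dihedral needs at least 4 residues"
        )
    idx_a = next((i for i, r in enumerate(s.residues) if r is ra), None)
    idx_b = next((i for i, r in enumerate(s.residues) if r is rb), None)
    if idx_a is None or idx_b is None:
        raise ValidationError("residues must belong to the structure")
    if idx_a == idx_b:
        raise DegenerateGeometryError("pseudo-dihedral of a residue with itself")

    coords = s.ca_coords()
    excluded = {idx_a, idx_b}

    def nearest(center: int, extra_excluded: set[int]) -> int:
        best = None
        best_d = np.inf
        for j in range(len(s)):
            if j in excluded or j in extra_excluded:
                continue
            d = np.linalg.norm(coords[j] - coords[center])
            if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and (best is None or j < best)):
                best, best_d = j, d
        return best

    idx_i = nearest(idx_a, set())          # closest to CA(a)
    idx_i3 = nearest(idx_b, {idx_i})       # closest to CA(b), i excluded
    quad = (coords[idx_i3], coords[idx_b], coords[idx_a], coords[idx_i])
    try:
        q = QuadDistances.from_points(*quad)
        return cos_dihedral_from_distances(q)
    except (DegenerateGeometryError, GeometryInconsistencyError, ValidationError):
        return None
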
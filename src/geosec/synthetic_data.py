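"""Labeled synthetic protein backbones from internal coordinates.

Chains are grown atom by atom (natural-extension reference frame) from
ideal bond lengths and angles, with per-residue (phi, psi) dihedrals set
by segment class:

* alpha helix: phi = -57, psi = -47 degrees;
* beta strand: phi = -139, psi = +135 degrees (antiparallel convention);
* coil: phi ~ -U(95, 150), psi ~ U(-30, 30) degrees per residue.

The coil region is chosen so that the *cosines* of the three classes
occupy disjoint regions: cosines are even functions, so e.g. a
left-handed region at phi = +57 would collide with the helix basin in
cosine space.  Gaussian jitter (degrees) on the dihedrals emulates
thermal/coordinate spread.  The peptide bond omega is fixed at 180
(trans); carbonyl O atoms are placed in the peptide plane.

These generated backbones carry exact labels by construction, which makes
every downstream stage — featurization, the FOS baseline, the
message-passing classifier, noise channels, evaluation — testable without
external structure downloads.  What they do not emulate: side chains,
inter-strand hydrogen bonding, compact tertiary packing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .structure_io import (
    AMINO_ACIDS,
    ProteinStructure,
    Residue,
    Atom,
    LabelSet,
    map_labels,
    MODE_BACKBONE,
    MODE_CA,
)

# ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

IDEAL_DIHEDRALS = {"alpha": (-57.0, -47.0), "beta": (-139.0, 135.0)}
CLASS_LETTER = {"alpha": "H", "beta": "E", "coil": "-"}


@dataclass
class SegmentSpec:
    """One secondary-structure segment of the chain to generate."""

    ss_class: str
    length: int
    phi: float | None = None
    psi: float | None = None
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.ss_class not in CLASS_LETTER:
            raise ValidationError(f"unknown segment class {self.ss_class!r}")
        if self.length < 1:
            raise ValidationError("segment length must be >= 1")
        if self.jitter < 0:
            raise ValidationError("jitter must be >= 0")


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position d such that |cd| = bond, angle(b,c,d) = angle and the
    dihedral a-b-c-d equals torsion (right-handed sign convention)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            -bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def signed_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees (IUPAC sign convention)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2))))


def _draw_dihedrals(seg: SegmentSpec, rng: np.random.Generator):
    """Per-residue (phi, psi) draws for one segment."""
    out = []
    for _ in range(seg.length):
        if seg.ss_class == "coil":
            phi = -rng.uniform(95.0, 150.0)
            psi = rng.uniform(-30.0, 30.0)
        else:
            phi0, psi0 = IDEAL_DIHEDRALS[seg.ss_class]
            phi = seg.phi if seg.phi is not None else phi0
            psi = seg.psi if seg.psi is not None else psi0
        if seg.jitter > 0:
            phi += rng.normal(0.0, seg.jitter)
            psi += rng.normal(0.0, seg.jitter)
        out.append((phi, psi))
    return out


def segment_letters(segments) -> list[str]:
    """Per-residue DSSP-style letters (H/E/-) implied by the segments."""
    letters = []
    for seg in segments:
        letters += [CLASS_LETTER[seg.ss_class]] * seg.length
    return letters


def build_backbone(
    segments,
    seed: int | np.random.Generator = 0,
    scheme: str = "alpha-beta-other",
    chain_id: str = "A",
) -> tuple[ProteinStructure, LabelSet]:
    """Grow a labeled backbone chain from the segment list.

    Returns the structure (N, CA, C, O atoms per residue) and its exact
    labels under ``scheme``.  Deterministic for a fixed seed.
    """
    segments = list(segments)
    if not segments:
        raise ValidationError("need at least one segment")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dihedrals = []
    for seg in segments:
        dihedrals += _draw_dihedrals(seg, rng)
    n_res = len(dihedrals)

    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(n_res - 1):
        psi_i = dihedrals[i][1]
        phi_next = dihedrals[i + 1][0]
        N.append(place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi_i))
        CA.append(
            place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        )
        C.append(
            place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi_next)
        )
    residues = []
    for i in range(n_res):
        O = place_atom(
            N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, dihedrals[i][1] + 180.0
        )
        res_type = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_index=i + 1,
                res_type=res_type,
                atoms=[
                    Atom("N", "N", N[i]),
                    Atom("CA", "C", CA[i]),
                    Atom("C", "C", C[i]),
                    Atom("O", "O", O),
                ],
            )
        )
    structure = ProteinStructure(
        residues=residues, source="synthetic", mode=MODE_BACKBONE
    )
    labels = map_labels(segment_letters(segments), scheme)
    return structure, labels


def to_ca_only(s: ProteinStructure) -> ProteinStructure:
    """CA-trace view of a backbone structure (fresh residue objects)."""
    residues = [
        Residue(
            chain_id=r.chain_id,
            seq_index=r.seq_index,
            res_type=r.res_type,
            atoms=[Atom("CA", "C", r.get_atom("CA").coords.copy())],
        )
        for r in s.residues
    ]
    return ProteinStructure(residues=residues, source=s.source, mode=MODE_CA)


def generate_dataset(
    n_proteins: int = 60,
    length_range: tuple[int, int] = (40, 80),
    class_mix: tuple[float, float, float] = (0.4, 0.3, 0.3),
    jitter: float = 5.0,
    seed: int = 0,
    scheme: str = "alpha-beta-other",
) -> list[tuple[ProteinStructure, LabelSet]]:
    """Generate a reproducible labeled dataset of synthetic proteins.

    Each protein is a random alternation of alpha/beta/coil segments
    (segment classes drawn from ``class_mix`` over (alpha, beta, coil);
    lengths: alpha 6-14, beta 4-8, coil 3-8 residues) until the target
    chain length from ``length_range`` is reached.
    """
    if n_proteins < 2:
        raise ValidationError("n_proteins must be >= 2")
    mix = np.asarray(class_mix, dtype=float)
    if mix.min() < 0 or mix.sum() <= 0:
        raise ValidationError("class_mix must be non-negative with positive sum")
    mix = mix / mix.sum()
    seg_lengths = {"alpha": (6, 14), "beta": (4, 8), "coil": (3, 8)}
    rng = np.random.default_rng(seed)
    dataset = []
    for p in range(n_proteins):
        target = int(rng.integers(length_range[0], length_range[1] + 1))
        segments = []
        total = 0
        while total < target:
            cls = ("alpha", "beta", "coil")[rng.choice(3, p=mix)]
            lo, hi = seg_lengths[cls]
            length = int(rng.integers(lo, hi + 1))
            segments.append(SegmentSpec(ss_class=cls, length=length, jitter=jitter))
            total += length
        structure, labels = build_backbone(
            segments, seed=rng, scheme=scheme, chain_id="A"
        )
        structure.source = f"synthetic-{p}"
        dataset.append((structure, labels))
    return dataset


def write_dssp_fixture(
    letters,
    path: str | Path,
    chain_id: str = "A",
    breaks=(),
) -> None:
    """Write a synthetic DSSP-format text file for the given 8-state letters.

    Produces the classic fixed-column layout (header banner, '#  RESIDUE'
    table header, one row per residue) with placeholder energies and
    coordinates — enough structure for any standards-compliant DSSP
    reader.  Residue list positions in ``breaks`` are emitted as '!'
    chain-break rows.  Synthetic: the records do not come from running
    the DSSP program.
    """
    letters = list(letters)
    if not letters:
        raise ValidationError("need at least one residue letter")
    path = Path(path)
    lines = [
        "==== SECONDARY STRUCTURE DEFINITION BY THE PROGRAM DSSP "
        "(SYNTHETIC FIXTURE) ====",
        "REFERENCE   SYNTHETIC RECORDS FOR TESTING ONLY",
        f"{len(letters):5d}{1:3d} TOTAL NUMBER OF RESIDUES, NUMBER OF CHAINS",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    index = 1
    resseq = 1
    for pos, letter in enumerate(letters):
        if pos in set(breaks):
            row = [" "] * 120
            row[:5] = f"{index:5d}"
            row[13] = "!"
            lines.append("".join(row))
            index += 1
        row = [" "] * 120
        row[:5] = f"{index:5d}"
        row[5:10] = f"{resseq:5d}"
        row[11] = chain_id
        row[13] = "A"
        row[16] = " " if letter == "-" else letter
        row[34:38] = f"{0:4d}"
        row[38:45] = f"{0:7d}"
        row[46:50] = f"{0.0:4.1f}"
        row[50:56] = f"{0:6d}"
        row[57:61] = f"{0.0:4.1f}"
        row[61:67] = f"{0:6d}"
        row[68:72] = f"{0.0:4.1f}"
        row[72:78] = f"{0:6d}"
        row[79:83] = f"{0.0:4.1f}"
        row[103:109] = f"{-57.0:6.1f}"
        row[109:115] = f"{-47.0:6.1f}"
        lines.append("".join(row))
        index += 1
        resseq += 1
    path.write_text("\n".join(lines) + "\n")


_PDB_RES3 = {aa: aa for aa in AMINO_ACIDS}


def write_fixture(s: ProteinStructure, path: str | Path) -> None:
    """Write minimal PDB ATOM records readable by structure_io."""
    if not s.residues:
        raise ValidationError("cannot write an empty structure")
    path = Path(path)
    serial = 1
    lines = []
    for res in s.residues:
        res3 = _PDB_RES3.get(res.res_type, "UNK")
        for atom in res.atoms:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:4s} {res3:>3s} {res.chain_id:1s}"
                f"{res.seq_index:4d}    "
                f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
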
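"""Structure and label input/output.

Protein structures are read from PDB files into a deliberately small data
model: ordered residues carrying heavy backbone atoms (N, CA, C, O) or a
bare C-alpha trace.  Residue numbering is kept only for reporting — no
downstream feature ever depends on it, which is what makes the whole
pipeline applicable to structures whose sequence connectivity is unknown.

Secondary-structure labels come from DSSP text output (8 states:
H, G, I, E, B, T, S, '-') and are collapsed onto one of four classification
schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.DSSP import make_dssp_dict

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

MODE_BACKBONE = "all-backbone"
MODE_CA = "ca-only"

BACKBONE_ATOMS = ("N", "CA", "C", "O")

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
#: index of each residue type in the 21-way one-hot (20 aa + UNK).
RES_TYPE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
UNK_INDEX = len(AMINO_ACIDS)

DSSP_LETTERS = "HGIEBTS-"

#: label schemes -> number of classes
SCHEMES = {
    "alpha-other": 2,
    "beta-other": 2,
    "alpha-beta-other": 3,
    "all8": 8,
}

# Default letter -> class-id tables.  Only DSSP H counts as helix and only E
# as strand in the reduced schemes (G/I/B go to Other); the tables are
# arguments of map_labels so stricter or looser collapses remain available.
DEFAULT_TABLES = {
    "alpha-other": {letter: (1 if letter == "H" else 0) for letter in DSSP_LETTERS},
    "beta-other": {letter: (1 if letter == "E" else 0) for letter in DSSP_LETTERS},
    "alpha-beta-other": {
        letter: (0 if letter == "H" else 1 if letter == "E" else 2)
        for letter in DSSP_LETTERS
    },
    "all8": {letter: i for i, letter in enumerate(DSSP_LETTERS)},
}

#: class ids that denote an alpha/beta secondary-structure *element*
#: (used by segmentation and boundary analyses), and the id of "Other".
ELEMENT_CLASSES = {
    "alpha-other": {1: "alpha"},
    "beta-other": {1: "beta"},
    "alpha-beta-other": {0: "alpha", 1: "beta"},
    "all8": {0: "alpha", 3: "beta"},
}
OTHER_CLASS = {"alpha-other": 0, "beta-other": 0, "alpha-beta-other": 2, "all8": 7}


@dataclass
class Atom:
    """A named atom with 3-D coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValidationError("atom name must be non-empty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.name}: coords must be a finite 3-vector")


@dataclass
class Residue:
    """One residue: a chain id, an author number, and its retained atoms.

    ``seq_index`` is reporting metadata only; featurization never reads it.
    """

    chain_id: str
    seq_index: int
    res_type: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def __post_init__(self) -> None:
        if self.res_type not in RES_TYPE_INDEX and self.res_type != "UNK":
            self.res_type = "UNK"
        seen = set()
        for a in self.atoms:
            key = (a.name, a.altloc)
            if key in seen:
                raise ValidationError(
                    f"duplicate atom {key} in residue {self.chain_id}{self.seq_index}"
                )
            seen.add(key)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_complete_backbone(self) -> bool:
        names = {a.name for a in self.atoms}
        return {"N", "CA", "C"} <= names

    def type_index(self) -> int:
        return RES_TYPE_INDEX.get(self.res_type, UNK_INDEX)


@dataclass
class ProteinStructure:
    """An ordered list of residues plus provenance and atom-content mode."""

    residues: list[Residue]
    source: str = ""
    mode: str = MODE_BACKBONE

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError("structure must contain at least one residue")
        if self.mode not in (MODE_BACKBONE, MODE_CA):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == MODE_CA:
            for r in self.residues:
                if len(r.atoms) != 1 or r.atoms[0].name != "CA":
                    raise ValidationError(
                        f"ca-only structure has non-CA content at {r.chain_id}{r.seq_index}"
                    )

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of C-alpha positions (every residue has a CA)."""
        return np.array([r.get_atom("CA").coords for r in self.residues])


@dataclass
class LabelSet:
    """Per-residue class ids under one of the four schemes."""

    scheme: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        self.labels = np.asarray(self.labels, dtype=int)
        n_classes = SCHEMES[self.scheme]
        if self.labels.ndim != 1:
            raise ValidationError("labels must be 1-D")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= n_classes
        ):
            raise ValidationError(
                f"labels out of range for scheme {self.scheme} ({n_classes} classes)"
            )

    @property
    def n_classes(self) -> int:
        return SCHEMES[self.scheme]

    def __len__(self) -> int:
        return len(self.labels)


def _pick_altloc(biopdb_atom):
    """Resolve a (possibly disordered) Biopython atom to a single location.

    Highest occupancy wins; equal occupancies fall back to altloc
    character order.
    """
    if biopdb_atom.is_disordered():
        children = biopdb_atom.disordered_get_list()
        children = sorted(
            children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc())
        )
        return children[0]
    return biopdb_atom


def read_structure(path: str | Path, mode: str = MODE_BACKBONE) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Only ATOM records are considered; only heavy backbone atoms (N, CA, C,
    O) are retained in all-backbone mode, only CA in ca-only mode.  For NMR
    ensembles the first model is used.  Residues without a CA atom are
    dropped with a warning.
    """
    if mode not in (MODE_BACKBONE, MODE_CA):
        raise ValidationError(f"unknown mode {mode!r}")
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        biostruct = parser.get_structure("s", str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio.PDB raises assorted construction errors
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(biostruct.get_models())
    if not models:
        raise FormatError(f"no models in {path}")
    wanted = ("CA",) if mode == MODE_CA else BACKBONE_ATOMS

    residues: list[Residue] = []
    for chain in models[0]:
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag.strip():  # skip HETATM / waters
                continue
            atoms = []
            for name in wanted:
                if name in res:
                    a = _pick_altloc(res[name])
                    atoms.append(
                        Atom(
                            name=name,
                            element=(a.element or name[0]).strip(),
                            coords=np.asarray(a.get_coord(), dtype=float),
                            altloc=(a.get_altloc() or "").strip(),
                        )
                    )
            if not any(a.name == "CA" for a in atoms):
                logger.warning(
                    "dropping residue %s%s%s (no CA atom)",
                    chain.id, resseq, icode.strip(),
                )
                continue
            residues.append(
                Residue(
                    chain_id=chain.id,
                    seq_index=resseq,
                    res_type=res.get_resname().strip(),
                    atoms=atoms,
                    icode=icode.strip(),
                )
            )
    if not residues:
        raise FormatError(f"no polymer residues parsed from {path}")
    return ProteinStructure(residues=residues, source=str(path), mode=mode)


def read_dssp(path: str | Path) -> list[tuple[str, int, str]]:
    """Parse classic DSSP text output into ordered (chain, resnum, letter).

    Chain-break records ('!') are skipped; a blank secondary-structure
    column maps to '-'.
    """
    path = Path(path)
    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse DSSP file {path}: {exc}") from exc
    if not keys:
        raise FormatError(f"no residue records in DSSP file {path}")
    out = []
    for key in keys:
        chain, (_het, resseq, _icode) = key
        ss = dssp_dict[key][1]
        letter = "-" if ss in (" ", "", "-") else ss
        if letter not in DSSP_LETTERS:
            raise FormatError(f"unknown DSSP state {ss!r} in {path}")
        out.append((chain, resseq, letter))
    return out


def map_labels(
    letters, scheme: str, table: dict[str, int] | None = None
) -> LabelSet:
    """Collapse 8-state DSSP letters onto class ids for ``scheme``.

    ``letters`` may be raw letters or (chain, resnum, letter) triples as
    returned by :func:`read_dssp`.  A custom ``table`` overrides the default
    collapse (e.g. to count G/I helices as alpha).
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    table = table if table is not None else DEFAULT_TABLES[scheme]
    ids = []
    for item in letters:
        letter = item[2] if isinstance(item, tuple) else item
        if letter not in table:
            raise ValidationError(f"unknown secondary-structure letter {letter!r}")
        ids.append(table[letter])
    return LabelSet(scheme=scheme, labels=np.asarray(ids, dtype=int))


def write_labels(
    structure: ProteinStructure,
    labels: LabelSet,
    path: str | Path,
    letters=None,
) -> None:
    """Write per-residue labels as TSV: chain, resnum, letter, class_id."""
    if len(labels) != len(structure):
        raise ValidationError("label/structure length mismatch")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chain\tresnum\tletter\tclass_id\n")
        for i, (res, cls) in enumerate(zip(structure.residues, labels.labels)):
            letter = letters[i] if letters is not None else "."
            fh.write(f"{res.chain_id}\t{res.seq_index}\t{letter}\t{int(cls)}\n")


def read_labels(path: str | Path, scheme: str) -> LabelSet:
    """Read a labels TSV produced by :func:`write_labels`."""
    path = Path(path)
    ids = []
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("chain"):
            raise FormatError(f"unexpected labels header in {path}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise FormatError(f"malformed labels row in {path}: {line!r}")
            ids.append(int(parts[3]))
    return LabelSet(scheme=scheme, labels=np.asarray(ids, dtype=int))
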
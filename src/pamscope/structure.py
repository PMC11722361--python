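"""Structure and trajectory data model, PDB I/O and atom selections.

The containers here are deliberately thin: plain numpy arrays indexed per
atom, with coordinates stored in nm.  PDB files (including multi-model
files, which serve as the portable trajectory format) are read and written
through biotite; masses are filled in from an internal element table so
that centre-of-mass operations never depend on topology files.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bts
import biotite.structure.io.pdb as bts_pdb

from .units import ANGSTROM_TO_NM, NM_TO_ANGSTROM

# Standard atomic masses (amu); sufficient for protein/nucleic systems plus
# common ions.  Unknown elements fall back to a carbon-like default with a
# warning rather than failing, since exotic HETATM records are not this
# package's concern.
ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "HE": 4.0026,
    "LI": 6.94, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "AL": 26.982, "SI": 28.085,
    "P": 30.974, "S": 32.06, "CL": 35.45, "K": 39.098, "CA": 40.078,
    "MN": 54.938, "FE": 55.845, "CO": 58.933, "NI": 58.693, "CU": 63.546,
    "ZN": 65.38, "SE": 78.971, "BR": 79.904, "I": 126.904,
}
_DEFAULT_MASS = 12.011

PROTEIN_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
NUCLEIC_BACKBONE_NAMES = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "O2'", "C1'",
}
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}
NUCLEOTIDES = {
    "DA", "DT", "DG", "DC", "DU", "A", "U", "G", "C", "T",
    "DA3", "DA5", "DT3", "DT5", "DG3", "DG5", "DC3", "DC5",
    "RA", "RU", "RG", "RC",
}


def element_from_atom_name(name: str) -> str:
    """Infer the chemical element from a PDB atom name (e.g. 'OP1' -> 'O')."""
    stripped = re.sub(r"[^A-Za-z]", "", name)
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in ELEMENT_MASSES and two not in {"CA", "CO", "CL", "NA", "NI", "SE", "HE", "MG"}:
        return two
    # Atom names like CA (C-alpha) or HG1 start with the element letter.
    return stripped[0].upper()


def mass_of_element(element: str, atom_name: str = "") -> float:
    key = element.upper().strip()
    if key in ELEMENT_MASSES:
        return ELEMENT_MASSES[key]
    guess = element_from_atom_name(atom_name) if atom_name else ""
    if guess in ELEMENT_MASSES:
        warnings.warn(
            f"unknown element {element!r}; using element {guess!r} derived "
            f"from atom name {atom_name!r}"
        )
        return ELEMENT_MASSES[guess]
    warnings.warn(f"unknown element {element!r}; assigning default mass")
    return _DEFAULT_MASS


@dataclass
class StructureModel:
    """A molecular structure as flat per-atom arrays; coordinates in nm."""

    atom_id: np.ndarray          # int
    atom_name: np.ndarray        # str
    element: np.ndarray          # str
    residue_number: np.ndarray   # int
    residue_name: np.ndarray     # str
    chain_id: np.ndarray         # str
    mass: np.ndarray             # amu
    coordinates: np.ndarray      # (n_atoms, 3), nm
    charge: np.ndarray | None = None  # e, optional

    def __post_init__(self) -> None:
        n = len(self.atom_id)
        if len(set(self.atom_id.tolist())) != n:
            raise ValueError("atom_ids must be unique")
        if np.any(self.mass <= 0):
            raise ValueError("all masses must be positive")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must have shape (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    def select(self, expression: str, label: str | None = None) -> "AtomSelection":
        return select(self, expression, label=label)

    def subset(self, indices: np.ndarray) -> "StructureModel":
        idx = np.asarray(indices, dtype=int)
        return StructureModel(
            atom_id=self.atom_id[idx],
            atom_name=self.atom_name[idx],
            element=self.element[idx],
            residue_number=self.residue_number[idx],
            residue_name=self.residue_name[idx],
            chain_id=self.chain_id[idx],
            mass=self.mass[idx],
            coordinates=self.coordinates[idx],
            charge=None if self.charge is None else self.charge[idx],
        )


@dataclass
class TrajectoryEnsemble:
    """An ordered set of coordinate frames sharing one reference topology."""

    reference: StructureModel
    frames: np.ndarray        # (n_frames, n_atoms, 3), nm
    frame_interval: float = 1.0   # ps
    replicate_id: int = 0
    source_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.reference.n_atoms:
            raise ValueError(
                "frames must have shape (n_frames, n_atoms, 3) matching the reference"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class AtomSelection:
    """An ordered, unique list of atom indices into a StructureModel."""

    structure: StructureModel
    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) != len(set(self.indices.tolist())):
            raise ValueError("selection indices must be unique")
        if len(self.indices) and (
            self.indices.min() < 0 or self.indices.max() >= self.structure.n_atoms
        ):
            raise ValueError("selection indices out of range")
        if len(self.indices) == 0:
            warnings.warn(f"selection {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def masses(self) -> np.ndarray:
        return self.structure.mass[self.indices]

    def coordinates(self, frame: np.ndarray | None = None) -> np.ndarray:
        coords = self.structure.coordinates if frame is None else frame
        return coords[self.indices]


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _model_from_atom_array(atoms: bts.AtomArray) -> StructureModel:
    n = atoms.array_length()
    elements = np.array([e if e else "" for e in atoms.element], dtype=object)
    names = np.array(atoms.atom_name, dtype=object)
    masses = np.array(
        [mass_of_element(e, str(nm)) for e, nm in zip(elements, names)]
    )
    fixed_elements = np.array(
        [e.upper() if e.upper() in ELEMENT_MASSES else element_from_atom_name(str(nm))
         for e, nm in zip(elements, names)],
        dtype=object,
    )
    charge = None
    if "charge" in atoms.get_annotation_categories():
        raw = np.asarray(atoms.charge, dtype=float)
        if np.any(raw != 0):
            charge = raw
    return StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=names,
        element=fixed_elements,
        residue_number=np.array(atoms.res_id, dtype=int),
        residue_name=np.array(atoms.res_name, dtype=object),
        chain_id=np.array(atoms.chain_id, dtype=object),
        mass=masses,
        coordinates=np.asarray(atoms.coord, dtype=float) * ANGSTROM_TO_NM,
        charge=charge,
    )


def load_structure(path: str, model: int | None = None) -> StructureModel:
    """Read a PDB file into a StructureModel (first model by default).

    Atoms are kept in file order; masses come from the element table, with
    name-derived fallback for blank or unknown element columns.
    """
    pdb = bts_pdb.PDBFile.read(path)
    n_models = pdb.get_model_count()
    if n_models < 1:
        raise ValueError(f"{path}: no MODEL/coordinate records found")
    atoms = pdb.get_structure(model=1 if model is None else model)
    return _model_from_atom_array(atoms)


def load_trajectory(
    path: str, frame_interval: float = 1.0, replicate_id: int = 0
) -> TrajectoryEnsemble:
    """Read a multi-model PDB file as a trajectory ensemble."""
    pdb = bts_pdb.PDBFile.read(path)
    stack = pdb.get_structure()  # AtomArrayStack over all models
    if isinstance(stack, bts.AtomArray):
        stack = bts.stack([stack])
    reference = _model_from_atom_array(stack[0])
    frames = np.asarray(stack.coord, dtype=float) * ANGSTROM_TO_NM
    return TrajectoryEnsemble(
        reference=reference,
        frames=frames,
        frame_interval=frame_interval,
        replicate_id=replicate_id,
        source_label=str(path),
    )


def _atom_array_from_model(
    model: StructureModel, coordinates_nm: np.ndarray
) -> bts.AtomArray:
    n = model.n_atoms
    atoms = bts.AtomArray(n)
    atoms.coord = np.asarray(coordinates_nm, dtype=np.float32) * NM_TO_ANGSTROM
    atoms.atom_name = np.array(model.atom_name, dtype="U6")
    atoms.element = np.array(model.element, dtype="U2")
    atoms.res_id = np.array(model.residue_number, dtype=int)
    atoms.res_name = np.array(model.residue_name, dtype="U5")
    atoms.chain_id = np.array(model.chain_id, dtype="U4")
    atoms.hetero = np.zeros(n, dtype=bool)
    return atoms


def write_pdb(path: str, obj: StructureModel | TrajectoryEnsemble) -> None:
    """Write a structure (one MODEL) or an ensemble (multi-MODEL) to PDB."""
    pdb = bts_pdb.PDBFile()
    if isinstance(obj, TrajectoryEnsemble):
        arrays = [
            _atom_array_from_model(obj.reference, frame) for frame in obj.frames
        ]
        pdb.set_structure(bts.stack(arrays))
    else:
        pdb.set_structure(_atom_array_from_model(obj, obj.coordinates))
    pdb.write(path)


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------
#
# Grammar (case-insensitive keywords):
#   expr     := term ("or" term)*
#   term     := factor ("and" factor)*
#   factor   := "not" factor | "(" expr ")" | primary
#   primary  := "resid" ranges | "resname" words | "name" words
#             | "chain" words | "element" words
#             | "protein" | "nucleic" | "backbone" | "sidechain"
#             | "hydrogen" | "heavy" | "all" | "none"
#   ranges   := (INT | INT "-" INT)+

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS = {
    "and", "or", "not", "resid", "resname", "name", "chain", "element",
    "protein", "nucleic", "backbone", "sidechain", "hydrogen", "heavy",
    "all", "none",
}


class SelectionSyntaxError(ValueError):
    pass


class _Parser:
    def __init__(self, structure: StructureModel, expression: str):
        self.s = structure
        self.tokens = _TOKEN_RE.findall(expression)
        if not self.tokens:
            raise SelectionSyntaxError("empty selection expression")
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionSyntaxError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression")
        if tok.lower() == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionSyntaxError("missing closing parenthesis")
            return mask
        return self.primary()

    def _collect_words(self) -> list[str]:
        words = []
        while True:
            tok = self.peek()
            if tok is None or tok in {"(", ")"} or tok.lower() in _KEYWORDS:
                break
            words.append(self.next())
        if not words:
            raise SelectionSyntaxError("keyword requires at least one argument")
        return words

    def primary(self) -> np.ndarray:
        s = self.s
        tok = self.next().lower()
        names_u = np.char.upper(s.atom_name.astype(str))
        res_u = np.char.upper(s.residue_name.astype(str))
        if tok == "resid":
            mask = np.zeros(s.n_atoms, dtype=bool)
            for word in self._collect_words():
                m = re.fullmatch(r"(-?\d+)\s*[-:]\s*(-?\d+)", word)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                else:
                    try:
                        lo = hi = int(word)
                    except ValueError:
                        raise SelectionSyntaxError(f"bad resid token {word!r}")
                mask |= (s.residue_number >= lo) & (s.residue_number <= hi)
            return mask
        if tok == "resname":
            wanted = {w.upper() for w in self._collect_words()}
            return np.isin(res_u, list(wanted))
        if tok == "name":
            wanted = {w.upper() for w in self._collect_words()}
            return np.isin(names_u, list(wanted))
        if tok == "chain":
            wanted = set(self._collect_words())
            return np.isin(s.chain_id.astype(str), list(wanted))
        if tok == "element":
            wanted = {w.upper() for w in self._collect_words()}
            return np.isin(np.char.upper(s.element.astype(str)), list(wanted))
        if tok == "protein":
            return np.isin(res_u, list(AMINO_ACIDS))
        if tok == "nucleic":
            return np.isin(res_u, list(NUCLEOTIDES))
        if tok == "hydrogen":
            return np.char.upper(s.element.astype(str)) == "H"
        if tok == "heavy":
            return np.char.upper(s.element.astype(str)) != "H"
        if tok == "backbone":
            prot = np.isin(res_u, list(AMINO_ACIDS)) & np.isin(
                names_u, list(PROTEIN_BACKBONE_NAMES)
            )
            nuc = np.isin(res_u, list(NUCLEOTIDES)) & np.isin(
                names_u, list(NUCLEIC_BACKBONE_NAMES)
            )
            return prot | nuc
        if tok == "sidechain":
            prot = np.isin(res_u, list(AMINO_ACIDS))
            not_bb = ~np.isin(names_u, list(PROTEIN_BACKBONE_NAMES))
            not_h = np.char.upper(s.element.astype(str)) != "H"
            return prot & not_bb & not_h
        if tok == "all":
            return np.ones(s.n_atoms, dtype=bool)
        if tok == "none":
            return np.zeros(s.n_atoms, dtype=bool)
        raise SelectionSyntaxError(f"unknown selection keyword {tok!r}")


def select(
    structure: StructureModel, expression: str, label: str | None = None
) -> AtomSelection:
    """Evaluate a selection expression, preserving atom (file) order."""
    mask = _Parser(structure, expression).parse()
    indices = np.nonzero(mask)[0]
    return AtomSelection(structure, indices, label=label or expression)


def selection_from_indices(
    structure: StructureModel, indices: Iterable[int], label: str = ""
) -> AtomSelection:
    return AtomSelection(structure, np.asarray(list(indices), dtype=int), label=label)


def com(coordinates: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted centre of geometry of one coordinate set (nm)."""
    masses = np.asarray(masses, dtype=float)
    return (coordinates * masses[:, None]).sum(axis=0) / masses.sum()
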
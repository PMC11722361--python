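import numpy as np
import pytest

from pamscope import structure as st


def pdb_atom_line(serial, name, res_name, chain, res_id, x, y, z, element):
    """Format one fixed-column PDB ATOM record (coordinates in Angstrom)."""
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_field} {res_name:<3s} {chain}{res_id:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


@pytest.fixture
def three_atom_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_atom_line(2, "CA", "GLY", "A", 1, 1.458, 0.0, 0.0, "C"),
        pdb_atom_line(3, "C", "GLY", "A", 1, 2.0, 1.4, 0.0, "C"),
        "END",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def two_model_pdb(tmp_path):
    block1 = [
        pdb_atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_atom_line(2, "CA", "GLY", "A", 1, 1.458, 0.0, 0.0, "C"),
    ]
    block2 = [
        pdb_atom_line(1, "N", "GLY", "A", 1, 0.5, 0.0, 0.0, "N"),
        pdb_atom_line(2, "CA", "GLY", "A", 1, 1.958, 0.0, 0.0, "C"),
    ]
    lines = ["MODEL     1", *block1, "ENDMDL", "MODEL     2", *block2, "ENDMDL", "END"]
    path = tmp_path / "two_model.pdb"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


ARG_ATOMS = [
    # (name, element), author residue number 1335 as in SpCas9's PAM dyad
    ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"),
    ("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"),
    ("CZ", "C"), ("NH1", "N"), ("NH2", "N"),
]


@pytest.fixture
def arginine_structure(tmp_path):
    rng = np.random.default_rng(0)
    lines = []
    for i, (name, elem) in enumerate(ARG_ATOMS):
        x, y, z = rng.uniform(0, 5, 3)
        lines.append(pdb_atom_line(i + 1, name, "ARG", "B", 1335, x, y, z, elem))
    lines.append("END")
    path = tmp_path / "arg.pdb"
    path.write_text("\n".join(lines) + "\n")
    return st.load_structure(str(path))


@pytest.fixture
def dna_three_nt(tmp_path):
    """3-nucleotide DNA strand; the 5' residue carries no phosphate group."""
    res_atoms = {
        1: [("O5'", "O"), ("C5'", "C"), ("C1'", "C"), ("N9", "N")],
        2: [("P", "P"), ("OP1", "O"), ("OP2", "O"), ("O5'", "O"), ("C1'", "C"), ("N1", "N")],
        3: [("P", "P"), ("OP1", "O"), ("OP2", "O"), ("O5'", "O"), ("C1'", "C"), ("N9", "N")],
    }
    res_names = {1: "DG", 2: "DT", 3: "DG"}
    rng = np.random.default_rng(1)
    lines, serial = [], 1
    for res_id, atoms in res_atoms.items():
        for name, elem in atoms:
            x, y, z = rng.uniform(0, 20, 3)
            lines.append(
                pdb_atom_line(serial, name, res_names[res_id], "C", res_id, x, y, z, elem)
            )
            serial += 1
    lines.append("END")
    path = tmp_path / "dna.pdb"
    path.write_text("\n".join(lines) + "\n")
    return st.load_structure(str(path))


def make_structure(coords_nm, names=None, elements=None, masses=None,
                   res_ids=None, res_names=None, chain="A", charges=None):
    """Build a StructureModel directly from arrays (coordinates in nm)."""
    coords = np.asarray(coords_nm, dtype=float)
    n = len(coords)
    elements = np.array(elements if elements is not None else ["C"] * n, dtype=object)
    if masses is None:
        masses = np.array([st.mass_of_element(e) for e in elements])
    return st.StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=np.array(names if names is not None else [f"X{i}" for i in range(n)],
                           dtype=object),
        element=elements,
        residue_number=np.array(res_ids if res_ids is not None else np.ones(n, int)),
        residue_name=np.array(res_names if res_names is not None else ["UNK"] * n,
                              dtype=object),
        chain_id=np.array([chain] * n, dtype=object),
        mass=np.asarray(masses, dtype=float),
        coordinates=coords,
        charge=None if charges is None else np.asarray(charges, dtype=float),
    )


def make_trajectory(structure, frames_nm, dt=1.0, replicate_id=0):
    return st.TrajectoryEnsemble(structure, np.asarray(frames_nm, dtype=float),
                                 frame_interval=dt, replicate_id=replicate_id)
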
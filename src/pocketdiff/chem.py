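"""Chemical domain types, element radii, and molecular file I/O.

Atoms are treated as nuclei with two concentric length scales: the van der
Waals radius ``R`` (the spatial extent of the electron cloud, used to build
the manifold shell) and the covalent radius ``d`` (the bonding scale, used
as the steric-clash threshold: a ligand-protein pair closer than
``D_ij = d_i + d_j`` is an atomic collision).

Coordinates are Cartesian, in Angstrom, with no periodic boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ElementInfo",
    "AtomRecord",
    "LigandStructure",
    "PocketStructure",
    "ComplexRecord",
    "UnknownElementError",
    "ParseError",
    "lookup_radii",
    "pair_threshold",
    "read_ligand",
    "write_ligand",
    "read_pocket",
    "write_pocket",
    "k_nearest_pocket_atoms",
    "DEFAULT_ATOM_VOCABULARY",
    "BACKBONE_ATOM_NAMES",
]

# van der Waals radii: Bondi (1964), Angstrom.
_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "B": 1.92, "Si": 2.10, "Se": 1.90,
}

# Covalent radii: Cordero et al. (2008), Angstrom (C sp3).
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
    "B": 0.84, "Si": 1.11, "Se": 1.20,
}

#: Default ligand atom-type vocabulary for the categorical diffusion channel.
DEFAULT_ATOM_VOCABULARY = ("C", "N", "O", "F", "P", "S", "Cl")

#: Protein backbone atom names kept by the default pocket reader.
BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")


class UnknownElementError(KeyError):
    """Raised when an element symbol is not in the bundled radii tables."""


class ParseError(ValueError):
    """Raised on malformed molecular file content; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclasses.dataclass(frozen=True)
class ElementInfo:
    """An element symbol with its van der Waals and covalent radii (Angstrom)."""

    symbol: str
    vdw_radius: float
    covalent_radius: float

    def __post_init__(self):
        if not (self.vdw_radius > 0 and self.covalent_radius > 0):
            raise ValueError("radii must be positive")
        if not self.covalent_radius < self.vdw_radius:
            raise ValueError("covalent radius must be below the vdW radius")


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom: element identity plus a finite 3-vector coordinate in Angstrom."""

    element: ElementInfo
    coordinate: np.ndarray

    def __post_init__(self):
        coord = np.asarray(self.coordinate, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError("coordinate must be a finite 3-vector")
        object.__setattr__(self, "coordinate", coord)


def lookup_radii(symbol: str) -> ElementInfo:
    """Return the bundled van der Waals and covalent radii for ``symbol``.

    Raises :class:`UnknownElementError` for out-of-table symbols; there is no
    silent default radius.
    """
    symbol = symbol.strip()
    key = symbol.capitalize()
    if key not in _VDW_RADII or key not in _COVALENT_RADII:
        raise UnknownElementError(f"no bundled radii for element {symbol!r}")
    return ElementInfo(key, _VDW_RADII[key], _COVALENT_RADII[key])


def pair_threshold(a: ElementInfo, b: ElementInfo) -> float:
    """Collision threshold for an atom pair: the sum of covalent radii, D = d_a + d_b."""
    return a.covalent_radius + b.covalent_radius


class _AtomCollection:
    """Shared storage: element list + (n, 3) coordinate array."""

    def __init__(self, elements: Sequence[ElementInfo], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if len(elements) != len(coords):
            raise ValueError("elements and coords length mismatch")
        if len(elements) == 0:
            raise ValueError("structure must contain at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.elements = list(elements)
        self.coords = coords

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [AtomRecord(e, c) for e, c in zip(self.elements, self.coords)]

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.elements]


class LigandStructure(_AtomCollection):
    """A small-molecule ligand: an ordered set of atoms, optionally bonded."""

    def __init__(self, elements, coords, bonds: Sequence[tuple[int, int]] | None = None):
        super().__init__(elements, coords)
        n = len(self.elements)
        bonds = [tuple(sorted(map(int, b))) for b in (bonds or [])]
        for i, j in bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index ({i},{j}) out of range for {n} atoms")
        # no two atoms at identical coordinates
        if n > 1:
            d = np.linalg.norm(self.coords[:, None] - self.coords[None, :], axis=-1)
            if np.any(d[np.triu_indices(n, 1)] == 0.0):
                raise ValueError("two atoms share identical coordinates")
        self.bonds = bonds

    def with_coords(self, coords: np.ndarray) -> "LigandStructure":
        return LigandStructure(self.elements, coords, self.bonds)


class PocketStructure(_AtomCollection):
    """A protein binding-site: atoms with per-atom residue id and name."""

    def __init__(self, elements, coords, residue_labels: Sequence[tuple[int, str]] | None = None,
                 atom_names: Sequence[str] | None = None):
        super().__init__(elements, coords)
        n = len(self.elements)
        self.residue_labels = list(residue_labels) if residue_labels is not None else [(i + 1, "UNK") for i in range(n)]
        self.atom_names = list(atom_names) if atom_names is not None else self.symbols
        if len(self.residue_labels) != n or len(self.atom_names) != n:
            raise ValueError("per-atom annotation length mismatch")


@dataclasses.dataclass
class ComplexRecord:
    """A pocket paired with a ligand; the unit of all metrics and generation."""

    ligand: LigandStructure
    pocket: PocketStructure
    provenance: str = ""

    def __post_init__(self):
        if len(self.ligand) == 0 or len(self.pocket) == 0:
            raise ValueError("both ligand and pocket must be nonempty")


# ---------------------------------------------------------------------------
# File I/O


def _ligand_from_rdkit(mol) -> LigandStructure:
    from rdkit import Chem

    conf = mol.GetConformer()
    elements, coords = [], []
    for atom in mol.GetAtoms():
        elements.append(lookup_radii(atom.GetSymbol()))
        p = conf.GetAtomPosition(atom.GetIdx())
        coords.append([p.x, p.y, p.z])
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return LigandStructure(elements, np.array(coords), bonds)


def _read_xyz(path: Path) -> LigandStructure:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty XYZ file", 1)
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("expected atom count", 1)
    elements, coords = [], []
    for k in range(n):
        lineno = k + 3
        try:
            parts = lines[k + 2].split()
            sym, x, y, z = parts[0], float(parts[1]), float(parts[2]), float(parts[3])
        except (IndexError, ValueError):
            raise ParseError("malformed XYZ atom record", lineno)
        elements.append(lookup_radii(sym))
        coords.append([x, y, z])
    return LigandStructure(elements, np.array(coords))


def read_ligand(path, fmt: str | None = None) -> LigandStructure:
    """Read a ligand from SDF, MOL or XYZ. ``fmt`` defaults to the file suffix."""
    from rdkit import Chem

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt in ("sdf", "mol"):
        if fmt == "sdf":
            supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
            mol = next(iter(supplier), None)
        else:
            mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
        if mol is None:
            raise ParseError(f"RDKit could not parse {path}")
        return _ligand_from_rdkit(mol)
    raise ValueError(f"unsupported ligand format: {fmt}")


def write_ligand(ligand: LigandStructure, path, fmt: str | None = None) -> None:
    """Write a ligand to SDF or XYZ (3-decimal coordinate precision for both)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        lines = [str(len(ligand)), "generated by pocketdiff"]
        for e, c in zip(ligand.elements, ligand.coords):
            lines.append(f"{e.symbol} {c[0]:.3f} {c[1]:.3f} {c[2]:.3f}")
        path.write_text("\n".join(lines) + "\n")
        return
    if fmt == "sdf":
        mol = Chem.RWMol()
        for e in ligand.elements:
            mol.AddAtom(Chem.Atom(e.symbol))
        for i, j in ligand.bonds:
            mol.AddBond(i, j, Chem.BondType.SINGLE)
        conf = Chem.Conformer(len(ligand))
        for idx, c in enumerate(ligand.coords):
            conf.SetAtomPosition(idx, Point3D(*map(float, c)))
        mol.AddConformer(conf)
        with Chem.SDWriter(str(path)) as w:
            w.SetKekulize(False)
            w.write(mol.GetMol())
        return
    raise ValueError(f"unsupported ligand format: {fmt}")


def read_pocket(path, backbone_only: bool = True) -> PocketStructure:
    """Read a protein pocket from a PDB file.

    Keeps backbone atoms (N, CA, C, O) of standard ATOM records by default;
    ``backbone_only=False`` keeps every non-hydrogen ATOM record.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1)
    mask = ~arr.hetero
    if backbone_only:
        mask &= np.isin(arr.atom_name, BACKBONE_ATOM_NAMES)
    else:
        mask &= arr.element != "H"
    arr = arr[mask]
    if arr.array_length() == 0:
        raise ParseError(f"no protein {'backbone ' if backbone_only else ''}atoms in {path}")
    elements = [lookup_radii(e) for e in arr.element]
    labels = list(zip((int(r) for r in arr.res_id), arr.res_name))
    return PocketStructure(elements, arr.coord, labels, list(arr.atom_name))


def write_pocket(pocket: PocketStructure, path) -> None:
    """Write a pocket to PDB (ATOM records, 3-decimal coordinates)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(pocket)
    arr = struc.AtomArray(n)
    arr.coord = pocket.coords.astype(np.float32)
    arr.element = np.array(pocket.symbols)
    arr.atom_name = np.array(pocket.atom_names)
    arr.res_id = np.array([rid for rid, _ in pocket.residue_labels])
    arr.res_name = np.array([name for _, name in pocket.residue_labels])
    arr.chain_id = np.array(["A"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def k_nearest_pocket_atoms(ligand_atom: AtomRecord | np.ndarray, pocket: PocketStructure, k: int) -> np.ndarray:
    """Indices of the K pocket atoms nearest to a ligand atom.

    Sorted by ascending Euclidean distance; exact ties broken by lower atom
    index (stable sort), making the neighborhood deterministic.
    """
    if k > len(pocket):
        raise ValueError(f"K={k} exceeds pocket size {len(pocket)}")
    x = ligand_atom.coordinate if isinstance(ligand_atom, AtomRecord) else np.asarray(ligand_atom, float)
    d = np.linalg.norm(pocket.coords - x[None, :], axis=1)
    order = np.argsort(d, kind="stable")
    return order[:k]
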
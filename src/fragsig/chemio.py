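"""Small-molecule input/output and per-atom annotation.

Molecules are read from Tripos MOL2 or SDF files into a light internal model
(atoms with coordinates, van der Waals radii and partial charges, plus a bond
list).  The MOL2 reader/writer handles the MOLECULE/ATOM/BOND record subset
and keeps any partial-charge column exactly as found in the file; SDF records
are parsed through RDKit.  Radii come from a named, packaged table (Bondi by
default) and partial charges either from the file, from a Gasteiger
calculation, or are zeroed for pure-shape work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "ParseError",
    "read_molecule",
    "read_molecules",
    "write_mol2",
    "load_radii_table",
    "assign_radii",
    "ensure_charges",
]


class ParseError(ValueError):
    """Raised when a structure record cannot be interpreted."""


@dataclass
class Atom:
    """One atom: 0-based index, element symbol, position in Angstrom."""

    index: int
    element: str
    position: np.ndarray
    vdw_radius: float | None = None
    partial_charge: float | None = None
    name: str = ""
    sybyl_type: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index}: position must be a finite 3-vector")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"atom {self.index}: vdw_radius must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class Bond:
    """Unordered atom-index pair with a Tripos-style order label."""

    a: int
    b: int
    order: str = "1"

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-bond on atom {self.a}")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class Molecule:
    """Atoms plus bonds; the chemical input to fragmentation and surfacing."""

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    source_format: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(f"bond {bond.pair} references a missing atom")
            if bond.pair in seen:
                raise ValueError(f"duplicate bond {bond.pair}")
            seen.add(bond.pair)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        if any(a.vdw_radius is None for a in self.atoms):
            raise ValueError("radii not assigned; call assign_radii first")
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        if any(a.partial_charge is None for a in self.atoms):
            raise ValueError("charges not assigned; call ensure_charges first")
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def has_charges(self) -> bool:
        return all(a.partial_charge is not None for a in self.atoms)

    def heavy_indices(self) -> list[int]:
        return [a.index for a in self.atoms if not a.is_hydrogen]

    def heavy_bonds(self) -> list[tuple[int, int]]:
        return [
            b.pair
            for b in self.bonds
            if not (self.atoms[b.a].is_hydrogen or self.atoms[b.b].is_hydrogen)
        ]


# ---------------------------------------------------------------------------
# MOL2
# ---------------------------------------------------------------------------

def _element_from_sybyl(sybyl_type: str) -> str:
    sym = sybyl_type.split(".")[0]
    if len(sym) > 1:
        sym = sym[0].upper() + sym[1:].lower()
    return sym


def _split_mol2_records(text: str) -> list[list[str]]:
    records: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        if line.strip() == "@<TRIPOS>MOLECULE":
            current = [line]
            records.append(current)
        elif current is not None:
            current.append(line)
    return records


def _parse_mol2_record(lines: list[str], where: str) -> Molecule:
    sections: dict[str, list[str]] = {}
    name = None
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("@<TRIPOS>"):
            name = stripped[len("@<TRIPOS>") :]
            sections.setdefault(name, [])
        elif name is not None and stripped and not stripped.startswith("#"):
            sections[name].append(stripped)

    mol_lines = sections.get("MOLECULE", [])
    if not mol_lines:
        raise ParseError(f"{where}: missing MOLECULE section")
    mol_id = mol_lines[0].strip() or "unnamed"
    charge_type = mol_lines[3].strip() if len(mol_lines) > 3 else "NO_CHARGES"

    atoms: list[Atom] = []
    for row in sections.get("ATOM", []):
        fields = row.split()
        if len(fields) < 6:
            raise ParseError(f"{where} ({mol_id}): short ATOM line: {row!r}")
        try:
            pos = np.array([float(fields[2]), float(fields[3]), float(fields[4])])
        except ValueError as exc:
            raise ParseError(f"{where} ({mol_id}): bad coordinates: {row!r}") from exc
        charge = None
        if len(fields) >= 9 and charge_type != "NO_CHARGES":
            try:
                charge = float(fields[8])
            except ValueError as exc:
                raise ParseError(f"{where} ({mol_id}): bad charge field: {row!r}") from exc
        atoms.append(
            Atom(
                index=len(atoms),
                element=_element_from_sybyl(fields[5]),
                position=pos,
                partial_charge=charge,
                name=fields[1],
                sybyl_type=fields[5],
            )
        )
    if not atoms:
        raise ParseError(f"{where} ({mol_id}): no atoms")

    bonds: list[Bond] = []
    for row in sections.get("BOND", []):
        fields = row.split()
        if len(fields) < 4:
            raise ParseError(f"{where} ({mol_id}): short BOND line: {row!r}")
        try:
            a, b = int(fields[1]) - 1, int(fields[2]) - 1
        except ValueError as exc:
            raise ParseError(f"{where} ({mol_id}): bad BOND indices: {row!r}") from exc
        bonds.append(Bond(a, b, order=fields[3]))

    try:
        return Molecule(mol_id, atoms, bonds, source_format="mol2")
    except ValueError as exc:
        raise ParseError(f"{where} ({mol_id}): {exc}") from exc


def write_mol2(molecules: Molecule | list[Molecule], path: str | Path) -> None:
    """Write one or more molecules as a (multi-record) Tripos MOL2 file."""
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    out: list[str] = []
    for mol in molecules:
        charged = mol.has_charges
        out.append("@<TRIPOS>MOLECULE")
        out.append(mol.id)
        out.append(f"{len(mol.atoms)} {len(mol.bonds)} 0 0 0")
        out.append("SMALL")
        out.append("USER_CHARGES" if charged else "NO_CHARGES")
        out.append("@<TRIPOS>ATOM")
        for a in mol.atoms:
            sybyl = a.sybyl_type or a.element
            nm = a.name or f"{a.element}{a.index + 1}"
            row = (
                f"{a.index + 1:>4} {nm:<6} "
                f"{a.position[0]:>10.4f} {a.position[1]:>10.4f} {a.position[2]:>10.4f} "
                f"{sybyl:<6} 1 RES1"
            )
            if charged:
                row += f" {a.partial_charge:>10.6f}"
            out.append(row)
        out.append("@<TRIPOS>BOND")
        for i, b in enumerate(mol.bonds):
            out.append(f"{i + 1:>4} {b.a + 1:>4} {b.b + 1:>4} {b.order}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# SDF (through RDKit)
# ---------------------------------------------------------------------------

_TRIPOS_ORDER = {"1": 1.0, "2": 2.0, "3": 3.0, "am": 1.0, "ar": 1.5, "du": 1.0, "un": 1.0}


def _parse_sdf(path: Path) -> list[Molecule]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    molecules: list[Molecule] = []
    for i, rd in enumerate(supplier):
        if rd is None:
            raise ParseError(f"{path}: SDF record {i + 1} failed to parse")
        if rd.GetNumConformers() == 0:
            raise ParseError(f"{path}: SDF record {i + 1} has no coordinates")
        conf = rd.GetConformer()
        pos = conf.GetPositions()
        if not conf.Is3D() and np.allclose(pos[:, 2], 0.0) and rd.GetNumAtoms() > 3:
            raise ParseError(
                f"{path}: SDF record {i + 1} carries 2D coordinates; "
                "3D structures are required"
            )
        atoms = [
            Atom(index=j, element=a.GetSymbol(), position=pos[j])
            for j, a in enumerate(rd.GetAtoms())
        ]
        order_names = {1.0: "1", 2.0: "2", 3.0: "3", 1.5: "ar"}
        bonds = [
            Bond(
                b.GetBeginAtomIdx(),
                b.GetEndAtomIdx(),
                order=order_names.get(b.GetBondTypeAsDouble(), "1"),
            )
            for b in rd.GetBonds()
        ]
        mol_id = rd.GetProp("_Name") if rd.HasProp("_Name") and rd.GetProp("_Name") else f"sdf_{i + 1}"
        molecules.append(Molecule(mol_id, atoms, bonds, source_format="sdf"))
    if not molecules:
        raise ParseError(f"{path}: empty SDF file")
    return molecules


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_molecules(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read every record of a MOL2 or SDF file.

    ``format`` is inferred from the file suffix when not given.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"mol2": "mol2", "sdf": "sdf", "sd": "sdf", "mol": "sdf"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    if format == "mol2":
        records = _split_mol2_records(path.read_text())
        if not records:
            raise ParseError(f"{path}: no MOL2 records found")
        return [
            _parse_mol2_record(rec, f"{path} record {i + 1}")
            for i, rec in enumerate(records)
        ]
    if format == "sdf":
        return _parse_sdf(path)
    raise ValueError(f"unknown format {format!r}; expected 'mol2' or 'sdf'")


def read_molecule(path: str | Path, format: str | None = None) -> Molecule:
    """Read the first (or only) molecule of a structure file."""
    return read_molecules(path, format)[0]


# ---------------------------------------------------------------------------
# Radii and charges
# ---------------------------------------------------------------------------

def load_radii_table(name: str = "bondi") -> dict[str, float]:
    """Load a named van der Waals radii table packaged with fragsig."""
    ref = resources.files("fragsig").joinpath(f"data/{name}_radii.txt")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"unknown radii table {name!r}") from exc
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            element, radius = line.split()
            table[element] = float(radius)
    return table


def assign_radii(mol: Molecule, table: str | dict[str, float] = "bondi") -> Molecule:
    """Return a copy of ``mol`` with van der Waals radii filled in."""
    radii = load_radii_table(table) if isinstance(table, str) else table
    missing = sorted({a.element for a in mol.atoms} - radii.keys())
    if missing:
        raise ValueError(f"no van der Waals radius for element(s): {', '.join(missing)}")
    atoms = [replace(a, vdw_radius=radii[a.element]) for a in mol.atoms]
    return Molecule(mol.id, atoms, list(mol.bonds), mol.source_format)


def _gasteiger_charges(mol: Molecule) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import rdPartialCharges

    rw = Chem.RWMol()
    for a in mol.atoms:
        rw.AddAtom(Chem.Atom(a.element))
    order = {
        "1": Chem.BondType.SINGLE,
        "2": Chem.BondType.DOUBLE,
        "3": Chem.BondType.TRIPLE,
        "am": Chem.BondType.SINGLE,
        "ar": Chem.BondType.AROMATIC,
    }
    for b in mol.bonds:
        rw.AddBond(b.a, b.b, order.get(b.order, Chem.BondType.SINGLE))
    rd = rw.GetMol()
    try:
        Chem.SanitizeMol(rd)
        rdPartialCharges.ComputeGasteigerCharges(rd)
    except Exception as exc:  # noqa: BLE001 - surface RDKit failures uniformly
        raise ValueError(
            f"Gasteiger charge calculation failed for {mol.id!r}: {exc}"
        ) from exc
    charges = np.array([a.GetDoubleProp("_GasteigerCharge") for a in rd.GetAtoms()])
    if not np.all(np.isfinite(charges)):
        raise ValueError(f"Gasteiger charges not finite for {mol.id!r}")
    return charges


def ensure_charges(mol: Molecule, method: str = "keep-imported") -> Molecule:
    """Return a copy of ``mol`` in which every atom has a finite partial charge.

    ``keep-imported`` insists on file-supplied charges, ``gasteiger`` computes
    Gasteiger partial charges, and ``zero`` nulls the electrostatics so that
    every downstream potential is identically zero.
    """
    if method == "keep-imported":
        if not mol.has_charges:
            raise ValueError(
                f"{mol.id!r} carries no imported charges; use method='gasteiger' "
                "or method='zero'"
            )
        return mol
    if method in ("gasteiger", "gasteiger-like"):
        values = _gasteiger_charges(mol)
    elif method == "zero":
        values = np.zeros(len(mol.atoms))
    else:
        raise ValueError(f"unknown charge method {method!r}")
    atoms = [replace(a, partial_charge=float(q)) for a, q in zip(mol.atoms, values)]
    return Molecule(mol.id, atoms, list(mol.bonds), mol.source_format)
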
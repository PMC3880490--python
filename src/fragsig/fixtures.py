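"""Deterministic toy inputs: idealized molecules, analytic meshes, synthetic
signatures.

Toy molecules are built from idealized bond lengths and angles (planar rings,
zig-zag chains, out-of-plane hydrogens) — good enough geometry for surface
and ray-trace work without any conformer generation.  They carry small preset
partial charges (+0.06 e per hydrogen, compensated on the bonded heavy atom)
so electrostatic descriptors are nonzero yet exactly neutral overall.

Analytic meshes (icosphere, subdivided cube) provide geometric oracles for
the ray-trace: the mean chord of an ergodic interior trace equals 4V/S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chemio import Atom, Bond, Molecule
from .signatures import (
    FragmentSignature,
    Histogram1D,
    MoleculeSignature,
    SignatureParams,
)
from .surface import CONTACT, TriSurface

__all__ = [
    "FixtureSpec",
    "make_sphere_mesh",
    "make_box_mesh",
    "make_toy_molecule",
    "make_toy_library",
    "make_synthetic_signature",
    "TOY_MOLECULES",
    "EXPECTED_FRAGMENTS",
]

H_CHARGE = 0.06  # preset charge per hydrogen, elementary charge units
CC = 1.50  # sp3 C-C bond, Angstrom
CC_AR = 1.40  # aromatic C-C
CH = 1.09  # C-H

# expected automatic fragment counts; doubles as documentation of the rules
EXPECTED_FRAGMENTS = {
    "methane": 1,  # acyclic: single fragment
    "benzene": 1,  # one ring system
    "toluene": 1,  # methyl (1 heavy atom <= 5) subsumed into the ring
    "biphenyl": 2,  # two ring systems joined by a bond
    "naphthalene": 1,  # fused rings merge
    "decalin": 1,  # fused (saturated) rings merge
    "hexylbenzene": 2,  # hexyl chain: 6 heavy atoms > 5, kept separate
    "diphenylethane": 3,  # bridge borders two ring systems
    "tetracycle": 1,  # linearly fused four-ring system
}
TOY_MOLECULES = tuple(EXPECTED_FRAGMENTS)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a fixture; equal specs always generate identical output."""

    name: str
    radius: float = 1.0
    side: float = 10.0
    fragments: int = 1
    seed: int = 0


# ---------------------------------------------------------------------------
# Molecule builder
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self) -> None:
        self.elements: list[str] = []
        self.positions: list[np.ndarray] = []
        self.bonds: list[tuple[int, int, str]] = []

    def add(self, element: str, pos) -> int:
        self.elements.append(element)
        self.positions.append(np.asarray(pos, dtype=float))
        return len(self.elements) - 1

    def bond(self, a: int, b: int, order: str = "1") -> None:
        self.bonds.append((a, b, order))

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def add_h_planar(self, c: int) -> int:
        """One in-plane hydrogen pointing away from the neighbour centroid."""
        nb = self.neighbors(c)
        direction = self.positions[c] - np.mean([self.positions[j] for j in nb], axis=0)
        direction /= np.linalg.norm(direction)
        h = self.add("H", self.positions[c] + CH * direction)
        self.bond(c, h)
        return h

    def add_h_out_of_plane(self, c: int, n_h: int) -> None:
        """Hydrogens straight out of the xy construction plane (and, for a
        terminal CH3, one extra in-plane)."""
        if n_h >= 1:
            h = self.add("H", self.positions[c] + np.array([0.0, 0.0, CH]))
            self.bond(c, h)
        if n_h >= 2:
            h = self.add("H", self.positions[c] + np.array([0.0, 0.0, -CH]))
            self.bond(c, h)
        if n_h >= 3:
            self.add_h_planar(c)

    def saturate_ring_carbons(self, aromatic: bool) -> None:
        """Give each ring carbon its hydrogens (1 in-plane if aromatic,
        CH2/CH pattern out of plane if saturated)."""
        n_heavy = len(self.elements)
        for c in range(n_heavy):
            if self.elements[c] != "C":
                continue
            deg = len(self.neighbors(c))
            if aromatic:
                if deg == 2:
                    self.add_h_planar(c)
            else:
                self.add_h_out_of_plane(c, max(0, 4 - deg) if deg >= 2 else 0)

    def to_molecule(self, mol_id: str) -> Molecule:
        charges = np.zeros(len(self.elements))
        for a, b, _ in self.bonds:
            for h, heavy in ((a, b), (b, a)):
                if self.elements[h] == "H" and self.elements[heavy] != "H":
                    charges[h] = H_CHARGE
                    charges[heavy] -= H_CHARGE
        atoms = [
            Atom(index=i, element=el, position=pos, partial_charge=float(q))
            for i, (el, pos, q) in enumerate(zip(self.elements, self.positions, charges))
        ]
        bonds = [Bond(a, b, order) for a, b, order in self.bonds]
        return Molecule(mol_id, atoms, bonds, source_format="fixture")


def _hexagon(center: np.ndarray, phase_deg: float = 30.0) -> list[np.ndarray]:
    return [
        center
        + CC_AR
        * np.array(
            [math.cos(math.radians(phase_deg + 60 * k)), math.sin(math.radians(phase_deg + 60 * k)), 0.0]
        )
        for k in range(6)
    ]


def _acene(n_rings: int, aromatic: bool, mol_id: str) -> Molecule:
    """Linearly fused hexagons sharing vertical edges (benzene for n=1)."""
    b = _Builder()
    index_of: dict[tuple[int, int], int] = {}
    spacing = 2.0 * CC_AR * math.cos(math.radians(30))
    for ring in range(n_rings):
        center = np.array([spacing * ring, 0.0, 0.0])
        ring_idx = []
        for p in _hexagon(center):
            key = (round(p[0] * 1000), round(p[1] * 1000))
            if key not in index_of:
                index_of[key] = b.add("C", p)
            ring_idx.append(index_of[key])
        for k in range(6):
            a, c = ring_idx[k], ring_idx[(k + 1) % 6]
            if (a, c) not in {(x, y) for x, y, _ in b.bonds} and (c, a) not in {
                (x, y) for x, y, _ in b.bonds
            }:
                order = "1"
                if aromatic and n_rings == 1:
                    order = "2" if k % 2 == 0 else "1"  # kekule alternation
                b.bond(a, c, order)
    b.saturate_ring_carbons(aromatic)
    return b.to_molecule(mol_id)


def _alkane_chain(b: _Builder, n: int, start: np.ndarray, first_bond_to: int | None) -> list[int]:
    """Zig-zag carbon chain in the xy plane, returning the carbon indices."""
    idx = []
    for i in range(n):
        pos = start + np.array([1.25 * i, 0.44 * (i % 2), 0.0])
        c = b.add("C", pos)
        if idx:
            b.bond(idx[-1], c)
        elif first_bond_to is not None:
            b.bond(first_bond_to, c)
        idx.append(c)
    return idx


def _alkane(n: int, mol_id: str) -> Molecule:
    b = _Builder()
    idx = _alkane_chain(b, n, np.zeros(3), None)
    if n == 1:
        t = 1.0 / math.sqrt(3.0)
        for sign in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
            h = b.add("H", b.positions[idx[0]] + CH * t * np.array(sign, dtype=float))
            b.bond(idx[0], h)
    else:
        for i, c in enumerate(idx):
            n_h = 3 if i in (0, len(idx) - 1) else 2
            b.add_h_out_of_plane(c, n_h)
    return b.to_molecule(mol_id)


def _cycloalkane(n: int, mol_id: str) -> Molecule:
    b = _Builder()
    r = CC / (2.0 * math.sin(math.pi / n))
    idx = [
        b.add("C", np.array([r * math.cos(2 * math.pi * k / n), r * math.sin(2 * math.pi * k / n), 0.0]))
        for k in range(n)
    ]
    for k in range(n):
        b.bond(idx[k], idx[(k + 1) % n])
    for c in idx:
        b.add_h_out_of_plane(c, 2)
    return b.to_molecule(mol_id)


def _alkylbenzene(chain: int, mol_id: str) -> Molecule:
    mol = _acene(1, True, "ring")
    b = _Builder()
    for atom in mol.atoms:
        b.add(atom.element, atom.position)
    for bond in mol.bonds:
        b.bond(bond.a, bond.b, bond.order)
    # replace the in-plane hydrogen of ring carbon 0 by the chain
    h0 = next(h for h in b.neighbors(0) if b.elements[h] == "H")
    anchor = b.positions[0]
    direction = b.positions[h0] - anchor
    direction /= np.linalg.norm(direction)
    b.positions[h0] = anchor + CC * direction  # hydrogen becomes the first carbon
    b.elements[h0] = "C"
    chain_idx = [h0]
    if chain > 1:
        start = b.positions[h0] + np.array([1.25, 0.44, 0.0])
        chain_idx += _alkane_chain(b, chain - 1, start, h0)
    for i, c in enumerate(chain_idx):
        b.add_h_out_of_plane(c, 3 if i == len(chain_idx) - 1 else 2)
    return b.to_molecule(mol_id)


def _xylene(positions: tuple[int, int], mol_id: str) -> Molecule:
    mol = _acene(1, True, "ring")
    b = _Builder()
    for atom in mol.atoms:
        b.add(atom.element, atom.position)
    for bond in mol.bonds:
        b.bond(bond.a, bond.b, bond.order)
    for ring_c in positions:
        h = next(h for h in b.neighbors(ring_c) if b.elements[h] == "H")
        anchor = b.positions[ring_c]
        direction = b.positions[h] - anchor
        direction /= np.linalg.norm(direction)
        b.positions[h] = anchor + CC * direction
        b.elements[h] = "C"
        b.add_h_out_of_plane(h, 3)
    return b.to_molecule(mol_id)


def _biphenyl(mol_id: str) -> Molecule:
    b = _Builder()
    gap = CC  # inter-ring bond
    for side in (-1, 1):
        center = np.array([side * (CC_AR + gap / 2.0), 0.0, 0.0])
        ring = _hexagon(center, phase_deg=0.0 if side < 0 else 180.0)
        idx = [b.add("C", p) for p in ring]
        for k in range(6):
            b.bond(idx[k], idx[(k + 1) % 6], "2" if k % 2 == 0 else "1")
    # attachment carbons sit at +/- gap/2 on the x axis
    att = [
        i
        for i, p in enumerate(b.positions)
        if abs(abs(p[0]) - gap / 2.0) < 1e-6 and abs(p[1]) < 1e-6
    ]
    b.bond(att[0], att[1], "1")
    b.saturate_ring_carbons(True)
    return b.to_molecule(mol_id)


def _diphenylethane(mol_id: str) -> Molecule:
    b = _Builder()
    c1 = b.add("C", [-0.75, 0.0, 0.0])
    c2 = b.add("C", [0.75, 0.0, 0.0])
    b.bond(c1, c2)
    for bridge_c, side in ((c1, -1), (c2, 1)):
        a0 = b.add("C", [side * (0.75 + CC), 0.0, 0.0])
        b.bond(bridge_c, a0)
        center = np.asarray(b.positions[a0]) + np.array([side * CC_AR, 0.0, 0.0])
        ring = _hexagon(center, phase_deg=180.0 if side < 0 else 0.0)
        idx = []
        for p in ring:
            if np.linalg.norm(p - b.positions[a0]) < 1e-6:
                idx.append(a0)
            else:
                idx.append(b.add("C", p))
        for k in range(6):
            b.bond(idx[k], idx[(k + 1) % 6], "2" if k % 2 == 0 else "1")
    b.add_h_out_of_plane(c1, 2)
    b.add_h_out_of_plane(c2, 2)
    b.saturate_ring_carbons(True)
    return b.to_molecule(mol_id)


def make_toy_molecule(name: str) -> Molecule:
    """Named toy molecule with idealized geometry and preset charges."""
    builders = {
        "methane": lambda: _alkane(1, "methane"),
        "benzene": lambda: _acene(1, True, "benzene"),
        "toluene": lambda: _alkylbenzene(1, "toluene"),
        "biphenyl": lambda: _biphenyl("biphenyl"),
        "naphthalene": lambda: _acene(2, True, "naphthalene"),
        "decalin": lambda: _acene(2, False, "decalin"),
        "hexylbenzene": lambda: _alkylbenzene(6, "hexylbenzene"),
        "diphenylethane": lambda: _diphenylethane("diphenylethane"),
        "tetracycle": lambda: _acene(4, True, "tetracycle"),
    }
    if name not in builders:
        raise ValueError(f"unknown toy molecule {name!r}; known: {sorted(builders)}")
    return builders[name]()


def make_toy_library(size: int = 30) -> list[Molecule]:
    """A deterministic library of distinct toy molecules (at most 30)."""
    library: list[Molecule] = [make_toy_molecule(n) for n in TOY_MOLECULES]
    library += [_alkane(n, f"alkane_C{n}") for n in (4, 5, 6, 7, 8, 9, 12)]
    library += [_cycloalkane(n, f"cycloalkane_C{n}") for n in (5, 6, 7, 8, 10)]
    library += [_alkylbenzene(n, f"{p}benzene") for n, p in ((2, "ethyl"), (3, "propyl"), (4, "butyl"))]
    library += [
        _xylene(p, f"{nm}-xylene")
        for p, nm in (((0, 3), "para"), ((0, 2), "meta"), ((0, 1), "ortho"))
    ]
    library += [
        _acene(3, True, "anthracene"),
        _acene(3, False, "perhydroanthracene"),
        _acene(5, True, "pentacycle"),
    ]
    if size > len(library):
        raise ValueError(f"toy library holds at most {len(library)} molecules")
    return library[:size]


# ---------------------------------------------------------------------------
# Analytic meshes
# ---------------------------------------------------------------------------

def _pseudo_atom_surface(vertices: np.ndarray, faces: np.ndarray) -> TriSurface:
    surf = TriSurface(vertices=vertices, faces=faces)
    if surf.volume < 0:
        surf = TriSurface(vertices=vertices, faces=faces[:, ::-1].copy())
    surf.face_class = np.full(surf.n_faces, CONTACT, dtype=np.int8)
    atoms = np.full((surf.n_faces, 3), -1, dtype=np.int64)
    atoms[:, 0] = 0
    surf.face_atoms = atoms
    surf.primary_atom = np.zeros(surf.n_faces, dtype=np.int64)
    surf.vertex_mep = np.zeros(len(vertices))
    return surf


def make_sphere_mesh(R: float, subdivisions: int = 4) -> TriSurface:
    """Closed icosphere of radius R; all elements contact, one pseudo-atom."""
    if R <= 0:
        raise ValueError("radius must be positive")
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=R)
    return _pseudo_atom_surface(np.asarray(mesh.vertices), np.asarray(mesh.faces))


def make_box_mesh(L: float, resolution: int = 4) -> TriSurface:
    """Closed axis-aligned cube of side L, each face subdivided 4:1
    ``resolution`` times (mean-chord oracle: 4V/S = 2L/3)."""
    if L <= 0:
        raise ValueError("side must be positive")
    import trimesh

    mesh = trimesh.creation.box(extents=(L, L, L))
    for _ in range(resolution):
        mesh = mesh.subdivide()
    return _pseudo_atom_surface(np.asarray(mesh.vertices), np.asarray(mesh.faces))


# ---------------------------------------------------------------------------
# Synthetic signatures
# ---------------------------------------------------------------------------

def make_synthetic_signature(
    m: int,
    topology: str = "path",
    bins: int = 20,
    seed: int = 0,
    molecule_id: str | None = None,
) -> MoleculeSignature:
    """Random normalized per-fragment 1D histograms with a declared topology.

    Suitable as direct input to the mapping and prefilter machinery; no 2D
    descriptors or inter-fragment histograms are attached.
    """
    if m < 1:
        raise ValueError("fragment count must be >= 1")
    if topology == "path":
        edges = frozenset((i, i + 1) for i in range(m - 1))
    elif topology == "star":
        edges = frozenset((0, i) for i in range(1, m))
    else:
        raise ValueError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)
    params = SignatureParams()
    fragments = []
    for f in range(m):
        total = int(rng.integers(2000, 20001))
        p = rng.dirichlet(np.ones(bins))
        counts = rng.multinomial(total, p)
        fragments.append(
            FragmentSignature(
                fragment=f,
                hist1d=Histogram1D(params.bin_width, counts),
                hist2d={},
                count=int(counts.sum()),
            )
        )
    return MoleculeSignature(
        molecule_id=molecule_id or f"synthetic_{topology}_{m}_{seed}",
        n_fragments=m,
        heavy_counts=tuple([6] * m),
        adjacency=edges,
        fragments=fragments,
        inter_1d={},
        inter_2d={},
        total_segments=sum(fs.count for fs in fragments),
        params=params,
    )
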
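"""Ring-system fragmentation of the heavy-atom molecular graph.

A molecule is partitioned into fragments built around its ring systems: ring
closures (one per independent cycle) are found with a deterministic spanning
subtree, the cycles through each closure are grown into ring systems (fused
and spiro systems merge), and the remaining acyclic components are either kept
as fragments of their own or subsumed into a neighbouring ring system
depending on their size and on how many ring systems they touch.  Hydrogens
always follow the heavy atom they are bonded to.  A user-supplied per-atom
assignment file can replace the automatic procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .chemio import Molecule

__all__ = [
    "MolGraph",
    "Fragmentation",
    "mol_graph",
    "find_ring_closures",
    "grow_ring_systems",
    "assign_fragments",
    "load_fragment_assignment",
    "fragment_adjacency",
]

# Acyclic components bordering one ring system are kept as separate fragments
# only when they have more than this many heavy atoms.
MAX_SUBSUMED_HEAVY_ATOMS = 5


@dataclass(frozen=True)
class MolGraph:
    """Simple graph of heavy atoms (vertices) and heavy-atom bonds (edges)."""

    vertices: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        vs = set(self.vertices)
        for a, b in self.edges:
            if a == b or a not in vs or b not in vs:
                raise ValueError(f"invalid edge ({a}, {b})")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    @property
    def cyclomatic_number(self) -> int:
        g = self.to_networkx()
        return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


def mol_graph(mol: Molecule) -> MolGraph:
    """Heavy-atom graph of a molecule (hydrogens are dropped)."""
    edges = tuple(sorted(tuple(sorted(e)) for e in mol.heavy_bonds()))
    return MolGraph(tuple(sorted(mol.heavy_indices())), edges)


def find_ring_closures(
    graph: MolGraph,
    seed: tuple[int, int] | None = None,
    order: str = "index",
) -> set[tuple[int, int]]:
    """Bonds left over after growing a maximal spanning subtree.

    The subtree is grown depth-first from ``seed`` (default: the lowest-index
    edge), taking neighbours in ascending (``order='index'``) or descending
    index order.  The returned edges are the ring closures; their number
    always equals the cyclomatic number of the graph, although which specific
    edges are returned depends on the traversal.
    """
    if not graph.edges:
        return set()
    edges = {tuple(sorted(e)) for e in graph.edges}
    if seed is None:
        seed = min(edges)
    else:
        seed = tuple(sorted(seed))
        if seed not in edges:
            raise ValueError(f"seed {seed} is not an edge of the graph")
    if order not in ("index", "reverse"):
        raise ValueError(f"unknown traversal order {order!r}")
    reverse = order == "reverse"

    adjacency: dict[int, list[int]] = {v: [] for v in graph.vertices}
    for a, b in edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    for v in adjacency:
        adjacency[v].sort(reverse=reverse)

    tree_edges: set[tuple[int, int]] = set()
    in_tree = {seed[0], seed[1]}
    tree_edges.add(seed)
    stack = [seed[1], seed[0]]
    while stack:
        v = stack.pop()
        for w in adjacency[v]:
            if w not in in_tree:
                in_tree.add(w)
                tree_edges.add(tuple(sorted((v, w))))
                stack.append(w)
    # Other connected components (the seed only roots one of them).
    for v in sorted(adjacency):
        if v not in in_tree:
            in_tree.add(v)
            stack = [v]
            while stack:
                u = stack.pop()
                for w in adjacency[u]:
                    if w not in in_tree:
                        in_tree.add(w)
                        tree_edges.add(tuple(sorted((u, w))))
                        stack.append(w)
    return edges - tree_edges


def grow_ring_systems(
    graph: MolGraph, closures: set[tuple[int, int]]
) -> list[set[int]]:
    """Union the cycles through each ring closure into ring systems.

    The atoms reachable from one end of a closure to the other along
    non-self-intersecting paths form one ring system; systems that share an
    atom (fused or spiro arrangements) are merged so every ring atom belongs
    to exactly one system.  Returned sets are ordered by their lowest atom.
    """
    if not closures:
        return []
    g = graph.to_networkx()
    closures = {tuple(sorted(c)) for c in closures}
    for a, b in closures:
        if not g.has_edge(a, b):
            raise ValueError(f"closure ({a}, {b}) is not an edge of the graph")

    # The union of simple paths joining the two ends of a closure is exactly
    # the biconnected component holding that edge.
    systems: list[set[int]] = []
    for component in nx.biconnected_components(g):
        if len(component) < 3:
            continue  # bridge component: not a cycle
        if any(a in component and b in component for a, b in closures):
            systems.append(set(component))

    # Merge systems sharing atoms (spiro junctions).
    merged: list[set[int]] = []
    for system in systems:
        absorbed = set(system)
        rest = []
        for existing in merged:
            if existing & absorbed:
                absorbed |= existing
            else:
                rest.append(existing)
        merged = rest + [absorbed]
    return sorted(merged, key=min)


@dataclass
class Fragmentation:
    """Total partition of a molecule's atoms into numbered fragments."""

    atom_fragment: np.ndarray  # fragment id per atom, hydrogens included
    heavy_counts: tuple[int, ...]  # heavy atoms per fragment
    adjacency: frozenset[tuple[int, int]]  # fragment pairs joined by >=1 bond

    def __post_init__(self) -> None:
        self.atom_fragment = np.asarray(self.atom_fragment, dtype=np.int64)
        n = self.n_fragments
        if n != len(self.heavy_counts):
            raise ValueError("heavy_counts length does not match fragment count")
        for a, b in self.adjacency:
            if not (0 <= a < b < n):
                raise ValueError(f"bad adjacency pair ({a}, {b})")

    @property
    def n_fragments(self) -> int:
        return int(self.atom_fragment.max()) + 1

    def atoms_of(self, fragment: int) -> np.ndarray:
        return np.flatnonzero(self.atom_fragment == fragment)

    def summary(self) -> dict:
        return {
            "n_fragments": self.n_fragments,
            "heavy_counts": list(self.heavy_counts),
            "adjacency": sorted(list(p) for p in self.adjacency),
        }


def fragment_adjacency(
    atom_fragment: np.ndarray, mol: Molecule
) -> frozenset[tuple[int, int]]:
    """Fragment pairs (a, b), a < b, connected by at least one bond."""
    pairs = set()
    for bond in mol.bonds:
        fa, fb = int(atom_fragment[bond.a]), int(atom_fragment[bond.b])
        if fa != fb:
            pairs.add((min(fa, fb), max(fa, fb)))
    return frozenset(pairs)


def _finalize(raw_groups: list[set[int]], mol: Molecule) -> Fragmentation:
    """Attach hydrogens, renumber by lowest member atom, build adjacency."""
    atom_fragment = np.full(len(mol.atoms), -1, dtype=np.int64)
    for gid, group in enumerate(raw_groups):
        for atom in group:
            atom_fragment[atom] = gid

    neighbor_lists: dict[int, list[int]] = {a.index: [] for a in mol.atoms}
    for bond in mol.bonds:
        neighbor_lists[bond.a].append(bond.b)
        neighbor_lists[bond.b].append(bond.a)

    for atom in mol.atoms:
        if atom.is_hydrogen and atom_fragment[atom.index] < 0:
            heavy = [w for w in neighbor_lists[atom.index] if not mol.atoms[w].is_hydrogen]
            if heavy:
                atom_fragment[atom.index] = atom_fragment[heavy[0]]
    # Stray hydrogens with no heavy neighbour (H2 and the like) each keep the
    # fragment of any neighbour, else become their own group.
    for atom in mol.atoms:
        if atom_fragment[atom.index] < 0:
            assigned = [w for w in neighbor_lists[atom.index] if atom_fragment[w] >= 0]
            if assigned:
                atom_fragment[atom.index] = atom_fragment[assigned[0]]
            else:
                raw_groups.append({atom.index})
                atom_fragment[atom.index] = len(raw_groups) - 1

    # Renumber so fragment ids ascend with the lowest member atom index.
    first_atom = {}
    for idx, frag in enumerate(atom_fragment):
        first_atom.setdefault(int(frag), idx)
    relabel = {
        old: new for new, old in enumerate(sorted(first_atom, key=first_atom.get))
    }
    atom_fragment = np.array([relabel[int(f)] for f in atom_fragment], dtype=np.int64)

    n = len(relabel)
    heavy_counts = [0] * n
    for atom in mol.atoms:
        if not atom.is_hydrogen:
            heavy_counts[atom_fragment[atom.index]] += 1
    return Fragmentation(
        atom_fragment=atom_fragment,
        heavy_counts=tuple(heavy_counts),
        adjacency=fragment_adjacency(atom_fragment, mol),
    )


def assign_fragments(mol: Molecule) -> Fragmentation:
    """Automatic ring-system fragmentation.

    Ring systems seed the fragments.  Each remaining acyclic heavy-atom
    component either becomes its own fragment (it touches two or more ring
    systems, or touches one but has more than five heavy atoms) or is subsumed
    into the single ring system it touches.  A molecule without rings is a
    single fragment, which makes the descriptors degenerate to the global,
    non-fragment form.
    """
    if not mol.atoms:
        raise ValueError("empty molecule")
    graph = mol_graph(mol)
    systems = grow_ring_systems(graph, find_ring_closures(graph))
    ring_atoms = set().union(*systems) if systems else set()

    g = graph.to_networkx()
    nonring = g.subgraph([v for v in g if v not in ring_atoms])

    groups = [set(s) for s in systems]
    for component in nx.connected_components(nonring):
        component = set(component)
        touching = {
            i
            for i, system in enumerate(systems)
            if any(
                (g.has_edge(v, w) for w in system for v in component)
            )
        }
        if len(touching) == 1 and len(component) <= MAX_SUBSUMED_HEAVY_ATOMS:
            groups[touching.pop()] |= component
        else:
            groups.append(component)
    if not groups:  # single atom, no heavy bonds at all
        groups = [set(mol.heavy_indices() or [0])]
    return _finalize(groups, mol)


def load_fragment_assignment(path: str | Path, mol: Molecule) -> Fragmentation:
    """Read a custom per-atom assignment ("atom_index fragment_id", 1-based).

    Lines may carry ``#`` comments.  The assignment is honoured verbatim;
    hydrogens missing from the file inherit the fragment of their heavy
    neighbour, while an unassigned heavy atom is an error.
    """
    assignment: dict[int, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'atom_index fragment_id'")
        idx, frag = int(parts[0]) - 1, int(parts[1])
        if not 0 <= idx < len(mol.atoms):
            raise ValueError(
                f"{path}:{lineno}: atom index {idx + 1} outside molecule "
                f"of {len(mol.atoms)} atoms"
            )
        if frag < 0:
            raise ValueError(f"{path}:{lineno}: fragment id must be >= 0")
        assignment[idx] = frag

    missing = [
        a.index
        for a in mol.atoms
        if not a.is_hydrogen and a.index not in assignment
    ]
    if missing:
        raise ValueError(
            f"{path}: heavy atoms without fragment assignment: "
            f"{[i + 1 for i in missing]}"
        )
    groups: dict[int, set[int]] = {}
    for idx, frag in assignment.items():
        groups.setdefault(frag, set()).add(idx)
    raw_groups = [groups[k] for k in sorted(groups)]
    return _finalize(raw_groups, mol)
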
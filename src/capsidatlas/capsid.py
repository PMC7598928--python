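"""Capsid polyhedra, dual graphs, interface-type orbits and connectivity
pathways.

An icosahedral capsid built from 60*T identical (or quasi-equivalent) coat
protein subunits is abstracted as its *dual graph*: one vertex per subunit,
one edge per inter-subunit interface.  The proper icosahedral rotation group
(order 60) acts on this graph; interface *types* are the orbits of edges
under that action.  A *connectivity pathway* is a minimal set of interface
types whose edge union is a connected spanning subgraph — the combinatorial
skeleton any successful assembly must contain.

T = 1 construction.  Each icosahedron face carries three subunits, one per
corner; a subunit is the flag (face, vertex).  Within a face the three
subunits meet around the 3-fold axis; around each vertex five subunits form
the pentamer ring (5-fold); across each icosahedron edge one chirally chosen
trans pair forms the 2-fold dimer contact.  The resulting graph is the
skeleton of the snub dodecahedron: 60 vertices, degree 5, 150 edges, three
edge orbits.

T = 3 construction.  The Caspar-Klug (1,1) lattice triangulates the capsid
into 60 facets (the pentakis dodecahedron): 12 five-fold vertices (P, the
icosahedron vertices) and 20 six-fold vertices (H, the face centres).  Each
facet carries one A subunit at its P corner and B, C subunits at its two H
corners, so pentamers are all-A and hexamers alternate B/C.  The default
contact template keeps seven orbit classes: the three quasi-3-fold contacts
A-B, A-C, B-C inside a facet, the A-A pentamer contact, the B-C hexamer
contact across icosahedral (H-H) edges, the C-C dimer at the true 2-fold and
the A-B dimer at the quasi-2-fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import UnknownTypeError

PHI = (1 + 5 ** 0.5) / 2


# ---------------------------------------------------------------------------
# Icosahedron geometry and the proper rotation group
# ---------------------------------------------------------------------------

def icosahedron_vertices() -> np.ndarray:
    """The 12 vertices of a regular icosahedron (circumradius-normalized)."""
    verts = []
    for a, b in itertools.product((-1.0, 1.0), repeat=2):
        verts.append((0.0, a, b * PHI))
        verts.append((a, b * PHI, 0.0))
        verts.append((a * PHI, 0.0, b))
    arr = np.array(verts)
    return arr / np.linalg.norm(arr[0])


def icosahedron_faces(verts: np.ndarray) -> list[tuple[int, int, int]]:
    """The 20 faces as outward-oriented (counterclockwise) vertex triples."""
    n = len(verts)
    edge_len = np.min(
        [np.linalg.norm(verts[i] - verts[j]) for i in range(n) for j in range(i + 1, n)]
    )
    faces = []
    for i, j, k in itertools.combinations(range(n), 3):
        d = (np.linalg.norm(verts[i] - verts[j]),
             np.linalg.norm(verts[j] - verts[k]),
             np.linalg.norm(verts[i] - verts[k]))
        if np.allclose(d, edge_len, atol=1e-6):
            centroid = (verts[i] + verts[j] + verts[k]) / 3
            normal = np.cross(verts[j] - verts[i], verts[k] - verts[i])
            if np.dot(normal, centroid) < 0:
                faces.append((i, k, j))
            else:
                faces.append((i, j, k))
    assert len(faces) == 20
    return sorted(faces)


def rotation_group(verts: np.ndarray) -> list[np.ndarray]:
    """The 60 proper rotations of the icosahedron, generated by closure."""
    v0 = verts[0]
    # a face containing v0 for the 3-fold generator
    faces = icosahedron_faces(verts)
    f0 = next(f for f in faces if 0 in f)
    axis5 = v0 / np.linalg.norm(v0)
    c = (verts[f0[0]] + verts[f0[1]] + verts[f0[2]]) / 3
    axis3 = c / np.linalg.norm(c)

    def rot(axis: np.ndarray, angle: float) -> np.ndarray:
        from scipy.spatial.transform import Rotation
        return Rotation.from_rotvec(axis * angle).as_matrix()

    gens = [rot(axis5, 2 * np.pi / 5), rot(axis3, 2 * np.pi / 3)]

    def snap(M: np.ndarray) -> np.ndarray:
        # project back onto SO(3) to stop fp drift during closure
        U, _, Vt = np.linalg.svd(M)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
        return R

    group: list[np.ndarray] = [np.eye(3)]

    def known(M: np.ndarray) -> bool:
        return any(np.abs(M - G).max() < 1e-6 for G in group)

    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for M in frontier:
            for g in gens:
                P = snap(g @ M)
                if not known(P):
                    group.append(P)
                    nxt.append(P)
        frontier = nxt
    assert len(group) == 60, f"expected 60 rotations, got {len(group)}"
    return group


# ---------------------------------------------------------------------------
# Dual graphs
# ---------------------------------------------------------------------------

@dataclass
class DualGraph:
    """Capsid dual graph with its rotation-group action and edge typing.

    Attributes
    ----------
    T : int
        Triangulation number (1 or 3).
    graph : nx.Graph
        Nodes are subunit labels; node attribute ``chain`` gives the chain
        class ('A' for T=1; 'A'/'B'/'C' for T=3).
    positions : dict
        Representative 3-D point per subunit (equivariant under the group).
    rotations : list of (3,3) arrays
        The 60 proper icosahedral rotations.
    edge_type : dict
        frozenset({u, v}) -> interface-type label.
    type_annotations : dict
        type label -> human-readable axis-class annotation.
    construction_class : dict
        frozenset({u, v}) -> the construction rule that produced the edge.
    """

    T: int
    graph: nx.Graph
    positions: dict
    rotations: list
    edge_type: dict = field(default_factory=dict)
    type_annotations: dict = field(default_factory=dict)
    construction_class: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def types(self) -> list[str]:
        return sorted(set(self.edge_type.values()))

    def edges_of_type(self, label: str) -> list[frozenset]:
        if label not in set(self.edge_type.values()):
            raise UnknownTypeError(f"no interface type {label!r}")
        return sorted(
            (e for e, t in self.edge_type.items() if t == label),
            key=lambda e: tuple(sorted(e)),
        )

    def vertex_permutation(self, rotation: np.ndarray) -> dict:
        """The permutation of subunits induced by one rotation."""
        nodes = sorted(self.graph.nodes)
        pts = np.array([self.positions[n] for n in nodes])
        moved = pts @ rotation.T
        # match each moved point to the nearest original point
        d2 = ((moved[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        idx = np.argmin(d2, axis=1)
        if len(set(idx)) != len(nodes) or np.max(np.min(d2, axis=1)) > 1e-6:
            raise ValueError("rotation does not permute subunit positions")
        return {nodes[i]: nodes[idx[i]] for i in range(len(nodes))}


# --- T = 1 -----------------------------------------------------------------

def _build_t1() -> DualGraph:
    verts = icosahedron_vertices()
    faces = icosahedron_faces(verts)
    G = nx.Graph()
    positions = {}
    construction = {}

    def node(fi: int, vi: int) -> tuple:
        return (fi, vi)

    for fi, f in enumerate(faces):
        centroid = verts[list(f)].mean(axis=0)
        for vi in f:
            n = node(fi, vi)
            G.add_node(n, chain="A")
            positions[n] = 0.55 * verts[vi] + 0.45 * centroid

    def add(u, v, cls):
        G.add_edge(u, v)
        construction[frozenset((u, v))] = cls

    # 3-fold: within-face pairs
    for fi, f in enumerate(faces):
        for a, b in itertools.combinations(f, 2):
            add(node(fi, a), node(fi, b), "3f")

    # shared-edge bookkeeping: icosahedron edge -> the two adjacent faces
    edge_faces: dict[frozenset, list[int]] = {}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_faces.setdefault(frozenset((a, b)), []).append(fi)

    def head(fi: int, e: frozenset) -> int:
        """Second vertex of e in face fi's counterclockwise boundary."""
        f = faces[fi]
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if frozenset((a, b)) == e:
                return b
        raise ValueError("edge not on face")

    for e, (fa, fb) in edge_faces.items():
        va, vb = sorted(e)
        # 5-fold: same-vertex pairs across the shared edge
        add(node(fa, va), node(fb, va), "5f")
        add(node(fa, vb), node(fb, vb), "5f")
        # 2-fold: one chirally chosen trans pair (head-head)
        add(node(fa, head(fa, e)), node(fb, head(fb, e)), "2f")

    dg = DualGraph(T=1, graph=G, positions=positions,
                   rotations=rotation_group(verts),
                   construction_class=construction)
    return dg


# --- T = 3 -----------------------------------------------------------------

def _build_t3() -> DualGraph:
    verts = icosahedron_vertices()
    faces = icosahedron_faces(verts)
    face_centers = np.array([verts[list(f)].mean(axis=0) for f in faces])

    # facets of the pentakis dodecahedron: (P vertex, H face a, H face b),
    # with faces a, b consecutive counterclockwise around the P axis
    facets = []  # (vi, fa, fb)
    for vi in range(12):
        around = [fi for fi, f in enumerate(faces) if vi in f]
        axis = verts[vi] / np.linalg.norm(verts[vi])
        ref = face_centers[around[0]] - np.dot(face_centers[around[0]], axis) * axis
        ref = ref / np.linalg.norm(ref)
        perp = np.cross(axis, ref)

        def angle(fi: int) -> float:
            p = face_centers[fi] - np.dot(face_centers[fi], axis) * axis
            return float(np.arctan2(np.dot(p, perp), np.dot(p, ref)) % (2 * np.pi))

        ordered = sorted(around, key=angle)
        for i in range(5):
            facets.append((vi, ordered[i], ordered[(i + 1) % 5]))
    assert len(facets) == 60

    facet_index = {t: i for i, t in enumerate(sorted(facets))}
    facets = sorted(facets)

    G = nx.Graph()
    positions = {}
    construction = {}

    def corner_points(t: tuple) -> list[np.ndarray]:
        vi, fa, fb = t
        return [verts[vi], face_centers[fa], face_centers[fb]]

    CHAINS = ("A", "B", "C")  # P corner, first H corner, second H corner

    def node(ti: int, corner: int) -> tuple:
        return (ti, corner)

    for t in facets:
        ti = facet_index[t]
        pts = corner_points(t)
        for corner in range(3):
            n = node(ti, corner)
            G.add_node(n, chain=CHAINS[corner])
            w = [(0.60, 0.25, 0.15), (0.15, 0.60, 0.25), (0.25, 0.15, 0.60)][corner]
            positions[n] = w[0] * pts[0] + w[1] * pts[1] + w[2] * pts[2]

    def add(u, v, cls):
        G.add_edge(u, v)
        construction[frozenset((u, v))] = cls

    # quasi-3-fold: the three contacts inside a facet
    for t in facets:
        ti = facet_index[t]
        add(node(ti, 0), node(ti, 1), "AB_q3")
        add(node(ti, 0), node(ti, 2), "AC_q3")
        add(node(ti, 1), node(ti, 2), "BC_q3")

    # around each P vertex: consecutive facets share the pyramid edge (P, H)
    for vi in range(12):
        ring = sorted(t for t in facets if t[0] == vi)
        # order the ring by following fb -> fa chaining
        succ = {t[1]: t for t in ring}  # facet keyed by its first face
        ordered = [ring[0]]
        while len(ordered) < 5:
            ordered.append(succ[ordered[-1][2]])
        for i in range(5):
            t_prev = ordered[i]
            t_next = ordered[(i + 1) % 5]  # t_next.fa == t_prev.fb
            # A-A pentamer contact
            add(node(facet_index[t_prev], 0), node(facet_index[t_next], 0), "AA_5f")
            # A-B quasi-2-fold dimer: B of the later facet with A of the earlier
            add(node(facet_index[t_next], 1), node(facet_index[t_prev], 0), "AB_q2")

    # across each icosahedron (H-H) edge: the two facets sharing both faces
    hh: dict[frozenset, list[tuple]] = {}
    for t in facets:
        hh.setdefault(frozenset((t[1], t[2])), []).append(t)
    for e, pair in hh.items():
        assert len(pair) == 2
        t, u = pair
        ti, ui = facet_index[t], facet_index[u]
        # B-C hexamer contacts at the two shared H vertices
        # t = (v, fa, fb), u = (v', fb, fa): at fa t has B, u has C; at fb vice versa
        assert t[1] == u[2] and t[2] == u[1]
        add(node(ti, 1), node(ui, 2), "BC_6f")
        add(node(ti, 2), node(ui, 1), "BC_6f")
        # C-C dimer across the true 2-fold
        add(node(ti, 2), node(ui, 2), "CC_2f")

    dg = DualGraph(T=3, graph=G, positions=positions,
                   rotations=rotation_group(verts),
                   construction_class=construction)
    return dg


def build_capsid_polyhedron(T: int) -> DualGraph:
    """Build the dual graph of the T=1 or T=3 capsid polyhedron and type its
    edges by rotation-group orbit."""
    if T == 1:
        dg = _build_t1()
    elif T == 3:
        dg = _build_t3()
    else:
        raise UnknownTypeError(f"unsupported T number {T!r} (must be 1 or 3)")
    classify_interface_types(dg)
    return dg


# ---------------------------------------------------------------------------
# Interface types = edge orbits
# ---------------------------------------------------------------------------

def classify_interface_types(dg: DualGraph) -> dict:
    """Partition edges into orbits under the proper rotation group and assign
    stable canonical labels (2f/3f/5f for T=1, i1..i7 for T=3).

    Raises ValueError if any rotation fails to act by graph automorphisms.
    """
    perms = [dg.vertex_permutation(R) for R in dg.rotations]
    edges = sorted((frozenset(e) for e in dg.graph.edges), key=lambda e: tuple(sorted(e)))
    edge_set = set(edges)
    for p in perms:
        for e in edges:
            u, v = tuple(e)
            if frozenset((p[u], p[v])) not in edge_set:
                raise ValueError("group action does not preserve edges")

    orbit_of: dict[frozenset, int] = {}
    orbits: list[list[frozenset]] = []
    for e in edges:
        if e in orbit_of:
            continue
        k = len(orbits)
        members = set()
        for p in perms:
            u, v = tuple(e)
            members.add(frozenset((p[u], p[v])))
        for m in members:
            orbit_of[m] = k
        orbits.append(sorted(members, key=lambda x: tuple(sorted(x))))

    # canonical labels: T=1 named by axis class, T=3 numbered i1.. in
    # lexicographic order of each orbit's smallest edge
    order = sorted(range(len(orbits)), key=lambda k: tuple(sorted(orbits[k][0])))
    dg.edge_type = {}
    dg.type_annotations = {}
    for rank, k in enumerate(order):
        cls = dg.construction_class[orbits[k][0]]
        if dg.T == 1:
            label = cls  # "2f" | "3f" | "5f"
        else:
            label = f"i{rank + 1}"
        for e in orbits[k]:
            if dg.construction_class[e] != cls:
                raise ValueError("orbit mixes construction classes")
            dg.edge_type[e] = label
        dg.type_annotations[label] = cls
    return dg.edge_type


# ---------------------------------------------------------------------------
# Assembly systems and connectivity pathways
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriangleAssemblySystem:
    """One interface assembly system derived from a dual-graph edge (a, b)
    and, for the dimer systems, a triangle vertex c adjacent to both."""

    interface_type: str
    kind: str  # "monomer-monomer" | "dimer-monomer"
    fixed_members: tuple
    mobile_members: tuple

    @property
    def label(self) -> str:
        fm = "+".join(map(str, self.fixed_members))
        mm = "+".join(map(str, self.mobile_members))
        return f"{self.interface_type}:{fm}|{mm}"


def representative_edge(dg: DualGraph, type_label: str) -> tuple:
    """Lexicographically smallest edge of an interface type."""
    return tuple(sorted(dg.edges_of_type(type_label)[0]))


def enumerate_assembly_systems(dg: DualGraph, type_label: str,
                               triangle_policy: str = "auto"
                               ) -> list[TriangleAssemblySystem]:
    """Enumerate the interface assembly systems for one interface type.

    A representative edge (a, b) of the type is chosen (lexicographically
    smallest).  The monomer-monomer system (a, b) is emitted once.  For each
    considered triangle a-b-c, two dimer-monomer systems are emitted: the
    dimer a+c against b, and the dimer b+c against a.

    triangle_policy:
      * ``"one"``  — use only the lexicographically smallest incident
        triangle (three systems per type; the T=1 convention).
      * ``"all"``  — use every incident triangle (the T=3 convention).
      * ``"auto"`` — "one" for T=1, "all" for T=3.
    """
    if triangle_policy == "auto":
        triangle_policy = "one" if dg.T == 1 else "all"
    if triangle_policy not in ("one", "all"):
        raise ValueError(f"unknown triangle policy {triangle_policy!r}")
    a, b = representative_edge(dg, type_label)
    cs = sorted(set(dg.graph.neighbors(a)) & set(dg.graph.neighbors(b)))
    systems = [TriangleAssemblySystem(type_label, "monomer-monomer", (a,), (b,))]
    if not cs:
        import warnings
        warnings.warn(f"edge {(a, b)} of type {type_label} lies in no triangle; "
                      "emitting the monomer-monomer system only")
        return systems
    if triangle_policy == "one":
        cs = cs[:1]
    for c in cs:
        systems.append(TriangleAssemblySystem(type_label, "dimer-monomer", (a, c), (b,)))
        systems.append(TriangleAssemblySystem(type_label, "dimer-monomer", (b, c), (a,)))
    return systems


def assembly_system_census(dg: DualGraph, triangle_policy: str = "auto") -> int:
    """Total number of distinct assembly systems across all interface types."""
    total = 0
    for t in dg.types:
        total += len(enumerate_assembly_systems(dg, t, triangle_policy))
    return total


@dataclass(frozen=True)
class ConnectivityPathway:
    """A minimal set of interface types whose edge union spans and connects
    all subunits."""

    type_set: frozenset

    @property
    def label(self) -> str:
        return "+".join(sorted(self.type_set))


def _union_spanning_connected(dg: DualGraph, types: frozenset) -> bool:
    H = nx.Graph()
    H.add_nodes_from(dg.graph.nodes)
    for e, t in dg.edge_type.items():
        if t in types:
            u, v = tuple(e)
            H.add_edge(u, v)
    return nx.is_connected(H)


def connectivity_pathways(dg: DualGraph) -> list[ConnectivityPathway]:
    """Enumerate all connectivity pathways, in deterministic order.

    A subset I of interface types qualifies when the union of its edge sets
    is a connected subgraph spanning all 60*T subunits, and no proper subset
    obtained by dropping one member type still spans and connects.
    """
    types = dg.types
    found = []
    for r in range(1, len(types) + 1):
        for combo in itertools.combinations(types, r):
            s = frozenset(combo)
            if not _union_spanning_connected(dg, s):
                continue
            minimal = all(
                not _union_spanning_connected(dg, s - {t}) for t in s
            )
            if minimal:
                found.append(ConnectivityPathway(s))
    return sorted(found, key=lambda p: (len(p.type_set), p.label))


def pathway_cruciality(type_label: str,
                       pathways: list[ConnectivityPathway]) -> int:
    """Number of connectivity pathways containing the given interface type."""
    return sum(1 for p in pathways if type_label in p.type_set)
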
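"""Per-frame hydrogen-bond graph construction.

Each trajectory frame is converted into an undirected intermolecular graph:
vertices are named interaction-site atoms (a solute oxygen, a water hydrogen,
...), edges are geometric hydrogen-bond contacts.  Two criteria are provided:

* the distance-only criterion used for the network analysis proper,
  r(O...H) < 0.30 nm with the angle left unspecified (all angles accepted),
  measured between an acceptor/donor site atom and the opposite-role solvent
  atom; and
* the GROMACS ``g_hbond``-style criterion used for cross-comparison,
  r(DA) <= 0.35 nm plus an H-D-A angle <= 30 deg, at most one edge per
  donor-hydrogen/acceptor pair.

Distances honour periodic boundaries of the cubic box via the minimum-image
convention, so edges may cross the box boundary; the integer image shift used
is recorded on each edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .errors import AnalysisError, TopologyError
from .topology import Frame, MoleculeInstance, SystemTopology

__all__ = [
    "InteractionRule", "SiteVertex", "GraphEdge", "FrameGraph",
    "minimum_image_distance", "build_frame_graph", "build_gmx_graph",
    "CHEMNETWORKS_RULE", "GMX_RULE",
]


@dataclass(frozen=True)
class InteractionRule:
    """A geometric hydrogen-bond criterion.

    Parameters
    ----------
    name
        Free-form label recorded in outputs.
    measured_pair
        ``"OH"``: distance between a site oxygen and a solvent hydrogen (or a
        site hydrogen and the solvent oxygen).  ``"DA"``: donor-oxygen to
        acceptor-oxygen distance.
    distance_cutoff
        nm.  Compared strictly (``<``) when ``strict`` is true, else ``<=``.
    angle_cutoff
        Degrees, or ``None`` to accept all angles (the distance-only variant).
    angle_convention
        ``"HDA"``: angle at the donor between D->H and D->A.
        ``"DHA"``: angle at the hydrogen between H->D and H->A.
    """

    name: str
    measured_pair: str = "OH"
    distance_cutoff: float = 0.30
    strict: bool = True
    angle_cutoff: float | None = None
    angle_convention: str = "HDA"

    def __post_init__(self) -> None:
        if self.measured_pair not in ("OH", "DA"):
            raise ValueError("measured_pair must be 'OH' or 'DA'")
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if self.angle_cutoff is not None and not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle_cutoff must lie in (0, 180]")
        if self.angle_convention not in ("HDA", "DHA"):
            raise ValueError("angle_convention must be 'HDA' or 'DHA'")

    def accepts_distance(self, r: float | np.ndarray):
        return r < self.distance_cutoff if self.strict else r <= self.distance_cutoff


#: Distance-only criterion the network analysis runs under by default.
CHEMNETWORKS_RULE = InteractionRule("r(O..H)<0.30nm", "OH", 0.30, strict=True)

#: g_hbond-style donor-acceptor criterion for the comparison mode.
GMX_RULE = InteractionRule("gmx r(DA)<=0.35nm a(HDA)<=30", "DA", 0.35,
                           strict=False, angle_cutoff=30.0,
                           angle_convention="HDA")


class SiteVertex(NamedTuple):
    """A graph vertex: molecule instance index, site label, 1-based atom serial."""

    mol: int
    site: str
    serial: int


class GraphEdge(NamedTuple):
    """An undirected edge; ``u < v`` by tuple order.

    ``distance`` is the realized minimum-image distance (nm), ``shift`` the
    integer image displacement applied to ``v``'s position, ``via`` the serial
    of the mediating hydrogen for donor-acceptor edges (``None`` otherwise).
    """

    u: SiteVertex
    v: SiteVertex
    distance: float
    shift: tuple[int, int, int] = (0, 0, 0)
    via: int | None = None


@dataclass
class FrameGraph:
    """The intermolecular interaction graph of one frame."""

    frame_index: int
    vertices: list[SiteVertex]
    edges: list[GraphEdge] = field(default_factory=list)

    def degree(self, vertex: SiteVertex) -> int:
        return sum(1 for e in self.edges if e.u == vertex or e.v == vertex)

    def degrees(self) -> dict[SiteVertex, int]:
        out = {v: 0 for v in self.vertices}
        for e in self.edges:
            out[e.u] = out.get(e.u, 0) + 1
            out[e.v] = out.get(e.v, 0) + 1
        return out

    def neighbors(self, vertex: SiteVertex) -> list[SiteVertex]:
        out = []
        for e in self.edges:
            if e.u == vertex:
                out.append(e.v)
            elif e.v == vertex:
                out.append(e.u)
        return out

    def adjacency(self) -> dict[SiteVertex, set[SiteVertex]]:
        adj: dict[SiteVertex, set[SiteVertex]] = {v: set() for v in self.vertices}
        for e in self.edges:
            adj[e.u].add(e.v)
            adj[e.v].add(e.u)
        return adj

    def find_site(self, label: str) -> SiteVertex:
        """Look up a vertex by site label (first match in vertex order)."""
        for v in self.vertices:
            if v.site == label:
                return v
        raise AnalysisError(f"no vertex with site label {label!r}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Minimum image

def minimum_image_distance(a, b, box_edge: float):
    """Distance between ``a`` and the nearest periodic image of ``b``.

    Returns ``(distance_nm, shift)`` where ``shift`` is the integer triple of
    box translations applied to ``b``.
    """
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    shift = -np.round(d / box_edge)
    d = d + shift * box_edge
    return float(np.linalg.norm(d)), tuple(int(s) for s in shift)


def _mi_delta(a: np.ndarray, b: np.ndarray, box_edge: float | None):
    """Vectorized minimum-image displacement b[j] - a[i] -> (na, nb, 3) plus shifts."""
    d = b[None, :, :] - a[:, None, :]
    if box_edge is None:
        shift = np.zeros_like(d)
    else:
        shift = -np.round(d / box_edge)
        d = d + shift * box_edge
    return d, shift


# ---------------------------------------------------------------------------
# Vertex universe

def _detect_solvent(topology: SystemTopology) -> str:
    """The solvent template: 3-site O/H/H geometry; error if ambiguous."""
    waters = [name for name, tpl in topology.templates.items()
              if sorted(tpl.elements) == ["H", "H", "O"]]
    if len(waters) != 1:
        raise TopologyError(
            f"cannot auto-detect solvent template among {list(topology.templates)}; "
            "pass solvent= explicitly")
    return waters[0]


def _site_vertices(mi: MoleculeInstance) -> list[tuple[SiteVertex, int]]:
    """(vertex, local index) for every named site of a molecule instance."""
    out = []
    for label, local in mi.template.sites.items():
        out.append((SiteVertex(mi.mol_index, label, mi.atom_offset + local + 1), local))
    return out


def vertex_universe(topology: SystemTopology,
                    solvent: str | None = None) -> list[SiteVertex]:
    """All named-site vertices of a system, in layout order."""
    verts = []
    for mi in topology.instances():
        verts.extend(v for v, _ in _site_vertices(mi))
    return verts


# ---------------------------------------------------------------------------
# Graph builders

def build_frame_graph(frame: Frame, topology: SystemTopology,
                      rule: InteractionRule = CHEMNETWORKS_RULE,
                      include_water_water: bool = False,
                      solvent: str | None = None,
                      box_edge: float | None = None) -> FrameGraph:
    """Build the interaction graph of one frame under an O...H distance rule.

    Every qualifying (site atom, solvent atom) pair contributes one edge, so a
    water oriented with both hydrogens inside the cutoff of one site gives
    that site raw degree two.  Intramolecular pairs are excluded.  The angle
    test is applied only when the rule specifies a cutoff.
    """
    if rule.measured_pair != "OH":
        return build_gmx_graph(frame, topology, rule=rule,
                               include_water_water=include_water_water,
                               solvent=solvent, box_edge=box_edge)
    topology.check_frame(frame)
    solvent = solvent or _detect_solvent(topology)
    box = box_edge if box_edge is not None else (frame.box_edge or topology.box_edge)

    solute_O: list[SiteVertex] = []   # acceptor-capable site oxygens
    solute_H: list[SiteVertex] = []   # donor site hydrogens
    water_O: list[SiteVertex] = []
    water_H: list[SiteVertex] = []
    vertices: list[SiteVertex] = []
    for mi in topology.instances():
        for vert, local in _site_vertices(mi):
            vertices.append(vert)
            el = mi.template.elements[local]
            if mi.template.name == solvent:
                (water_O if el == "O" else water_H).append(vert)
            else:
                if el == "O":
                    solute_O.append(vert)
                elif el == "H":
                    solute_H.append(vert)

    graph = FrameGraph(frame.index, vertices)
    pair_blocks = [(solute_O, water_H), (solute_H, water_O)]
    if include_water_water:
        pair_blocks.append((water_O, water_H))
    for left, right in pair_blocks:
        _add_distance_edges(graph, frame, topology, rule, left, right, box)
    graph.edges.sort()
    return graph


def _add_distance_edges(graph: FrameGraph, frame: Frame,
                        topology: SystemTopology, rule: InteractionRule,
                        left: list[SiteVertex], right: list[SiteVertex],
                        box: float | None) -> None:
    if not left or not right:
        return
    a = frame.coords[[v.serial - 1 for v in left]]
    b = frame.coords[[v.serial - 1 for v in right]]
    d, shifts = _mi_delta(a, b, box)
    dist = np.linalg.norm(d, axis=-1)
    ii, jj = np.nonzero(rule.accepts_distance(dist))
    for i, j in zip(ii.tolist(), jj.tolist()):
        u, v = left[i], right[j]
        if u.mol == v.mol:  # intramolecular pair
            continue
        if rule.angle_cutoff is not None and not _angle_ok(
                frame, topology, rule, u, v, box):
            continue
        shift = tuple(int(s) for s in shifts[i, j])
        if u > v:
            u, v, shift = v, u, tuple(-s for s in shift)
        graph.edges.append(GraphEdge(u, v, float(dist[i, j]), shift))


def _instance_of(topology: SystemTopology, mol_index: int) -> MoleculeInstance:
    for mi in topology.instances():
        if mi.mol_index == mol_index:
            return mi
    raise TopologyError(f"no molecule instance {mol_index}")


def _angle_ok(frame: Frame, topology: SystemTopology, rule: InteractionRule,
              u: SiteVertex, v: SiteVertex, box: float | None) -> bool:
    """Angle test for an O...H contact; the donor is the oxygen bonded to the H."""
    h, o_acc = (u, v) if frame.elements[u.serial - 1] == "H" else (v, u)
    mi = _instance_of(topology, h.mol)
    local_h = h.serial - 1 - mi.atom_offset
    donors = [j for j in mi.template.bonded_to(local_h)
              if mi.template.elements[j] == "O"]
    if not donors:
        return False
    d_serial = mi.atom_offset + donors[0] + 1
    ang = _angle(frame, d_serial, h.serial, o_acc.serial, box, rule.angle_convention)
    return ang <= rule.angle_cutoff


def _angle(frame: Frame, d_serial: int, h_serial: int, a_serial: int,
           box: float | None, convention: str) -> float:
    pd = frame.coords[d_serial - 1]
    ph = frame.coords[h_serial - 1]
    pa = frame.coords[a_serial - 1]

    def mi_vec(p, q):
        d = q - p
        if box is not None:
            d = d - box * np.round(d / box)
        return d

    if convention == "HDA":
        v1, v2 = mi_vec(pd, ph), mi_vec(pd, pa)
    else:  # DHA: angle at the hydrogen
        v1, v2 = mi_vec(ph, pd), mi_vec(ph, pa)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def build_gmx_graph(frame: Frame, topology: SystemTopology,
                    rule: InteractionRule = GMX_RULE,
                    include_water_water: bool = False,
                    solvent: str | None = None,
                    box_edge: float | None = None) -> FrameGraph:
    """Build the graph under the donor-acceptor criterion.

    An edge connects a donor oxygen (an O bearing at least one bonded H) to
    an acceptor oxygen when r(DA) satisfies the cutoff and, if an angle
    cutoff is set, some donor hydrogen passes the angle test.  At most one
    edge is emitted per (donor hydrogen, acceptor) pair; the hydrogen's
    serial is recorded in the edge's ``via`` field.
    """
    topology.check_frame(frame)
    solvent = solvent or _detect_solvent(topology)
    box = box_edge if box_edge is not None else (frame.box_edge or topology.box_edge)

    # (vertex, [bonded H serials]) for donor-capable oxygens; plain acceptors too
    vertices: list[SiteVertex] = []
    oxygens: list[tuple[SiteVertex, list[int], bool]] = []  # (v, H serials, is_water)
    for mi in topology.instances():
        is_water = mi.template.name == solvent
        for vert, local in _site_vertices(mi):
            vertices.append(vert)
            if mi.template.elements[local] != "O":
                continue
            hs = [mi.atom_offset + j + 1 for j in mi.template.bonded_to(local)
                  if mi.template.elements[j] == "H"]
            oxygens.append((vert, hs, is_water))

    graph = FrameGraph(frame.index, vertices)
    for dv, hs, d_water in oxygens:
        if not hs:
            continue
        for av, _, a_water in oxygens:
            if av.mol == dv.mol:
                continue
            if not include_water_water and d_water and a_water:
                continue
            r, shift = minimum_image_distance(
                frame.coords[dv.serial - 1], frame.coords[av.serial - 1], box)
            if not rule.accepts_distance(r):
                continue
            for h_serial in hs:
                if rule.angle_cutoff is not None:
                    ang = _angle(frame, dv.serial, h_serial, av.serial, box,
                                 rule.angle_convention)
                    if ang > rule.angle_cutoff:
                        continue
                u, v, sh = dv, av, shift
                if u > v:
                    u, v, sh = v, u, tuple(-s for s in shift)
                graph.edges.append(GraphEdge(u, v, r, sh, via=h_serial))
    graph.edges.sort(key=lambda e: (e.u, e.v, e.via))
    return graph


def project_to_molecules(graph: FrameGraph,
                         keep: frozenset[int] = frozenset({0})) -> FrameGraph:
    """Collapse each molecule's vertices to one vertex, except molecules in
    ``keep`` (default: the solute, instance 0), whose named sites stay
    distinct.

    This is the representation geodesic pathways run on: a hydrogen-bond
    path can then pass *through* a bridging water, because the water's
    oxygen and hydrogen vertices become a single vertex.  Parallel edges
    collapse to one (the shortest realized distance is kept).
    """
    def proj(v: SiteVertex) -> SiteVertex:
        if v.mol in keep:
            return v
        return SiteVertex(v.mol, "*", 0)

    vertices: list[SiteVertex] = []
    seen: set[SiteVertex] = set()
    for v in graph.vertices:
        pv = proj(v)
        if pv not in seen:
            seen.add(pv)
            vertices.append(pv)
    best: dict[tuple[SiteVertex, SiteVertex], GraphEdge] = {}
    for e in graph.edges:
        u, v = proj(e.u), proj(e.v)
        if u == v:
            continue
        if u > v:
            u, v = v, u
        key = (u, v)
        if key not in best or e.distance < best[key].distance:
            best[key] = GraphEdge(u, v, e.distance, e.shift)
    return FrameGraph(graph.frame_index, vertices, sorted(best.values()))


# ---------------------------------------------------------------------------
# Graph-formalism file output

def write_graph_file(graph: FrameGraph, path) -> None:
    """Write one edge per line: molecule index, site label and atom serial of
    both endpoints plus the realized distance, in ascending endpoint order."""
    lines = ["# solvgraph edge list: mol_u site_u serial_u "
             "mol_v site_v serial_v distance_nm"]
    for e in sorted(graph.edges):
        lines.append(f"{e.u.mol} {e.u.site} {e.u.serial} "
                     f"{e.v.mol} {e.v.site} {e.v.serial} {e.distance:.6f}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
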
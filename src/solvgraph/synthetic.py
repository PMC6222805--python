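"""Synthetic solute-water trajectories with known ground truth.

The generator emulates, at toy scale, a small organic solute bearing two
hydroxyl-like and four methoxy-like oxygen sites, solvated by rigid 3-site
waters in a cubic periodic box.  Site occupancy evolves as a two-state
Markov chain per site -- per-frame unbind probability ``p`` and (re)bind
probability ``b`` -- so the true statistics are known by construction:

* mean bound duration 1/p frames (geometric), i.e. ``frame_interval / p`` ps;
* stationary occupancy b / (b + p);
* a bound water swaps which hydrogen points at the site with per-frame
  probability ``q``, so hydrogen-label runs end with per-frame hazard
  1 - (1-p)(1-q) and have mean 1 / (1 - (1-p)(1-q)) frames.

The default ``q = p / (1 - p)`` makes the expected hydrogen-label run
exactly half the molecule run, the idealized regime in which the doubling
convention for hydrogen-traced lifetimes is exact.

Bound waters sit in the first hydration shell with the near hydrogen at the
shell radius (default 0.18 nm) from the site oxygen, the far hydrogen
geometrically outside a 0.30 nm cutoff; optional second-shell waters place a
hydrogen near 0.30 nm; all remaining waters are resampled uniformly in the
box each frame, outside an exclusion radius of every site.  This is a
statistical stand-in, not physics: there are no forces, and unbound waters
may overlap one another.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import SolvgraphError
from .graphs import FrameGraph, GraphEdge, SiteVertex
from .topology import (Frame, MoleculeTemplate, SystemTopology,
                       write_gro_structure, write_topology,
                       write_xyz_trajectory)

__all__ = [
    "SyntheticParams", "SyntheticTruth", "SyntheticResult",
    "make_topology", "simulate_occupancy", "render_frames",
    "graphs_from_states", "generate_trajectory",
    "SITE_LABELS", "HYDROXYL_SITES", "METHOXY_SITES",
]

# Toy solute site labels: two hydroxyl-like and four methoxy-like oxygens.
HYDROXYL_SITES = ("O9", "O9p")
METHOXY_SITES = ("O3", "O4", "O4p", "O5p")
SITE_LABELS = HYDROXYL_SITES + METHOXY_SITES

_R_OH = 0.0957          # water O-H bond length, nm
_HOH_DEG = 104.52       # water H-O-H angle, degrees
_SCAFFOLD_R = 0.35      # site oxygen distance from the solute centre, nm
_N_SOLUTE_ATOMS = 9

# outward axes of the six sites (octahedral scaffold)
_SITE_AXES = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
], dtype=float)


@dataclass
class SyntheticParams:
    """Study conditions of the synthetic system.

    Defaults give a 500-frame, 200-water box sampled every 0.5 ps with mean
    bound time 1/p = 5 frames = 2.5 ps and stationary occupancy 0.5.
    """

    n_waters: int = 200
    box_edge: float = 5.2           # nm
    n_frames: int = 500
    frame_interval: float = 0.5     # ps
    shell_radius: float = 0.18      # site-O to near water H, nm
    shell_sigma: float = 0.003      # radial jitter of the shell radius, nm
    angular_jitter: float = 15.0    # half-angle of the binding cone, degrees
    unbind_prob: float = 0.2        # p: bound -> free per frame
    bind_prob: float = 0.2          # b: free site rebinds per frame
    swap_prob: float | None = None  # q; None -> p / (1 - p)
    both_hydrogens_inside: bool = False
    n_second_shell: int = 0
    second_shell_radius: float = 0.30
    second_shell_sigma: float = 0.012
    exclusion_radius: float = 0.45  # bulk waters stay this far from sites, nm
    seed: int = 0

    @property
    def q(self) -> float:
        if self.swap_prob is not None:
            return self.swap_prob
        p = self.unbind_prob
        return p / (1.0 - p) if p < 0.5 else 1.0

    def validate(self) -> None:
        for name in ("unbind_prob", "bind_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.swap_prob is not None and not 0.0 <= self.swap_prob <= 1.0:
            raise ValueError("swap_prob must lie in [0, 1]")
        if self.n_waters < len(SITE_LABELS) + self.n_second_shell:
            raise ValueError("not enough waters for sites plus second shell")
        if self.box_edge < 2 * (self.exclusion_radius + _SCAFFOLD_R):
            raise ValueError("box too small to hold the solute and exclusion zone")
        if self.n_waters * 0.01 > self.box_edge ** 3:
            raise ValueError("box too small to hold all waters without overlap")


def make_topology(params: SyntheticParams) -> SystemTopology:
    """Topology of the toy system: one solute plus ``n_waters`` waters."""
    lig = MoleculeTemplate(
        "LIG",
        elements=["C", "O", "H", "O", "H", "O", "O", "O", "O"],
        bonds=[(0, 1), (1, 2), (0, 3), (3, 4), (0, 5), (0, 6), (0, 7), (0, 8)],
        sites={"O9": 1, "O9p": 3, "O3": 5, "O4": 6, "O4p": 7, "O5p": 8},
    )
    wat = MoleculeTemplate(
        "WAT", elements=["O", "H", "H"], bonds=[(0, 1), (0, 2)],
        sites={"O": 0, "H1": 1, "H2": 2},
    )
    return SystemTopology({"LIG": lig, "WAT": wat},
                          [("LIG", 1), ("WAT", params.n_waters)],
                          box_edge=params.box_edge)


@dataclass
class SyntheticTruth:
    """Exact bound/unbound state sequence plus analytic expectations."""

    bound_water: np.ndarray  # (n_sites, n_frames) water index, -1 when empty
    active_h: np.ndarray     # (n_sites, n_frames) 0/1, -1 when empty
    site_labels: tuple[str, ...]
    params: SyntheticParams
    expected: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p, b, q = (self.params.unbind_prob, self.params.bind_prob,
                   self.params.q)
        h_hazard = 1.0 - (1.0 - p) * (1.0 - q)
        self.expected = {
            "mean_bound_frames": 1.0 / p if p > 0 else float("inf"),
            "mean_bound_time_ps": (self.params.frame_interval / p
                                   if p > 0 else float("inf")),
            "stationary_occupancy": b / (b + p) if b + p > 0 else 1.0,
            "mean_hydrogen_run_frames": (1.0 / h_hazard if h_hazard > 0
                                         else float("inf")),
        }


def simulate_occupancy(params: SyntheticParams,
                       rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Run the per-site Markov occupancy chains (no geometry)."""
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    p, b, q = params.unbind_prob, params.bind_prob, params.q
    n_sites = len(SITE_LABELS)
    n_exchange = params.n_waters - params.n_second_shell  # exchangeable pool
    bound = np.full((n_sites, params.n_frames), -1, dtype=np.int64)
    active = np.full((n_sites, params.n_frames), -1, dtype=np.int64)
    occ_stat = b / (b + p) if b + p > 0 else 1.0
    free = list(range(n_exchange))
    cur = np.full(n_sites, -1, dtype=np.int64)
    cur_h = np.full(n_sites, -1, dtype=np.int64)

    def recruit(s: int) -> None:
        k = int(rng.integers(len(free)))
        cur[s] = free.pop(k)
        cur_h[s] = int(rng.integers(2))

    for s in range(n_sites):
        if rng.random() < occ_stat:
            recruit(s)
    for t in range(params.n_frames):
        for s in range(n_sites):
            if t > 0:  # evolve from the previous frame's state
                if cur[s] >= 0:
                    if rng.random() < p:
                        free.append(int(cur[s]))
                        cur[s] = -1
                        cur_h[s] = -1
                    elif rng.random() < q:
                        cur_h[s] = 1 - cur_h[s]
                elif rng.random() < b and free:
                    recruit(s)
            bound[s, t] = cur[s]
            active[s, t] = cur_h[s]
    return SyntheticTruth(bound, active, SITE_LABELS, params)


# ---------------------------------------------------------------------------
# Geometry rendering

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _jittered_axis(axis: np.ndarray, half_angle_deg: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniform direction within a cone of the given half-angle around axis."""
    if half_angle_deg <= 0:
        return axis
    cos_min = np.cos(np.radians(half_angle_deg))
    c = rng.uniform(cos_min, 1.0)
    phi = rng.uniform(0.0, 2 * np.pi)
    s = np.sqrt(1.0 - c * c)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(axis, helper))
    e2 = np.cross(axis, e1)
    return c * axis + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _perp(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(u, helper))
    e2 = np.cross(u, e1)
    phi = rng.uniform(0.0, 2 * np.pi)
    return np.cos(phi) * e1 + np.sin(phi) * e2


def _bound_water_coords(site_pos: np.ndarray, u: np.ndarray, d: float,
                        rng: np.random.Generator,
                        both_inside: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(O, near/first H, far/second H) of a water bound along direction u."""
    theta = np.radians(_HOH_DEG)
    if both_inside:
        # symmetric geometry: both hydrogens equidistant from the site
        ow = site_pos + 0.28 * u
        w = _perp(u, rng)
        half = theta / 2.0
        h_a = ow + _R_OH * (np.cos(half) * -u + np.sin(half) * w)
        h_b = ow + _R_OH * (np.cos(half) * -u - np.sin(half) * w)
        return ow, h_a, h_b
    near = site_pos + d * u
    # Librational tilt of the O-H...site axis: a perfectly collinear
    # placement would give the far hydrogen an artificially sharp distance
    # distribution.  The tilt is resampled until the far hydrogen stays
    # outside the 0.30 nm cutoff, preserving the exact edge pattern.
    for attempt in range(50):
        psi = 0.0 if attempt == 49 else min(abs(rng.normal(0.0, np.radians(15))),
                                            np.radians(30))
        w1 = _perp(u, rng)
        axis = np.cos(psi) * u + np.sin(psi) * w1  # near-H -> O direction
        ow = near + _R_OH * axis
        w2 = _perp(axis, rng)
        far = ow + _R_OH * (np.cos(theta) * -axis + np.sin(theta) * w2)
        if np.linalg.norm(far - site_pos) > 0.302:
            return ow, near, far
    raise AssertionError("unreachable: collinear fallback always succeeds")


def render_frames(truth: SyntheticTruth,
                  rng: np.random.Generator | None = None) -> list[Frame]:
    """Realize the occupancy states as Cartesian frames."""
    params = truth.params
    rng = rng or np.random.default_rng(params.seed + 1)
    n_sites = len(SITE_LABELS)
    centre = np.full(3, params.box_edge / 2.0)
    site_pos = centre + _SCAFFOLD_R * _SITE_AXES
    # solute atom order: C, O9, H9, O9p, H9p, O3, O4, O4p, O5p
    solute = np.empty((_N_SOLUTE_ATOMS, 3))
    solute[0] = centre
    solute[1] = site_pos[0]
    solute[2] = site_pos[0] + _R_OH * np.array([0.0, 1.0, 0.0])
    solute[3] = site_pos[1]
    solute[4] = site_pos[1] + _R_OH * np.array([0.0, 1.0, 0.0])
    solute[5:9] = site_pos[2:6]
    elements = (["C", "O", "H", "O", "H", "O", "O", "O", "O"]
                + ["O", "H", "H"] * params.n_waters)

    second_shell = list(range(params.n_waters - params.n_second_shell,
                              params.n_waters))
    frames: list[Frame] = []
    for t in range(params.n_frames):
        coords = np.empty((_N_SOLUTE_ATOMS + 3 * params.n_waters, 3))
        coords[:_N_SOLUTE_ATOMS] = solute
        placed = np.zeros(params.n_waters, dtype=bool)
        for s in range(n_sites):
            w_idx = int(truth.bound_water[s, t])
            if w_idx < 0:
                continue
            u = _jittered_axis(_SITE_AXES[s], params.angular_jitter, rng)
            # keep the near hydrogen inside, the far one outside, the cutoff
            d = float(np.clip(rng.normal(params.shell_radius,
                                         params.shell_sigma), 0.172, 0.20))
            ow, h_near, h_far = _bound_water_coords(
                site_pos[s], u, d, rng, params.both_hydrogens_inside)
            off = _N_SOLUTE_ATOMS + 3 * w_idx
            coords[off] = ow
            a = int(truth.active_h[s, t])
            if params.both_hydrogens_inside:
                a = 0
            coords[off + 1 + a] = h_near
            coords[off + 2 - a] = h_far
            placed[w_idx] = True
        for k, w_idx in enumerate(second_shell):
            s = k % n_sites
            u = _jittered_axis(_SITE_AXES[s], params.angular_jitter, rng)
            d = max(float(rng.normal(params.second_shell_radius,
                                     params.second_shell_sigma)), 0.26)
            ow, h_near, h_far = _bound_water_coords(site_pos[s], u, d, rng, False)
            off = _N_SOLUTE_ATOMS + 3 * w_idx
            coords[off] = ow
            coords[off + 1] = h_near
            coords[off + 2] = h_far
            placed[w_idx] = True
        _place_bulk(coords, placed, site_pos, params, rng)
        frames.append(Frame(elements, coords, box_edge=params.box_edge,
                            index=t, time=t * params.frame_interval))
    return frames


def _place_bulk(coords: np.ndarray, placed: np.ndarray, site_pos: np.ndarray,
                params: SyntheticParams, rng: np.random.Generator,
                max_retries: int = 200) -> None:
    """Uniform bulk waters, resampled outside the site exclusion zone."""
    free = np.flatnonzero(~placed)
    if free.size == 0:
        return
    L = params.box_edge
    pos = rng.uniform(0.0, L, size=(free.size, 3))
    for _ in range(max_retries):
        d = site_pos[None, :, :] - pos[:, None, :]
        d -= L * np.round(d / L)
        bad = (np.linalg.norm(d, axis=-1).min(axis=1)
               < params.exclusion_radius + _R_OH)
        if not bad.any():
            break
        pos[bad] = rng.uniform(0.0, L, size=(int(bad.sum()), 3))
    else:
        raise SolvgraphError("water placement failed after retries "
                             "(exclusion zone too large for the box)")
    theta = np.radians(_HOH_DEG)
    for row, w_idx in enumerate(free):
        e1 = _unit(rng.normal(size=3))
        e2 = _perp(e1, rng)
        off = _N_SOLUTE_ATOMS + 3 * int(w_idx)
        coords[off] = pos[row]
        coords[off + 1] = pos[row] + _R_OH * e1
        coords[off + 2] = pos[row] + _R_OH * (np.cos(theta) * e1
                                              + np.sin(theta) * e2)


# ---------------------------------------------------------------------------
# State-level graphs (no geometry)

def graphs_from_states(truth: SyntheticTruth) -> list[FrameGraph]:
    """Frame graphs implied directly by the occupancy states.

    Vertex labelling matches what :func:`~solvgraph.graphs.build_frame_graph`
    produces on the rendered frames, so persistence and census code can run
    on exact ground truth without geometry.
    """
    params = truth.params
    site_verts = _solute_site_vertices()
    d = params.shell_radius
    graphs: list[FrameGraph] = []
    for t in range(params.n_frames):
        edges: list[GraphEdge] = []
        verts = list(site_verts)
        for s in range(len(SITE_LABELS)):
            w = int(truth.bound_water[s, t])
            if w < 0:
                continue
            a = int(truth.active_h[s, t])
            hs = [0, 1] if params.both_hydrogens_inside else [a]
            for h in hs:
                hv = _water_h_vertex(w, h)
                verts.append(hv)
                u, v = sorted((site_verts[s], hv))
                edges.append(GraphEdge(u, v, d))
        edges.sort()
        graphs.append(FrameGraph(t, verts, edges))
    return graphs


def _solute_site_vertices() -> list[SiteVertex]:
    serial_of = {"O9": 2, "O9p": 4, "O3": 6, "O4": 7, "O4p": 8, "O5p": 9}
    return [SiteVertex(0, lab, serial_of[lab]) for lab in SITE_LABELS]


def _water_h_vertex(water_index: int, h: int) -> SiteVertex:
    serial = _N_SOLUTE_ATOMS + 3 * water_index + 2 + h
    return SiteVertex(1 + water_index, f"H{h + 1}", serial)


# ---------------------------------------------------------------------------
# Top-level generation

@dataclass
class SyntheticResult:
    params: SyntheticParams
    topology: SystemTopology
    frames: list[Frame]
    truth: SyntheticTruth
    files: dict[str, Path] = field(default_factory=dict)


def generate_trajectory(params: SyntheticParams,
                        outdir: str | Path | None = None) -> SyntheticResult:
    """Generate the toy system; optionally write xyz/gro/topology/truth files.

    With an ``outdir``, writes ``topology.cfg``, ``traj.xyz``, ``frame0.gro``,
    ``truth.json`` (parameters and analytic expectations) and ``truth.csv``
    (per-frame bound water and active hydrogen per site).  Identical seeds
    give byte-identical files.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    truth = simulate_occupancy(params, rng)
    frames = render_frames(truth, rng)
    topology = make_topology(params)
    result = SyntheticResult(params, topology, frames, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {
            "topology": outdir / "topology.cfg",
            "xyz": outdir / "traj.xyz",
            "gro": outdir / "frame0.gro",
            "truth_json": outdir / "truth.json",
            "truth_csv": outdir / "truth.csv",
        }
        write_topology(topology, files["topology"])
        write_xyz_trajectory(frames, files["xyz"])
        write_gro_structure(frames[0], topology, files["gro"])
        payload = {"params": asdict(params), "expected": truth.expected,
                   "site_labels": list(truth.site_labels)}
        files["truth_json"].write_text(json.dumps(payload, indent=2) + "\n")
        lines = ["frame,site,bound_water,active_h"]
        for t in range(params.n_frames):
            for s, lab in enumerate(truth.site_labels):
                lines.append(f"{t},{lab},{truth.bound_water[s, t]},"
                             f"{truth.active_h[s, t]}")
        files["truth_csv"].write_text("\n".join(lines) + "\n")
        result.files = files
    return result
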
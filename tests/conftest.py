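import numpy as np
import pytest

import solvgraph as sg


@pytest.fixture(scope="session")
def small_system():
    """A 50-frame, 30-water synthetic system with default Markov exchange."""
    params = sg.SyntheticParams(n_waters=30, n_frames=50, seed=3)
    return sg.generate_trajectory(params)


@pytest.fixture(scope="session")
def small_graphs(small_system):
    return [sg.build_frame_graph(fr, small_system.topology)
            for fr in small_system.frames]


@pytest.fixture
def water_topology():
    """Minimal topology: one hydroxyl-bearing solute site plus n waters."""
    def make(n_waters, box_edge=3.0):
        sol = sg.MoleculeTemplate("SOL", ["O", "H"], bonds=[(0, 1)],
                                  sites={"O9": 0, "H9": 1})
        wat = sg.MoleculeTemplate("WAT", ["O", "H", "H"],
                                  bonds=[(0, 1), (0, 2)],
                                  sites={"O": 0, "H1": 1, "H2": 2})
        return sg.SystemTopology({"SOL": sol, "WAT": wat},
                                 [("SOL", 1), ("WAT", n_waters)],
                                 box_edge=box_edge)
    return make


def random_frame(topology, rng, box_edge=3.0):
    """Uniformly random coordinates matching a topology's element layout."""
    elements = []
    for mi in topology.instances():
        elements.extend(mi.template.elements)
    coords = rng.uniform(0.0, box_edge, size=(len(elements), 3))
    return sg.Frame(elements, coords, box_edge=box_edge)


def brute_force_oh_edges(frame, topology, rule, solvent="WAT"):
    """Independent all-pairs scan for the O...H distance criterion."""
    pairs = set()
    insts = list(topology.instances())
    for mi in insts:
        for label, local in mi.template.sites.items():
            el = mi.template.elements[local]
            serial = mi.atom_offset + local + 1
            is_water = mi.template.name == solvent
            for mj in insts:
                if mj.mol_index == mi.mol_index:
                    continue
                if not (mi.template.name != solvent and mj.template.name == solvent):
                    continue
                for lab2, loc2 in mj.template.sites.items():
                    el2 = mj.template.elements[loc2]
                    if {el, el2} != {"O", "H"}:
                        continue
                    s2 = mj.atom_offset + loc2 + 1
                    r, _ = sg.minimum_image_distance(
                        frame.coords[serial - 1], frame.coords[s2 - 1],
                        frame.box_edge)
                    ok = r < rule.distance_cutoff if rule.strict \
                        else r <= rule.distance_cutoff
                    if ok:
                        u = (mi.mol_index, label, serial)
                        v = (mj.mol_index, lab2, s2)
                        pairs.add(tuple(sorted((u, v))))
    return pairs


def edge_pairs(graph):
    return {((e.u.mol, e.u.site, e.u.serial), (e.v.mol, e.v.site, e.v.serial))
            for e in graph.edges}
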
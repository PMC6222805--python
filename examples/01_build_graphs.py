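"""Build per-frame hydrogen-bond graphs from a synthetic trajectory.

Generates a small solvated-solute system, converts the first frame into an
intermolecular graph under the r(O...H) < 0.30 nm criterion, and writes the
edge list in the .graph format.
"""

import solvgraph as sg

params = sg.SyntheticParams(n_waters=40, n_frames=5, seed=0)
result = sg.generate_trajectory(params)

graph = sg.build_frame_graph(result.frames[0], result.topology)
print(f"frame 0: {len(graph.vertices)} site vertices, {graph.n_edges} edges")
for e in graph.edges:
    print(f"  {e.u.site}(mol {e.u.mol}) -- {e.v.site}(mol {e.v.mol})"
          f"  r = {e.distance:.3f} nm  image shift {e.shift}")

sg.write_graph_file(graph, "frame0.graph")
print("wrote frame0.graph")

# Each edge is one geometric hydrogen-bond contact between a solute oxygen
# site and an individual water hydrogen; the image shift records when the
# contact crosses the periodic box boundary.
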
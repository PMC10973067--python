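"""Complex vs trimmed model: how outlet removal inflates distal flow.

Trims a 60-outlet template to its 10 most prominent outlets, simulates
both models with identical inlet waveforms, and compares time-averaged
centerline velocities along one path per inlet.
"""

import numpy as np

import cowflow as cf
from cowflow.metrics import removed_offtake_arcs
from cowflow.network import _outlet_inlet_branch, extract_path, outlet_prominence

complex_net = cf.generate_cow_template(60, seed=1, scale=0.8,
                                       min_radius=0.85,
                                       leaf_radius_range=(0.85, 1.25))
trimmed_net = cf.trim_network(complex_net, 10)
print(f"complex: {len(complex_net.outlets)} outlets; "
      f"trimmed: {len(trimmed_net.outlets)} outlets")

wfs = cf.default_inlet_waveforms()
res_c = cf.solve_unsteady(complex_net, wfs)
res_t = cf.solve_unsteady(trimmed_net, wfs)

# one representative path per inlet: to its most prominent kept outlet
chosen = {}
prom = dict(outlet_prominence(trimmed_net))
for o in trimmed_net.outlets:
    inlet = _outlet_inlet_branch(trimmed_net, o)
    if inlet not in chosen or prom[o] > prom[chosen[inlet]]:
        chosen[inlet] = o

for inlet, outlet in sorted(chosen.items()):
    path_c = extract_path(complex_net, inlet, outlet)
    path_t = extract_path(trimmed_net, inlet, outlet)
    mc = cf.compute_metrics(res_c, complex_net, case_id="complex",
                            paths={"p": path_c})
    mt = cf.compute_metrics(res_t, trimmed_net, case_id="trimmed",
                            paths={"p": path_t}, shared_radii={"p": path_c})
    removed = removed_offtake_arcs(complex_net, trimmed_net, path_c, path_t)
    rep = cf.compare_models(mc, mt, removed_offtakes={"p": removed})
    cl = rep.centerline["p"]
    frac = cl.get("distal_overestimation_fraction", float("nan"))
    print(f"\n{inlet} -> {outlet} ({path_c.length:.1f} mm, "
          f"{len(removed)} offtakes removed by trimming):")
    print(f"  max |delta CL-v| = {cl['max_abs_delta_v_m_s']:.3f} m/s")
    print(f"  trimmed model overestimates velocity at {100*frac:.0f}% of "
          "stations distal to the first removed offtake")
# delta = complex - trimmed; negative distal deltas mean the conventional
# trimmed model overestimates the flow that the fully segmented model
# actually distributes into its many small outlets.
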
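"""A miniature phase-diagram sweep.

Sweeps the domain-size parameter eta at fixed stress coupling gamma over
a reduced schedule and tabulates the pattern call per cell.  Real phase
diagrams use finer axes and longer horizons; this shows the mechanics of
the sweep table.  Takes several minutes.
"""

import numpy as np

import phyllosim as ps

base = ps.RunConfig(
    chem=ps.BVAMParams(eta=0.3902, c=0.57),
    schedule=ps.ScheduleParams(n_chem=400, n_mech=500, n_cycles=90,
                               stress_every=50, stop_after_generations=1,
                               on_divergence="truncate"),
    seed=1,
)

table = ps.phase_diagram_sweep(base, {"chem.eta": np.array([0.2014, 0.3902])})
print(table.to_string(index=False))
print("\nfold increases with eta: larger eta = shorter Turing wavelength")
print("= more organs fit around the dome circumference")
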
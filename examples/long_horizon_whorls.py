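"""Long-horizon run: successive whorl generations.

Runs the 4-whorl parameter set without an early stop for a long horizon
so later plastochrons (generations of whorls) can emerge as the dome
grows.  This is NOT desk scale -- expect on the order of an hour on one
core.  Snapshots are written so the shape sequence can be inspected in a
VTK viewer.
"""

from pathlib import Path

import phyllosim as ps
from phyllosim.io import export_fields, primordia_to_csv

config = ps.RunConfig(
    chem=ps.BVAMParams(eta=0.3902, c=0.57),
    mech=ps.MechParams(kappa=2.0, g_width=5.0),
    schedule=ps.ScheduleParams(n_chem=400, n_mech=500, n_cycles=400,
                               stress_every=50, snapshot_every=50,
                               on_divergence="truncate"),
    seed=1,
)

traj = ps.run_simulation(config, progress=True)

out = Path("long_horizon_output")
out.mkdir(exist_ok=True)
for snap in traj.snapshots:
    export_fields(snap, out / f"state_T{snap.T:04d}.vtk")
primordia_to_csv(traj.records, out / "primordia.csv")

print(f"generations completed: {traj.n_generations}")
print(f"records: {len(traj.records)}; logs and snapshots in {out}/")
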
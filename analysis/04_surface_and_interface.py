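"""Solvent-accessible surface and buried trimer-trimer interface area.

SASA of the two states is similar (same bead count, similar envelope); the
buried interface area IASA = ASA(top) + ASA(bottom) - ASA(both) separates
them clearly: the closed packing buries far more surface between the rings.
"""

import numpy as np
import pandas as pd

from hexadyn import surface, synthetic
from hexadyn.trajio import Trajectory

if __name__ == "__main__":
    rows = []
    for name, spec_fn in (("open", synthetic.open_state_spec),
                          ("closed", synthetic.closed_state_spec)):
        traj = synthetic.generate_hexamer_trajectory(spec_fn(seed=1, n_frames=8))
        total, per_chain = surface.sasa_series(traj, n_points=240)
        res = surface.iasa(traj, group_a={"A", "B", "C"},
                           group_b={"D", "E", "F"}, n_points=240)
        pd.DataFrame({"frame": np.arange(traj.n_frames), "sasa_A2": total,
                      "iasa_A2": res.iasa}).to_csv(
            f"results/surface_{name}.csv", index=False)
        rows.append((name, total.mean(), res.iasa.mean()))
        print(f"{name}: SASA {total.mean():.0f} A^2, "
              f"IASA {res.iasa.mean():.0f} A^2")
    (_, sasa_o, iasa_o), (_, sasa_c, iasa_c) = rows
    print(f"SASA differs by {100 * abs(sasa_o / sasa_c - 1):.1f}% — "
          f"weakly discriminating; IASA differs by a factor of "
          f"{iasa_c / iasa_o:.1f} (closed buries more interface)")
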
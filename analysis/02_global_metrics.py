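"""Global structural metrics of the two states: RMSD, core RMSD, RMSF, Rg.

Conventional RMSD barely separates the two states (both are dominated by
thermal noise of the same magnitude), which is exactly why the study moves
on to fraction-based core alignment and the mode/surface/cavity analyses.
"""

import numpy as np
import pandas as pd

from hexadyn import align, synthetic

if __name__ == "__main__":
    rows = []
    for name, spec_fn in (("open", synthetic.open_state_spec),
                          ("closed", synthetic.closed_state_spec)):
        traj = synthetic.generate_hexamer_trajectory(spec_fn(seed=1, n_frames=60))
        ca = traj.topology.mask(name="CA")
        rmsd = align.conventional_rmsd(traj, mask=ca)
        core = align.core_align(traj, 0.7, mask=ca)
        prof = align.rmsf(traj, mask=ca)
        rg = align.radius_of_gyration(traj, mask=ca)
        rows.append({
            "state": name,
            "mean_rmsd_A": rmsd.mean(),
            "mean_core_rmsd_A": core.core_rmsd.mean(),
            "mean_noncore_rmsd_A": np.nanmean(core.noncore_rmsd),
            "mean_rmsf_A": prof.rmsf.mean(),
            "mean_rg_A": rg.mean(),
        })
        print(f"{name}: RMSD {rmsd.mean():.2f} A, 70% core RMSD "
              f"{core.core_rmsd.mean():.2f} A, Rg {rg.mean():.2f} A")
    df = pd.DataFrame(rows)
    df.to_csv("results/global_metrics.csv", index=False)
    print("conventional RMSD separates the states by only "
          f"{abs(df.mean_rmsd_A.diff().iloc[-1]):.3f} A — "
          "the robust core split is what identifies the mobile regions")
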
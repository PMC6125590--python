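#!/usr/bin/env python
"""Distance-resolved contact analysis on planted synthetic trajectories.

For every ligand offset distance, generates three replicate trajectories
whose per-frame tail–ligand contact counts are planted with a
distance-dependent mean (high in the bound state, a dip at small offsets, an
intermediate-range peak, decay at long range — the qualitative shape of the
study system), analyses the second half of each run, and writes per-frame,
per-residue and grand-mean (Nc) contact tables.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tailbind.contacts import contact_time_series, per_residue_profile
from tailbind.pipeline import PipelineConfig, _contact_stage

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    cfg = PipelineConfig(seed=1)
    profiles, tables = _contact_stage(cfg)

    nc = pd.DataFrame({
        "distance": list(profiles),
        "Nc": [p.Nc for p in profiles.values()],
        "n_replicates": [p.per_frame_counts.shape[0]
                         for p in profiles.values()],
        "n_frames_analyzed": [p.per_frame_counts.shape[1]
                              for p in profiles.values()],
    })
    nc.to_csv(OUT / "contacts_nc_by_distance.csv", index=False)
    print("mean contacts per frame (Nc) by offset distance:")
    print(nc.to_string(index=False))

    rows = []
    for d, df in tables.items():
        df = df.copy()
        df.insert(0, "distance", d)
        rows.append(df)
    pd.concat(rows).to_csv(OUT / "contacts_per_residue.csv", index=False)

    # the full per-frame series is bulky diagnostics; park it under scratch/
    scratch = OUT.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    frames = []
    for d, prof in profiles.items():
        df = prof.per_frame_frame()
        df.insert(0, "distance", d)
        frames.append(df)
    pd.concat(frames).to_csv(scratch / "contacts_per_frame.csv", index=False)
    print(f"\nwrote per-residue tables under {OUT} "
          f"(per-frame series under {scratch})")
    print("note the non-monotone distance dependence: contacts dip just "
          "before docking and peak at intermediate offsets.")


if __name__ == "__main__":
    main()
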
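"""Extrapolation risk under the future scenarios: MOP similarity and
strict-extrapolation agreement across pseudo-GCMs.

Summarizes the MOP grids from script 04: per (GCM, scenario) the mean
environmental similarity of the projection region to the calibration
climate and the fraction of cells in strict extrapolation (any variable
outside the calibration range), plus the per-scenario strict-mask
agreement distribution. Writes results/mop_summary.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from tickenm.envstack import read_ascii_grid

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    marker = RESULTS / "demo_study" / "RUN_DIR.txt"
    if not marker.exists():
        print("run 04_calibrate_and_select.py first", flush=True)
        return 1
    grids = Path(marker.read_text().strip()) / "grids"
    rows = []
    for p in sorted(grids.glob("mop_*_similarity.asc")):
        _, gcm, scenario, _ = p.stem.split("_")
        sim, _ = read_ascii_grid(p)
        rows.append({"gcm": gcm, "scenario": scenario,
                     "mean_similarity": float(np.nanmean(sim)),
                     "min_similarity": float(np.nanmin(sim))})
    for scenario in ("rcp45", "rcp85"):
        agree, _ = read_ascii_grid(grids / f"mop_agreement_{scenario}.asc")
        finite = agree[np.isfinite(agree)].astype(int)
        frac_any = float((finite >= 1).mean())
        vals, counts = np.unique(finite, return_counts=True)
        dist = {int(v): int(c) for v, c in zip(vals, counts)}
        print(f"{scenario}: {frac_any:.1%} of cells strictly extrapolative for >= 1 GCM; "
              f"agreement distribution {dist}")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "mop_summary.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
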
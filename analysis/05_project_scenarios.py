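"""Present and future suitability composites: how much area is suitable,
how well truth is recovered, and where the pseudo-GCMs agree.

Summarizes the grids produced by script 04: suitable-area fraction in
the present and under each (GCM, scenario) transfer, the GCM change-
agreement class distribution per scenario, and the Spearman correlation
between the replicate-median suitability and the virtual species' known
truth surface. Writes results/scenario_summary.csv.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from tickenm.envstack import read_ascii_grid

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    marker = RESULTS / "demo_study" / "RUN_DIR.txt"
    if not marker.exists():
        print("run 04_calibrate_and_select.py first", flush=True)
        return 1
    run_dir = Path(marker.read_text().strip())
    grids = run_dir / "grids"
    truth, _ = read_ascii_grid(run_dir.parent / "inputs" / "truth.asc")
    med, _ = read_ascii_grid(grids / "present_median.asc")
    binary, _ = read_ascii_grid(grids / "present_binary.asc")
    m = np.isfinite(truth) & np.isfinite(med)
    rho = spearmanr(truth[m], med[m]).statistic
    print(f"truth recovery (median vs known suitability): Spearman rho = {rho:.3f}")
    threshold = json.loads((run_dir / "report.json").read_text())["threshold"]
    rows = [{"epoch": "present", "gcm": "-", "scenario": "-",
             "suitable_fraction": float(np.nansum(binary) / m.sum())}]
    for p in sorted(grids.glob("future_*_median.asc")):
        _, gcm, scenario, _ = p.stem.split("_")
        fut, _ = read_ascii_grid(p)
        rows.append({"epoch": "future", "gcm": gcm, "scenario": scenario,
                     "suitable_fraction": float(np.nanmean(fut[m] >= threshold))})
    for scenario in ("rcp45", "rcp85"):
        agree, _ = read_ascii_grid(grids / f"agreement_{scenario}.asc")
        vals, counts = np.unique(agree[np.isfinite(agree)].astype(int), return_counts=True)
        dist = {int(v): int(c) for v, c in zip(vals, counts)}
        print(f"{scenario} change-agreement classes (0 none, 1-4 gain, 5-8 loss): {dist}")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "scenario_summary.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
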
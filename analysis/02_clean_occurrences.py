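"""Occurrence cleaning audit: uncertainty filter, 25 km rarefaction, half split.

Reproduces the cleaning sequence on the synthetic sample from script 01
and writes the stage-by-stage record counts (the audit trail every
occurrence-based study should report) to results/occurrence_counts.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from tickenm.occurrences import filter_uncertainty, read_occurrences, split_half, thin_occurrences

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    occ_csv = RESULTS / "demo_study" / "study1" / "inputs" / "occurrences.csv"
    if not occ_csv.exists():
        print("run 01_build_synthetic_study.py first", flush=True)
        return 1
    occ = read_occurrences(occ_csv)
    stages = [("raw records", len(occ))]
    occ = filter_uncertainty(occ, 10_000.0)
    stages.append(("uncertainty <= 10,000 m", len(occ)))
    occ = occ.drop_duplicates()
    stages.append(("coordinate duplicates removed", len(occ)))
    occ = thin_occurrences(occ, 25.0, seed=0)
    stages.append(("rarefied to >= 25 km separation", len(occ)))
    cal, ev = split_half(occ, seed=0)
    stages.append(("calibration half", len(cal)))
    stages.append(("evaluation half", len(ev)))
    table = pd.DataFrame(stages, columns=["stage", "records"])
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "occurrence_counts.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
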
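"""Run configuration: every tunable of the workflow in one round-trippable record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters and input paths for a full pipeline run.

    Defaults follow the calibration protocol constants used throughout
    the package: 10 km uncertainty cap, 50 km rarefaction distance, a
    7-degree accessible-area buffer, E = 5% acceptable omission,
    alpha = 0.05 significance, a 2-unit AICc window and 10 final-model
    replicates.
    """

    # inputs
    occurrences_csv: str = ""
    present_dir: str = ""  # directory of .asc layers for the calibration period
    future_dirs: dict = field(default_factory=dict)  # {"gcm|scenario": dir}
    exclusion_csv: str | None = None

    # cleaning
    max_uncertainty_m: float = 10_000.0
    thin_km: float = 50.0

    # accessible area
    buffer_deg: float = 7.0

    # variable selection
    varset_target_sizes: list = field(default_factory=lambda: [4])
    varsel_classes: list = field(default_factory=lambda: ["linear", "quadratic"])
    varsel_beta: float = 1.0

    # calibration
    # mid-complexity subset of the 31 possible class combinations: enough
    # diversity for the sequential filters to keep workable candidates
    # while staying desk-scale
    feature_combos: list = field(
        default_factory=lambda: [
            ["linear"],
            ["quadratic"],
            ["linear", "quadratic"],
            ["linear", "product"],
            ["quadratic", "product"],
            ["linear", "quadratic", "product"],
            ["linear", "quadratic", "threshold"],
            ["linear", "quadratic", "hinge"],
        ]
    )
    multiplier_spec: str = "0.5; 1; 2"
    e_level: float = 0.05
    alpha: float = 0.05
    omission_max: float = 0.05
    delta_aicc_max: float = 2.0
    n_boot: int = 500
    boot_frac: float = 1.0
    aicc_on_all_occurrences: bool = True

    # final models
    n_replicates: int = 10
    bootstrap_replicates: bool = True
    final_fit_on_all: bool = True

    # background / MOP
    max_background: int = 10_000
    mop_reference_fraction: float = 0.1

    seed: int = 1

    def validate(self) -> None:
        checks = [
            (self.max_uncertainty_m > 0, "max_uncertainty_m must be positive"),
            (self.thin_km > 0, "thin_km must be positive"),
            (self.buffer_deg > 0, "buffer_deg must be positive"),
            (0 < self.e_level < 0.5, "e_level must be in (0, 0.5)"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (0 <= self.omission_max <= 1, "omission_max must be in [0, 1]"),
            (self.delta_aicc_max >= 0, "delta_aicc_max must be non-negative"),
            (self.n_replicates >= 1, "n_replicates must be >= 1"),
            (self.n_boot >= 1, "n_boot must be >= 1"),
            (0 < self.boot_frac <= 1, "boot_frac must be in (0, 1]"),
            (0 < self.mop_reference_fraction <= 1, "mop_reference_fraction must be in (0, 1]"),
            (bool(self.feature_combos), "feature_combos must be non-empty"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg
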
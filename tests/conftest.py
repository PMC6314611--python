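"""Shared fixtures: one synthetic study system reused across test modules.

Everything is generated programmatically with fixed seeds; heavy
objects (the fitted model, the demo pipeline run) are session-scoped so
expensive computations happen once.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

import tickenm
from tickenm.envstack import extract_values, read_ascii_grid
from tickenm.maxent import build_feature_spec, fit_maxent, sample_background

DATA_DIR = Path(__file__).resolve().parents[1] / "data"
VAR_NAMES = [f"var{i:02d}" for i in range(1, 7)]


@pytest.fixture(scope="session")
def env6():
    """50x50 six-variable synthetic climate stack."""
    return tickenm.generate_climate(50, 50, VAR_NAMES, smoothness=5.0, seed=1)


@pytest.fixture(scope="session")
def species(env6):
    """Virtual species with Gaussian responses to var01 and var03."""
    return tickenm.make_virtual_species(
        env6, ["var01", "var03"],
        optima={"var01": 0.5, "var03": -0.3},
        breadths={"var01": 0.8, "var03": 0.8},
    )


@pytest.fixture(scope="session")
def occurrences(species):
    return tickenm.sample_occurrences(species, 200, seed=2)


@pytest.fixture(scope="session")
def presence_values(env6, occurrences):
    vals, _ = extract_values(env6, occurrences)
    return vals


@pytest.fixture(scope="session")
def background(env6):
    return sample_background(env6, seed=0)


@pytest.fixture(scope="session")
def lq_model(presence_values, background):
    """Linear+quadratic model fitted to the virtual-species sample."""
    spec = build_feature_spec(("linear", "quadratic"), VAR_NAMES, background, presence_values)
    return fit_maxent(presence_values, background, spec, 1.0)


@pytest.fixture(scope="session")
def s1_fixture_path():
    return DATA_DIR / "s1_occurrences_synthetic.csv"


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo study (pipeline end to end on synthetic inputs)."""
    base = tmp_path_factory.mktemp("demo")
    cfg, report, run_dir = tickenm.run_demo_study(base, seed=1)
    truth, _ = read_ascii_grid(run_dir.parent / "inputs" / "truth.asc")
    return {"config": cfg, "report": report, "run_dir": run_dir, "truth": truth}


def rng_int(seed_seq_entropy: int) -> int:
    return int(np.random.SeedSequence(seed_seq_entropy).generate_state(1)[0] % (2**31))
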
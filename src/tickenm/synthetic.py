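"""Synthetic study systems: climate grids, a virtual species, samples, futures.

Every downstream stage of the niche-modeling pipeline is exercised on
data with known truth. The generator emulates the statistical shape of
the real inputs without imitating any particular region:

* **Climate layers** are spatially autocorrelated fields — Gaussian-
  smoothed white noise plus a latitudinal gradient — standardized to a
  chosen mean/sd. The smoothing kernel width is the autocorrelation
  ("smoothness") knob.
* **The virtual species** has Gaussian responses to a small subset of
  variables; its suitability surface (the product of per-variable
  Gaussian curves, rescaled to max 1) is the recoverable truth.
* **Occurrences** are sampled with probability proportional to truth,
  jittered within their cell, and tagged with a georeferencing
  uncertainty radius whose law straddles the 10,000 m filter cutoff
  (default: lognormal, median 5,000 m, ~10% mass above 10,000 m) so the
  uncertainty filter is exercised in both directions.
* **Futures** are per-scenario mean shifts plus smooth pseudo-GCM
  perturbations, one future stack per (GCM, scenario), mimicking how
  real general circulation models agree on direction but differ
  regionally.

All outputs are bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .envstack import EnvStack, GridTransform
from .occurrences import OccurrenceSet

import pandas as pd

#: default cell size, degrees (~10 arc-minutes, a common bioclim resolution)
DEFAULT_CELL_DEG = 1.0 / 6.0

# lognormal uncertainty with median 5,000 m and 10% of mass above 10,000 m:
# sigma = ln(10000/5000) / z_{0.90}
_UNC_MEDIAN_M = 5_000.0
_UNC_SIGMA = np.log(2.0) / 1.2815515655446004


@dataclass
class VirtualSpecies:
    """A species whose suitability is a known function of climate."""

    response_vars: list[str]
    optima: dict[str, float]
    breadths: dict[str, float]
    truth_grid: np.ndarray
    env: EnvStack = field(repr=False)


@dataclass
class ScenarioSet:
    """Present stack plus one future stack per (pseudo-GCM, scenario)."""

    present: EnvStack
    futures: dict[tuple[str, str], EnvStack]
    deltas: dict[str, dict[str, float]]

    @property
    def gcms(self) -> list[str]:
        return sorted({g for g, _ in self.futures})

    @property
    def scenarios(self) -> list[str]:
        return list(self.deltas)


def generate_climate(
    n_rows: int,
    n_cols: int,
    var_names: Sequence[str],
    smoothness: float = 5.0,
    seed: int = 0,
    cell_size: float = DEFAULT_CELL_DEG,
    origin: tuple[float, float] = (-95.0, 45.0),
    mean: float = 0.0,
    sd: float = 1.0,
    gradient_weight: float = 0.5,
) -> EnvStack:
    """Simulate a stack of spatially autocorrelated climate layers.

    Each layer is Gaussian-filtered white noise (kernel sd =
    ``smoothness`` cells, reflective boundaries) blended with a linear
    north-south gradient with weight ``gradient_weight``, then
    standardized to ``mean``/``sd`` over the grid. Alternate layers flip
    the gradient sign so temperature-like and precipitation-like
    variables are not collinear by construction.
    """
    if n_rows < 10 or n_cols < 10:
        raise ValueError("grid must be at least 10x10 cells")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    var_names = list(var_names)
    if len(var_names) < 2:
        raise ValueError("need at least 2 variables")
    rng = np.random.default_rng(seed)
    lat_grad = np.linspace(1.0, -1.0, n_rows)[:, None] * np.ones((1, n_cols))
    layers: dict[str, np.ndarray] = {}
    # asymptotic sd of unit white noise after a 2-D Gaussian filter; using
    # the theoretical value (not the empirical one) lets the noise term
    # vanish smoothly in the high-smoothness limit instead of
    # re-amplifying numerical dust
    noise_sd = 1.0 / (2.0 * smoothness * np.sqrt(np.pi))
    for i, name in enumerate(var_names):
        noise = ndimage.gaussian_filter(rng.standard_normal((n_rows, n_cols)), sigma=smoothness, mode="reflect")
        sign = 1.0 if i % 2 == 0 else -1.0
        raw = (1.0 - gradient_weight) * noise / noise_sd + gradient_weight * sign * lat_grad
        layers[name] = mean + sd * (raw - raw.mean()) / raw.std()
    tr = GridTransform(x_origin=origin[0], y_origin=origin[1], cell_size=cell_size)
    return EnvStack(layers, tr)


def make_virtual_species(
    env: EnvStack,
    response_vars: Sequence[str],
    optima: Mapping[str, float],
    breadths: Mapping[str, float],
) -> VirtualSpecies:
    """Define a virtual species with independent Gaussian responses.

    truth(cell) = prod_v exp(-(x_v - opt_v)^2 / (2 * breadth_v^2)),
    rescaled so its maximum over valid cells is exactly 1.
    """
    response_vars = list(response_vars)
    missing = [v for v in response_vars if v not in env.layers]
    if missing:
        raise KeyError(f"unknown response variable(s): {missing}")
    for v in response_vars:
        if breadths[v] <= 0:
            raise ValueError(f"breadth for {v!r} must be positive")
    truth = np.ones(env.shape, dtype=float)
    for v in response_vars:
        x = env.layers[v]
        truth = truth * np.exp(-((x - optima[v]) ** 2) / (2.0 * breadths[v] ** 2))
    truth = np.where(env.mask, truth, 0.0)
    peak = truth.max()
    if peak <= 0:
        raise ValueError("suitability is zero everywhere on valid cells")
    truth = truth / peak
    return VirtualSpecies(
        response_vars=response_vars,
        optima={v: float(optima[v]) for v in response_vars},
        breadths={v: float(breadths[v]) for v in response_vars},
        truth_grid=truth,
        env=env,
    )


def default_uncertainty_law(rng: np.random.Generator, n: int) -> np.ndarray:
    """Lognormal uncertainty radii: median 5,000 m, ~10% above 10,000 m."""
    return rng.lognormal(mean=np.log(_UNC_MEDIAN_M), sigma=_UNC_SIGMA, size=n)


def sample_occurrences(
    species: VirtualSpecies,
    n: int,
    uncertainty_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    species_name: str = "virtual_species",
) -> OccurrenceSet:
    """Sample presence records proportional to true suitability.

    Cells are drawn with probability proportional to the truth grid;
    each record is uniformly jittered within its cell and tagged with an
    uncertainty radius from ``uncertainty_law`` (default lognormal
    straddling the 10 km filter cutoff). Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = species.truth_grid.ravel()
    total = p.sum()
    if total <= 0:
        raise ValueError("truth grid has no positive-suitability cell")
    rng = np.random.default_rng(seed)
    idx = rng.choice(p.size, size=n, replace=True, p=p / total)
    nrow, ncol = species.truth_grid.shape
    row, col = np.divmod(idx, ncol)
    tr = species.env.transform
    cs = tr.cell_size
    lon = tr.x_origin + (col + rng.uniform(0.0, 1.0, size=n)) * cs
    lat = tr.y_origin - (row + rng.uniform(0.0, 1.0, size=n)) * cs
    law = uncertainty_law or default_uncertainty_law
    unc = np.asarray(law(rng, n), dtype=float)
    df = pd.DataFrame(
        {
            "species": species_name,
            "longitude": lon,
            "latitude": lat,
            "uncertainty_m": unc,
            "source_id": [f"synth-{i:06d}" for i in range(n)],
        }
    )
    return OccurrenceSet(df)


def generate_futures(
    env: EnvStack,
    n_gcm: int,
    scenario_deltas: Mapping[str, Mapping[str, float]],
    seed: int = 0,
    perturbation_sd: float = 0.3,
    perturbation_smoothness: float = 8.0,
) -> ScenarioSet:
    """Build pseudo-GCM future stacks: scenario mean shift + GCM-specific field.

    ``scenario_deltas`` maps scenario id -> {variable: shift}; every
    delta vector must cover exactly the stack's variables. Each of the
    ``n_gcm`` pseudo-GCMs adds its own smooth zero-mean perturbation
    field (sd ``perturbation_sd`` per variable, shared across scenarios)
    so GCMs agree on the forced trend but differ regionally — a larger-
    delta scenario therefore shifts every variable strictly more on
    average than a smaller-delta one.
    """
    if n_gcm < 1:
        raise ValueError("n_gcm must be >= 1")
    for sc, dd in scenario_deltas.items():
        if set(dd) != set(env.names):
            raise ValueError(f"scenario {sc!r}: delta vector does not match variables {env.names}")
    futures: dict[tuple[str, str], EnvStack] = {}
    ss = np.random.SeedSequence(seed)
    gcm_seeds = ss.spawn(n_gcm)
    for g in range(n_gcm):
        gid = f"gcm{g + 1}"
        rng = np.random.default_rng(gcm_seeds[g])
        perturb = {}
        for name in env.names:
            if perturbation_sd > 0:
                f = ndimage.gaussian_filter(
                    rng.standard_normal(env.shape), sigma=perturbation_smoothness, mode="reflect"
                )
                f = perturbation_sd * (f - f.mean()) / max(f.std(), 1e-12)
            else:
                f = np.zeros(env.shape)
            perturb[name] = f
        for sc, dd in scenario_deltas.items():
            layers = {
                name: env.layers[name] + dd[name] + perturb[name] for name in env.names
            }
            futures[(gid, sc)] = env.with_layers(layers)
    return ScenarioSet(
        present=env,
        futures=futures,
        deltas={sc: dict(dd) for sc, dd in scenario_deltas.items()},
    )
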
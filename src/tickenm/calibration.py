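"""Candidate-model calibration and three-stage selection.

A calibration run enumerates candidate model configurations — feature
class combination x regularization multiplier x environmental variable
set — fits each on the calibration half of the occurrences, and filters
them sequentially:

1. **Statistical significance** by partial ROC: the model's partial AUC
   (restricted to sensitivities >= 1-E) is compared against the partial
   AUCs of repeated matched-size random-prediction samples; a model is
   significant when the AUC ratio exceeds 1 for nearly all draws.
2. **Performance** by omission rate: the fraction of evaluation records
   falling below the E-adjusted training-presence threshold must not
   exceed E (default 5%), the error level expected in the occurrence
   data.
3. **Complexity** by AICc on the maxent raw likelihood with ``k`` =
   nonzero coefficients; among significant, low-omission candidates,
   those within ``delta_max`` (default 2) AICc units of the minimum are
   selected.

The result is a candidate table (one row per configuration) with a
selected flag, mirroring the evaluation tables produced by calibration
packages such as kuenm.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .maxent import FEATURE_CLASSES, MaxentModel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration enumeration
# ---------------------------------------------------------------------------

def parse_multiplier_spec(spec: str) -> list[float]:
    """Parse a regularization-multiplier grid specification.

    Accepts semicolon-separated terms, each either a single value
    (``"8"``) or a range ``"a-b by s"`` / ``"a:b:s"``; values are
    deduplicated (so overlapping range endpoints such as 1 appearing in
    both ``0.1-1 by 0.1`` and ``1-6 by 1`` count once) and returned
    sorted. Example: ``"0.1-1 by 0.1; 1-6 by 1; 8; 10"`` -> 17 values.
    """
    values: set[float] = set()
    for term in spec.split(";"):
        term = term.strip().lower().replace("–", "-").replace("plus", "").replace("and", ";")
        if not term:
            continue
        for sub in term.split(";"):
            sub = sub.strip()
            if not sub:
                continue
            m = re.fullmatch(r"(-?\d*\.?\d+)\s*(?:-|to|:)\s*(-?\d*\.?\d+)\s*(?:by|:)\s*(\d*\.?\d+)", sub)
            if m:
                a, b, s = (float(g) for g in m.groups())
                if s <= 0 or b < a:
                    raise ValueError(f"bad range term {sub!r}")
                k = int(round((b - a) / s))
                pts = a + s * np.arange(k + 1)
                if pts[-1] < b - 1e-9:
                    pts = np.append(pts, b)
                values.update(round(float(p), 9) for p in pts)
            else:
                values.add(round(float(sub), 9))
    if not values:
        raise ValueError(f"no multipliers parsed from {spec!r}")
    out = sorted(values)
    if any(v <= 0 for v in out):
        raise ValueError("multipliers must be positive")
    return out


def all_class_combos() -> list[tuple[str, ...]]:
    """All 31 non-empty combinations of the five feature classes."""
    combos = []
    for r in range(1, len(FEATURE_CLASSES) + 1):
        combos.extend(itertools.combinations(FEATURE_CLASSES, r))
    return combos


@dataclass(frozen=True)
class CandidateSpec:
    """One candidate configuration: features x multiplier x variable set."""

    feature_classes: tuple[str, ...]
    beta_multiplier: float
    varset_id: str


@dataclass
class CandidateResult:
    """Per-candidate evaluation statistics driving selection."""

    spec: CandidateSpec
    mean_auc_ratio: float
    proc_p: float
    omission_rate: float
    omission_threshold: float
    aicc: float
    k_params: int
    delta_aicc: float = np.nan
    selected: bool = False
    converged: bool = True


def enumerate_candidates(
    class_combos: Sequence[Sequence[str]],
    multipliers: Sequence[float],
    varset_ids: Sequence[str],
) -> list[CandidateSpec]:
    """Cartesian product of configuration factors, stably ordered
    (variable set, class combo, multiplier)."""
    if not class_combos or not multipliers or not varset_ids:
        raise ValueError("every configuration factor must be non-empty")
    specs = []
    for vs in varset_ids:
        for combo in class_combos:
            for mult in multipliers:
                specs.append(CandidateSpec(tuple(combo), float(mult), str(vs)))
    if len({(s.feature_classes, s.beta_multiplier, s.varset_id) for s in specs}) != len(specs):
        raise ValueError("duplicate candidate configurations")
    return specs


# ---------------------------------------------------------------------------
# partial ROC
# ---------------------------------------------------------------------------

def _roc_thresholds(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct grid suitability values and the fractional predicted
    area (share of grid cells at or above each value)."""
    grid_sorted = np.sort(grid)
    thresholds, first_idx = np.unique(grid_sorted, return_index=True)
    area = 1.0 - first_idx / len(grid_sorted)
    return thresholds, area


def _partial_auc_ratio(test_suit: np.ndarray, thresholds: np.ndarray, area: np.ndarray, e_level: float) -> float:
    """AUC ratio for one set of test suitabilities against a grid.

    The ROC here plots sensitivity (fraction of test points at or above
    a threshold) against the fractional predicted area, sweeping
    thresholds over the grid values. Partial AUC integrates sensitivity
    over the area axis where sensitivity >= 1 - e_level; the null
    (random-prediction) partial AUC is the analytic integral of the
    diagonal (sensitivity = area) over the *same* clipped area domain,
    so the finite-sample staircase of the empirical sensitivity curve
    affects numerator and denominator alike.
    """
    n_test = len(test_suit)
    sens = 1.0 - np.searchsorted(np.sort(test_suit), thresholds, side="left") / n_test
    # sweep from low to high threshold: area and sensitivity both decrease
    x = np.concatenate(([1.0], area, [0.0]))
    y = np.concatenate(([1.0], sens, [0.0]))
    smin = 1.0 - e_level
    # y is non-increasing: the kept part is a prefix; interpolate the crossing
    i0 = int(np.searchsorted(-y, -smin, side="right"))  # first index with y < smin
    if i0 == 0:
        return np.nan
    xs, ys = x[:i0], y[:i0]
    if i0 < len(y) and y[i0 - 1] > y[i0]:
        f = (y[i0 - 1] - smin) / (y[i0 - 1] - y[i0])
        xs = np.append(xs, x[i0 - 1] + f * (x[i0] - x[i0 - 1]))
        ys = np.append(ys, smin)
    pauc = float(np.trapezoid(ys[::-1], xs[::-1]))
    x_lo = float(xs[-1])  # lower end of the integrated area domain
    null = (1.0 - x_lo**2) / 2.0
    if null <= 0:
        return np.nan
    return pauc / null


def partial_roc(
    test_suitabilities: np.ndarray,
    grid_suitabilities: np.ndarray,
    e_level: float = 0.05,
    n_boot: int = 500,
    boot_frac: float = 1.0,
    seed: int = 0,
) -> tuple[float, float]:
    """Partial-ROC significance test; returns (mean AUC ratio, p-value).

    Each of the ``n_boot`` iterations forms an AUC ratio: the partial
    AUC of the evaluation records divided by the partial AUC of a
    random-prediction sample of the same size drawn i.i.d. from the
    grid suitabilities. The p-value is the fraction of iterations with
    ratio <= 1. Estimating the null partial AUC from matched-size
    draws — rather than the analytic diagonal — makes numerator and
    denominator exchangeable under the null hypothesis, so the test is
    a Monte-Carlo rank test with rejection rate ~ alpha regardless of
    evaluation-set size (the finite-sample staircase of the empirical
    sensitivity curve biases both sides equally).

    With ``boot_frac`` = 1 (default) the observed partial AUC uses the
    full evaluation set every iteration, which keeps the test exactly
    calibrated; fractions below 1 additionally subsample the evaluation
    records per iteration (the traditional construction, conservative).
    A constant suitability grid has no ROC; the model is reported
    non-significant (ratio NaN, p 1).
    """
    test_suitabilities = np.asarray(test_suitabilities, dtype=float)
    grid = np.asarray(grid_suitabilities, dtype=float)
    grid = grid[np.isfinite(grid)]
    if len(test_suitabilities) < 10:
        raise ValueError("need at least 10 test points")
    if not 0 < e_level < 0.5:
        raise ValueError("E must be in (0, 0.5)")
    if not 0 < boot_frac <= 1:
        raise ValueError("boot_frac must be in (0, 1]")
    if np.ptp(grid) == 0:
        log.warning("partial_roc: constant suitability grid; model non-significant")
        return np.nan, 1.0
    thresholds, area = _roc_thresholds(grid)
    rng = np.random.default_rng(seed)
    n = len(test_suitabilities)
    m = max(1, int(np.ceil(boot_frac * n)))
    obs_full = _partial_auc_ratio(test_suitabilities, thresholds, area, e_level) if m == n else np.nan
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        if m < n:
            idx = rng.choice(n, size=m, replace=False)
            obs = _partial_auc_ratio(test_suitabilities[idx], thresholds, area, e_level)
        else:
            obs = obs_full
        null = _partial_auc_ratio(rng.choice(grid, size=m, replace=True), thresholds, area, e_level)
        ratios[b] = obs / null
    ok = np.isfinite(ratios)
    if not ok.any():
        return np.nan, 1.0
    mean_ratio = float(np.mean(ratios[ok]))
    p = float(np.mean(ratios[ok] <= 1.0))
    return mean_ratio, p


# ---------------------------------------------------------------------------
# omission rate and AICc
# ---------------------------------------------------------------------------

def omission_rate(
    cal_suitabilities: np.ndarray,
    eval_suitabilities: np.ndarray,
    e_level: float = 0.05,
) -> tuple[float, float]:
    """E-adjusted training-presence threshold and evaluation omission rate.

    The threshold is the ``ceil(E * n_cal)``-th smallest calibration
    suitability — the value that excludes the lowest E fraction of the
    calibration records. The omission rate is the fraction of
    evaluation suitabilities strictly below it (equality retained).
    """
    cal = np.sort(np.asarray(cal_suitabilities, dtype=float))
    ev = np.asarray(eval_suitabilities, dtype=float)
    if len(cal) == 0 or len(ev) == 0:
        raise ValueError("calibration and evaluation suitabilities must be non-empty")
    if not 0 < e_level < 1:
        raise ValueError("E must be in (0, 1)")
    rank = int(np.ceil(e_level * len(cal)))  # 1-indexed order statistic
    threshold = float(cal[max(rank - 1, 0)])
    rate = float(np.mean(ev < threshold))
    return threshold, rate


def compute_aicc(
    model: MaxentModel,
    occurrence_raw: np.ndarray,
    grid_raw_sum: float,
) -> tuple[float, int]:
    """AICc from the maxent raw likelihood.

    Raw scores are renormalized over the full calibration grid
    (``grid_raw_sum``); ``ln L = sum ln(raw_i / grid_raw_sum)`` over
    the occurrences and ``k`` counts nonzero coefficients. The
    small-sample correction diverges at ``k >= n - 1`` and a zero raw
    score makes the likelihood undefined; both yield +inf.
    """
    raw = np.asarray(occurrence_raw, dtype=float)
    n = len(raw)
    k = model.k
    if n == 0 or grid_raw_sum <= 0:
        raise ValueError("need occurrences and a positive grid raw sum")
    if np.any(raw <= 0):
        log.warning("compute_aicc: zero raw score at an occurrence; AICc = +inf")
        return np.inf, k
    if k >= n - 1:
        return np.inf, k
    lnl = float(np.sum(np.log(raw / grid_raw_sum)))
    aicc = 2.0 * k - 2.0 * lnl + (2.0 * k * (k + 1.0)) / (n - k - 1.0)
    return aicc, k


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select_models(
    results: Sequence[CandidateResult],
    alpha: float = 0.05,
    omission_max: float = 0.05,
    delta_max: float = 2.0,
) -> list[CandidateResult]:
    """Three-stage sequential filter; returns selected results with ΔAICc filled.

    (1) keep partial-ROC p < alpha; (2) keep omission <= omission_max;
    (3) among survivors, keep ΔAICc <= delta_max from the stage-(1)+(2)
    minimum (ties kept). An empty selection at any stage returns [],
    never raises. Selection is invariant to the input order.
    """
    if not results:
        raise ValueError("no candidate results")
    significant = [r for r in results if np.isfinite(r.proc_p) and r.proc_p < alpha]
    low_omission = [r for r in significant if r.omission_rate <= omission_max]
    if not low_omission:
        log.warning(
            "select_models: empty selection (%d significant, 0 low-omission)", len(significant)
        )
        return []
    finite = [r for r in low_omission if np.isfinite(r.aicc)]
    if not finite:
        log.warning("select_models: no survivor has finite AICc")
        return []
    amin = min(r.aicc for r in finite)
    selected = []
    for r in finite:
        r.delta_aicc = r.aicc - amin
        if r.delta_aicc <= delta_max:
            r.selected = True
            selected.append(r)
    return selected


def results_table(results: Sequence[CandidateResult]) -> pd.DataFrame:
    """Candidate table, one row per configuration (mirrors a kuenm-style report)."""
    rows = []
    for r in results:
        rows.append(
            {
                "varset": r.spec.varset_id,
                "feature_classes": "+".join(r.spec.feature_classes),
                "beta_multiplier": r.spec.beta_multiplier,
                "mean_auc_ratio": r.mean_auc_ratio,
                "proc_p": r.proc_p,
                "omission_rate": r.omission_rate,
                "omission_threshold": r.omission_threshold,
                "k": r.k_params,
                "aicc": r.aicc,
                "delta_aicc": r.delta_aicc,
                "selected": r.selected,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)
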
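"""Sequential jackknife reduction of the environmental variable set.

Candidate variable sets are built by repeatedly dropping the least
informative variables: each variable's contribution is the drop in
regularized training gain when that variable is left out and the model
refit, and the lowest-contribution variables are removed until each
requested target size, yielding a strictly nested sequence of sets
(e.g. 11 -> 7 -> 4 variables) for the calibration stage to compare.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maxent import FeatureSpec, build_feature_spec, expand_features, fit_maxent

log = logging.getLogger(__name__)


@dataclass
class VariableSetSequence:
    """Strictly nested variable sets of decreasing size, with the
    per-step contribution tables that produced them."""

    sets: list[list[str]]
    contribution_tables: list[pd.DataFrame]

    def __post_init__(self):
        for a, b in zip(self.sets, self.sets[1:]):
            if not set(b) < set(a):
                raise ValueError("variable sets must be strictly nested")
        if not self.sets[-1]:
            raise ValueError("final variable set is empty")


def _regularized_gain(presences: np.ndarray, background: np.ndarray, var_names, classes, beta) -> float:
    """Regularized training gain of a fit on the given variables.

    Gain is the mean presence log-density relative to the uniform
    background density (so a no-signal model scores 0), minus the
    per-presence L1 penalty.
    """
    spec = build_feature_spec(classes, var_names, background, presences)
    model = fit_maxent(presences, background, spec, beta)
    Fp, _, _, _ = expand_features(presences, spec)
    eta = Fp @ model.lambdas
    n = len(presences)
    mean_log_q = float(np.mean(eta)) - model.log_density_normalizer
    penalty = float(model.betas @ np.abs(model.lambdas)) / n
    return mean_log_q + np.log(model.n_background) - penalty


def jackknife_contributions(
    presences: np.ndarray,
    background: np.ndarray,
    variables: list[str],
    classes=("linear", "quadratic"),
    beta_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Leave-one-out contribution of each variable to the training gain.

    The matrices carry one column per name in ``variables``. A fit
    failure on a leave-one-out model leaves that variable's score NaN.
    """
    if len(variables) < 2:
        raise ValueError("need at least 2 variables to jackknife")
    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    full_gain = _regularized_gain(presences, background, variables, classes, beta_multiplier)
    rows = []
    for j, v in enumerate(variables):
        keep = [i for i in range(len(variables)) if i != j]
        names = [variables[i] for i in keep]
        try:
            gain_wo = _regularized_gain(presences[:, keep], background[:, keep], names, classes, beta_multiplier)
            contrib = full_gain - gain_wo
        except Exception as exc:
            log.warning("jackknife: leave-out fit failed for %r: %s", v, exc)
            gain_wo, contrib = np.nan, np.nan
        rows.append({"variable": v, "gain_without": gain_wo, "contribution": contrib})
    df = pd.DataFrame(rows)
    df["full_gain"] = full_gain
    return df


def sequential_reduce(
    presences: np.ndarray,
    background: np.ndarray,
    variables: list[str],
    target_sizes: list[int],
    classes=("linear", "quadratic"),
    beta_multiplier: float = 1.0,
) -> VariableSetSequence:
    """Drop least-contributing variables stepwise to each target size.

    ``target_sizes`` must be strictly decreasing and at most the
    variable count. At each step, contributions are recomputed on the
    current set, and the lowest-scoring variables (ties broken
    alphabetically; NaN scores treated as lowest) are removed down to
    the next target; a snapshot is recorded at every target size.
    """
    if not target_sizes or any(b >= a for a, b in zip(target_sizes, target_sizes[1:])):
        raise ValueError("target sizes must be strictly decreasing")
    if target_sizes[0] > len(variables) or target_sizes[-1] < 1:
        raise ValueError(f"unreachable target size in {target_sizes} for {len(variables)} variables")
    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    current = list(variables)
    col = {v: i for i, v in enumerate(variables)}
    sets = [list(current)]
    tables = []
    for target in target_sizes:
        while len(current) > target:
            idx = [col[v] for v in current]
            table = jackknife_contributions(
                presences[:, idx], background[:, idx], current, classes, beta_multiplier
            )
            tables.append(table)
            scored = table.assign(
                sort_key=table["contribution"].fillna(-np.inf)
            ).sort_values(["sort_key", "variable"], ascending=[True, True])
            n_drop = min(len(current) - target, max(1, len(current) - target))
            drop = list(scored["variable"].iloc[:n_drop])
            log.info("sequential_reduce: dropping %s", drop)
            current = [v for v in current if v not in drop]
        sets.append(list(current))
    return VariableSetSequence(sets=sets, contribution_tables=tables)
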
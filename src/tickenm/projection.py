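"""Model transfer to new regions/scenarios and GCM-agreement composites.

Selected models are transferred (identical math to prediction, with
clamping against the training ranges) onto present-day and future
climate stacks; the replicate-median surfaces are thresholded into
binary suitable/unsuitable maps, and agreement across the general
circulation models is summarized per RCP scenario into a single
integer-class map:

* class 0  — no change signal (suitable in both epochs for all GCMs,
  or unsuitable in both),
* classes 1-4 — 1..4 GCMs predict newly suitable area (gain),
* classes 5-8 — 1..4 GCMs predict loss of presently suitable area.

Gain and loss are mutually exclusive per cell by construction (both are
judged against the same present-day binary map); per-RCP outputs are
kept separate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .envstack import EnvStack
from .maxent import MaxentModel, SuitabilityGrid, predict

log = logging.getLogger(__name__)


def transfer(
    model: MaxentModel,
    scenario_env: EnvStack,
    region_mask: np.ndarray | None = None,
    clamp: bool = True,
    output_scale: str = "cloglog",
) -> SuitabilityGrid:
    """Project a fitted model onto another climate stack.

    Same computation as prediction on the training stack; the clamped
    mask marks cells whose scenario values fall outside the training
    range of any model variable.
    """
    return predict(model, scenario_env, region_mask=region_mask, clamp=clamp, output_scale=output_scale)


def binarize(grid: SuitabilityGrid, threshold: float) -> np.ndarray:
    """Binary suitability: cell suitable iff suitability >= threshold.

    The threshold should come from the E-adjusted training-presence
    rule on the calibration records. Returns a boolean grid (False
    outside the valid mask); warns when the threshold sits outside the
    observed range (all-0 or all-1 map).
    """
    vals = grid.values
    out = np.zeros(vals.shape, dtype=bool)
    m = grid.valid_mask
    out[m] = vals[m] >= threshold
    if m.any():
        if threshold > np.nanmax(vals[m]):
            log.warning("binarize: threshold above all suitabilities; empty map")
        elif threshold <= np.nanmin(vals[m]):
            log.warning("binarize: threshold at/below all suitabilities; saturated map")
    return out


@dataclass
class AgreementMap:
    """Integer change-agreement classes over a grid (see module docstring)."""

    classes: np.ndarray
    n_gcm: int
    legend: dict[int, str]


def gcm_agreement(
    present_binary: np.ndarray,
    future_binaries: Sequence[np.ndarray],
    max_gcm: int = 4,
) -> AgreementMap:
    """Per-cell agreement of GCM-wise change against the present-day map.

    ``future_binaries`` holds one binary map per GCM under a single
    scenario (1 to ``max_gcm`` of them). Gain = future suitable where
    presently unsuitable; loss = future unsuitable where presently
    suitable. Class = gain count (1..n), or ``max_gcm`` + loss count
    (5..8 for four GCMs), or 0 when no GCM signals change. A cell can
    never carry both signals since both comparisons use the same
    present-day map. Permutation-invariant in the GCM order.
    """
    futures = [np.asarray(f, dtype=bool) for f in future_binaries]
    if not 1 <= len(futures) <= max_gcm:
        raise ValueError(f"need 1..{max_gcm} future maps, got {len(futures)} (extend max_gcm to override)")
    present = np.asarray(present_binary, dtype=bool)
    for f in futures:
        if f.shape != present.shape:
            raise ValueError("future map not co-registered with present map")
    gain = np.zeros(present.shape, dtype=int)
    loss = np.zeros(present.shape, dtype=int)
    for f in futures:
        gain += (f & ~present).astype(int)
        loss += (~f & present).astype(int)
    conflict = (gain > 0) & (loss > 0)
    if conflict.any():  # impossible under a single present map; guard for caller-mixed inputs
        log.warning("gcm_agreement: %d cell(s) with mixed gain/loss; gain takes precedence", int(conflict.sum()))
        loss[conflict] = 0
    classes = np.where(gain > 0, gain, np.where(loss > 0, max_gcm + loss, 0))
    legend = {0: "no change signal"}
    for i in range(1, max_gcm + 1):
        legend[i] = f"{i} GCM(s) predict newly suitable"
    for i in range(1, max_gcm + 1):
        legend[max_gcm + i] = f"{i} GCM(s) predict loss of suitable area"
    return AgreementMap(classes=classes, n_gcm=len(futures), legend=legend)
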
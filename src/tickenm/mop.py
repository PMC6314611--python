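"""Mobility-oriented parity (MOP): environmental novelty of transfer regions.

MOP measures, for every cell of a projection region, how far its
climate lies from the most similar conditions in the calibration
region: the mean Euclidean distance (on calibration-standardized
variables) to the nearest ``reference_fraction`` of calibration cells,
rescaled to a similarity in [0, 1] (1 = identical to calibration
conditions). Cells with any variable outside the calibration min-max
range are flagged as *strict extrapolation* — model output there rests
on no calibration information and deserves no interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)


@dataclass
class MopResult:
    """Continuous similarity surface plus strict-extrapolation mask (flat, per projection cell)."""

    similarity: np.ndarray
    strict_mask: np.ndarray
    distances: np.ndarray


def mop(
    calibration_cells: np.ndarray,
    projection_cells: np.ndarray,
    reference_fraction: float = 0.1,
    max_calibration_cells: int = 10_000,
    seed: int = 0,
    chunk: int = 2000,
) -> MopResult:
    """Compute the MOP similarity of projection cells to calibration climate.

    Both inputs are value matrices over the same variable set.
    Variables are standardized by calibration mean/sd before the
    distance computation; the strict-extrapolation test uses the raw
    (unstandardized) calibration min/max. For each projection cell the
    distance is the mean to its nearest ``ceil(reference_fraction *
    n_calib)`` calibration cells; similarity = 1 - distance / max
    distance over projection cells (identically-distributed regions,
    max distance 0, report similarity 1). Calibration clouds larger
    than ``max_calibration_cells`` are subsampled with ``seed``.
    """
    calib = np.atleast_2d(np.asarray(calibration_cells, dtype=float))
    proj = np.atleast_2d(np.asarray(projection_cells, dtype=float))
    if calib.size == 0 or len(calib) == 0:
        raise ValueError("empty calibration set")
    if calib.shape[1] != proj.shape[1]:
        raise ValueError("variable mismatch between calibration and projection")
    if not 0 < reference_fraction <= 1:
        raise ValueError("reference_fraction must be in (0, 1]")
    lo = calib.min(axis=0)
    hi = calib.max(axis=0)
    strict = ((proj < lo) | (proj > hi)).any(axis=1)
    if len(calib) > max_calibration_cells:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(calib), size=max_calibration_cells, replace=False))
        calib = calib[idx]
        log.info("mop: subsampled calibration cloud to %d cells", max_calibration_cells)
    mu = calib.mean(axis=0)
    sd = calib.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    calib_z = (calib - mu) / sd
    proj_z = (proj - mu) / sd
    k = int(np.ceil(reference_fraction * len(calib_z)))
    dists = np.empty(len(proj_z))
    for start in range(0, len(proj_z), chunk):
        d = cdist(proj_z[start : start + chunk], calib_z)
        d.partition(k - 1, axis=1)
        dists[start : start + chunk] = d[:, :k].mean(axis=1)
    dmax = dists.max(initial=0.0)
    similarity = 1.0 - dists / dmax if dmax > 0 else np.ones_like(dists)
    return MopResult(similarity=similarity, strict_mask=strict, distances=dists)


def mop_agreement(results: Sequence[MopResult]) -> np.ndarray:
    """Per-cell count of GCMs whose strict-extrapolation mask is set."""
    if not results:
        raise ValueError("need at least one MOP result")
    shapes = {r.strict_mask.shape for r in results}
    if len(shapes) != 1:
        raise ValueError("MOP results are not co-registered")
    return np.sum([r.strict_mask.astype(int) for r in results], axis=0)
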
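"""Occurrence-record cleaning: uncertainty filtering, spatial rarefaction, splitting.

Museum/surveillance point records arrive as delimited text with
longitude/latitude (decimal degrees, WGS84) and a georeferencing
uncertainty radius in meters. The cleaning sequence mirrors standard
niche-modeling practice for such data:

1. drop unparseable coordinates,
2. drop records lacking uncertainty or with uncertainty above a cap
   (default 10,000 m, matching the grid resolution being modeled),
3. spatially rarefy ("thin") so retained records are at least a minimum
   great-circle distance apart (default 50 km), damping sampling-effort
   clustering,
4. split randomly into equal calibration and evaluation halves.

Order matters and is enforced by the pipeline driver: the uncertainty
filter runs before thinning, so poor records never displace good ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geo import pairwise_distance_km

log = logging.getLogger(__name__)

_REQUIRED = ("longitude", "latitude")
_COLUMNS = ["species", "longitude", "latitude", "uncertainty_m", "source_id"]

# accepted aliases for the required columns in input files
_ALIASES = {
    "longitude": {"longitude", "lon", "long", "x", "decimallongitude"},
    "latitude": {"latitude", "lat", "y", "decimallatitude"},
    "uncertainty_m": {"uncertainty_m", "uncertainty", "coordinateuncertaintyinmeters", "error_m"},
    "species": {"species", "name", "taxon"},
    "source_id": {"source_id", "id", "record_id"},
}


@dataclass
class OccurrenceSet:
    """Ordered presence-only point records in WGS84 lon/lat.

    Backed by a pandas DataFrame with columns
    ``species, longitude, latitude, uncertainty_m, source_id``;
    ``uncertainty_m`` is NaN when the record carries no uncertainty
    information. Record order is stable under I/O round-trips.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.df.copy()
        for c in _COLUMNS:
            if c not in df.columns:
                df[c] = np.nan if c == "uncertainty_m" else ""
        self.df = df[_COLUMNS].reset_index(drop=True)
        lon = self.df["longitude"].to_numpy(dtype=float)
        lat = self.df["latitude"].to_numpy(dtype=float)
        if len(lon) and (
            np.nanmax(np.abs(lon), initial=0) > 180 or np.nanmax(np.abs(lat), initial=0) > 90
        ):
            raise ValueError("coordinates outside WGS84 bounds")
        unc = self.df["uncertainty_m"].to_numpy(dtype=float)
        if np.any(unc[np.isfinite(unc)] < 0):
            raise ValueError("negative uncertainty radius")

    def __len__(self) -> int:
        return len(self.df)

    def lonlat(self):
        return (
            self.df["longitude"].to_numpy(dtype=float),
            self.df["latitude"].to_numpy(dtype=float),
        )

    def take(self, index: Sequence[int]) -> "OccurrenceSet":
        return OccurrenceSet(self.df.iloc[list(index)])

    def drop_duplicates(self) -> "OccurrenceSet":
        return OccurrenceSet(self.df.drop_duplicates(subset=["longitude", "latitude"], keep="first"))

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Parse a delimited text file of occurrence records.

    Column names are matched case-insensitively against common aliases
    (lon/long/x, lat/y, uncertainty/coordinateUncertaintyInMeters...).
    Rows with unparseable or out-of-range coordinates are dropped with a
    logged count; missing uncertainty is retained as absent (NaN).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no records")
    rename = {}
    lowered = {c.lower().strip(): c for c in df.columns}
    for canon, aliases in _ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                rename[lowered[alias]] = canon
                break
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    n0 = len(df)
    df["longitude"] = pd.to_numeric(df["longitude"], errors="coerce")
    df["latitude"] = pd.to_numeric(df["latitude"], errors="coerce")
    if "uncertainty_m" in df.columns:
        df["uncertainty_m"] = pd.to_numeric(df["uncertainty_m"], errors="coerce")
    ok = (
        df["longitude"].between(-180, 180)
        & df["latitude"].between(-90, 90)
        & df["longitude"].notna()
        & df["latitude"].notna()
    )
    dropped = int(n0 - ok.sum())
    if dropped:
        log.info("read_occurrences: dropped %d row(s) with invalid coordinates", dropped)
    df = df[ok]
    if df.empty:
        raise ValueError(f"{path}: no rows with valid coordinates")
    return OccurrenceSet(df)


def filter_uncertainty(occ: OccurrenceSet, max_m: float = 10_000.0) -> OccurrenceSet:
    """Remove records lacking uncertainty information or with uncertainty > ``max_m``.

    The boundary is inclusive: a record at exactly ``max_m`` is kept.
    Relative order is preserved.
    """
    if max_m <= 0:
        raise ValueError("max_m must be positive")
    unc = occ.df["uncertainty_m"].to_numpy(dtype=float)
    keep = np.isfinite(unc) & (unc <= max_m)
    removed = int(len(occ) - keep.sum())
    log.info("filter_uncertainty: removed %d of %d record(s)", removed, len(occ))
    return OccurrenceSet(occ.df[keep])


def exclude_sources(occ: OccurrenceSet, source_ids: Iterable[str]) -> OccurrenceSet:
    """Drop records whose source_id is on an expert exclusion list.

    Out-of-range or unverifiable records identified by expert judgment
    (not algorithmic rules) are supplied as data, not hard-coded.
    """
    ids = {str(s) for s in source_ids}
    keep = ~occ.df["source_id"].astype(str).isin(ids)
    log.info("exclude_sources: removed %d record(s)", int((~keep).sum()))
    return OccurrenceSet(occ.df[keep])


def thin_occurrences(occ: OccurrenceSet, min_km: float = 50.0, seed: int | None = 0) -> OccurrenceSet:
    """Spatially rarefy so every retained pair is >= ``min_km`` apart (great circle).

    Iterative greedy deletion: repeatedly remove the record with the
    most neighbors closer than ``min_km``; ties broken by larger summed
    inverse-distance crowding, then by later input position. A final
    re-add pass (input order) restores any removed record that no
    longer conflicts, making the result maximal: no removed point can
    be re-added without violating the constraint. Fully deterministic;
    ``seed`` is accepted for interface symmetry but the rule above
    leaves no random ties in practice.
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    n = len(occ)
    if n <= 1:
        return occ
    lons, lats = occ.lonlat()
    d = pairwise_distance_km(lons, lats)
    np.fill_diagonal(d, np.inf)
    conflict = d < min_km
    with np.errstate(divide="ignore"):
        inv = np.where(conflict, 1.0 / np.maximum(d, 1e-9), 0.0)
    alive = np.ones(n, dtype=bool)
    degree = conflict.sum(axis=1).astype(float)
    crowd = inv.sum(axis=1)
    while True:
        if degree[alive].max(initial=0) == 0:
            break
        # worst offender: highest degree, then highest crowding, then latest input position
        cand = np.flatnonzero(alive)
        key = np.lexsort((cand, crowd[cand], degree[cand]))
        worst = cand[key[-1]]
        alive[worst] = False
        nb = conflict[worst] & alive
        degree[nb] -= 1
        crowd[nb] -= inv[worst, nb]
    # maximality pass: re-admit removed points that fit, in input order
    for i in np.flatnonzero(~alive):
        if not conflict[i, alive].any():
            alive[i] = True
    kept = np.flatnonzero(alive)
    log.info("thin_occurrences: kept %d of %d record(s) at >=%g km", len(kept), n, min_km)
    return occ.take(kept)


def split_half(occ: OccurrenceSet, seed: int = 0) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random equal-halves split into (calibration, evaluation) sets.

    Disjoint, union equals the input; for odd counts the calibration
    half receives the extra record. Deterministic given ``seed``.
    """
    n = len(occ)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = (n + 1) // 2
    cal = np.sort(perm[:n_cal])
    ev = np.sort(perm[n_cal:])
    return occ.take(cal), occ.take(ev)
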
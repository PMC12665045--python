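"""Short- versus long-range connection profiling.

A connection between two regions is *short-range* when the Euclidean
distance between their barycenters is at most a physical threshold
``thQ`` (mm), and *long-range* when it is larger.  Only connected pairs
are counted: for node i,

    S_SR(i) = #{ j : A[i, j] = 1 and T[i, j] <= thQ }
    S_LR(i) = #{ j : A[i, j] = 1 and T[i, j] >  thQ }

Profiles are computed within connectivity-probability bands — high
(CP > 0.7), moderate (0.5 < CP <= 0.7) and low (0.3 < CP <= 0.5) — taken
as half-open intervals so every suprathreshold edge falls in exactly one
band.

The distance threshold ``thQ`` defaults to the median off-diagonal
pairwise barycenter distance of the subject, a relative choice that
adapts across fetal and adult brain sizes; an absolute override in mm is
accepted and recorded in run metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .connectivity import AdjacencyMatrix, ConnectivityMatrix, symmetrize
from .errors import ConfigError, ValidationError
from .rois import DistanceMatrix


class Band(NamedTuple):
    """Half-open CP interval (lo, hi]."""

    name: str
    lo: float
    hi: float


DEFAULT_BANDS: tuple[Band, ...] = (
    Band("low", 0.3, 0.5),
    Band("moderate", 0.5, 0.7),
    Band("high", 0.7, 1.0),
)


@dataclass(frozen=True)
class RangeProfile:
    """Short/long-range connection counts of one node within one CP band."""

    abbrev: str
    band: str
    n_short: int
    n_long: int
    thq_mm: float


def default_thq(t: DistanceMatrix) -> float:
    """Median of the off-diagonal upper-triangle distances, in mm."""
    n = len(t.labels)
    if n < 2:
        raise ConfigError("thQ default needs at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float(np.median(t.values[iu]))


def count_ranges(a_band: AdjacencyMatrix, t: DistanceMatrix,
                 thq: float) -> pd.DataFrame:
    """Per-node (S_SR, S_LR) counts over a band-restricted adjacency."""
    if thq <= 0:
        raise ConfigError(f"thQ must be positive, got {thq}")
    if a_band.labels != t.labels:
        raise ValidationError("adjacency and distance matrix label mismatch")
    conn = a_band.a.astype(bool)
    short = (conn & (t.values <= thq)).sum(axis=1)
    long_ = (conn & (t.values > thq)).sum(axis=1)
    return pd.DataFrame({"abbrev": a_band.labels,
                         "n_short": short.astype(int),
                         "n_long": long_.astype(int)})


def band_adjacency(c: ConnectivityMatrix, band: Band,
                   mode: str = "max") -> AdjacencyMatrix:
    """Adjacency of seed pairs whose symmetrized CP falls in (lo, hi]."""
    sym = symmetrize(c.seed_block(), mode=mode)
    a = ((sym > band.lo) & (sym <= band.hi)).astype(np.int8)
    np.fill_diagonal(a, 0)
    return AdjacencyMatrix(labels=list(c.seeds), a=a, threshold_used=band.lo)


def _check_bands(bands: Sequence[Band]) -> None:
    ordered = sorted(bands, key=lambda b: b.lo)
    for b in ordered:
        if not (0 <= b.lo < b.hi <= 1):
            raise ConfigError(f"band {b.name}: invalid interval ({b.lo}, {b.hi}]")
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.lo < prev.hi:
            raise ConfigError(f"bands {prev.name} and {nxt.name} overlap")


def band_profiles(c: ConnectivityMatrix, t: DistanceMatrix,
                  thq: float | None = None,
                  bands: Sequence[Band] = DEFAULT_BANDS,
                  mode: str = "max") -> list[RangeProfile]:
    """One RangeProfile per seed node per CP band."""
    _check_bands(bands)
    t_seed = t.submatrix(c.seeds)
    if thq is None:
        thq = default_thq(t_seed)
    profiles: list[RangeProfile] = []
    for band in bands:
        counts = count_ranges(band_adjacency(c, band, mode=mode), t_seed, thq)
        for row in counts.itertuples(index=False):
            profiles.append(RangeProfile(abbrev=row.abbrev, band=band.name,
                                         n_short=int(row.n_short),
                                         n_long=int(row.n_long),
                                         thq_mm=float(thq)))
    return profiles


def profiles_to_frame(profiles: Sequence[RangeProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.abbrev, p.band, p.n_short, p.n_long, p.thq_mm) for p in profiles],
        columns=["abbrev", "band", "n_short", "n_long", "thq_mm"],
    )
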
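"""Connectivity-probability matrices from probabilistic-tractography counts.

The connectivity probability (CP) from seed region A to target region B is
the fraction of probabilistic streamlines launched from A that reach B:

    CP(A -> B) = n_connecting(A, B) / n_launched(A)

CP values live in [0, 1]; the matrix C[i, j] = CP(R_i -> R_j) is the
central quantitative object of the pipeline.  Because seeding only happens
from the N AAN seed regions while targets may include cortical regions, C
is in general rectangular (N seeds x M targets, with the first N targets
equal to the seeds).

Two regions are considered structurally connected when CP exceeds a
threshold ``th``; the resulting adjacency matrix is binary, symmetric and
zero-diagonal.  Tractography is directional, so the seed-block CP matrix
is asymmetric; before thresholding it is symmetrized (default: ``max`` —
a tract detected from either seeding direction is evidence of the same
anatomical connection).  No pathway-length correction is applied to CP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .rois import RoiTable

SYMMETRIZATION_MODES = ("max", "mean", "directed_or")

#: CP threshold used for graph construction throughout the analysis.
DEFAULT_THRESHOLD = 0.5

#: Base of the logarithm used for display transforms (decades).
LOG_BASE = 10


@dataclass
class StreamlineCounts:
    """Per-subject streamline counts: the raw tractography surrogate.

    ``connecting[i, j]`` streamlines launched from seed i reached target j;
    ``launched[i]`` streamlines were launched from seed i in total.
    """

    seeds: list[str]
    targets: list[str]
    connecting: np.ndarray
    launched: np.ndarray

    def __post_init__(self) -> None:
        self.connecting = np.asarray(self.connecting)
        self.launched = np.asarray(self.launched)
        n, m = len(self.seeds), len(self.targets)
        if self.targets[:n] != self.seeds:
            raise ValidationError("first targets must equal the seed list, in order")
        if self.connecting.shape != (n, m):
            raise ValidationError(
                f"connecting matrix shape {self.connecting.shape} != ({n}, {m})")
        if self.launched.shape != (n,):
            raise ValidationError("launched vector length must match seeds")
        if not np.issubdtype(self.connecting.dtype, np.integer):
            raise ValidationError("connecting counts must be integers")
        if (self.connecting < 0).any():
            raise ValidationError("connecting counts must be nonnegative")
        if (self.launched <= 0).any():
            bad = [self.seeds[i] for i in np.where(self.launched <= 0)[0]]
            raise ValidationError(f"launched must be positive; violated by {bad}")
        over = self.connecting > self.launched[:, None]
        if over.any():
            i, j = np.argwhere(over)[0]
            raise ValidationError(
                f"connecting > launched for seed {self.seeds[i]} -> target "
                f"{self.targets[j]} ({self.connecting[i, j]} > {self.launched[i]})")

    def to_tsv(self, counts_path, launched_path) -> None:
        pd.DataFrame(self.connecting, index=pd.Index(self.seeds, name="seed"),
                     columns=self.targets).to_csv(counts_path, sep="\t")
        pd.DataFrame({"abbrev": self.seeds, "launched": self.launched}
                     ).to_csv(launched_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, launched_path) -> "StreamlineCounts":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        side = pd.read_csv(launched_path, sep="\t")
        seeds = [str(s) for s in df.index]
        launched = side.set_index("abbrev")["launched"].reindex(seeds)
        if launched.isna().any():
            missing = [s for s in seeds if s not in set(side["abbrev"].astype(str))]
            raise ValidationError(f"{launched_path}: missing launched totals for {missing}")
        return cls(seeds=seeds, targets=[str(t) for t in df.columns],
                   connecting=df.to_numpy(dtype=np.int64),
                   launched=launched.to_numpy(dtype=np.int64))


@dataclass
class ConnectivityMatrix:
    """CP matrix ``cp[i, j] = CP(seed_i -> target_j)``, values in [0, 1]."""

    seeds: list[str]
    targets: list[str]
    cp: np.ndarray

    def __post_init__(self) -> None:
        self.cp = np.asarray(self.cp, dtype=float)
        n, m = len(self.seeds), len(self.targets)
        if self.targets[:n] != self.seeds:
            raise ValidationError("first targets must equal the seed list, in order")
        if self.cp.shape != (n, m):
            raise ValidationError(f"cp shape {self.cp.shape} != ({n}, {m})")
        if (self.cp < 0).any() or (self.cp > 1).any():
            raise ValidationError("cp values must lie in [0, 1]")

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    def seed_block(self) -> np.ndarray:
        """The square seed x seed sub-matrix (directed CP)."""
        return self.cp[:, : self.n_seeds]

    def loc(self, seed: str, target: str) -> float:
        try:
            i = self.seeds.index(seed)
        except ValueError:
            raise KeyError(f"unknown seed ROI {seed!r}") from None
        try:
            j = self.targets.index(target)
        except ValueError:
            raise KeyError(f"unknown target ROI {target!r}") from None
        return float(self.cp[i, j])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.cp, index=pd.Index(self.seeds, name="seed"),
                     columns=self.targets).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(seeds=[str(s) for s in df.index],
                   targets=[str(t) for t in df.columns],
                   cp=df.to_numpy(dtype=float))


@dataclass
class AdjacencyMatrix:
    """Binary, symmetric, zero-diagonal adjacency over one node set."""

    labels: list[str]
    a: np.ndarray
    threshold_used: float = field(default=DEFAULT_THRESHOLD)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int8)
        n = len(self.labels)
        if self.a.shape != (n, n):
            raise ValidationError("adjacency shape does not match labels")
        if not np.isin(self.a, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0/1")
        if (self.a != self.a.T).any():
            raise ValidationError("adjacency must be symmetric")
        if np.diag(self.a).any():
            raise ValidationError("adjacency diagonal must be zero")

    def degree_vector(self) -> np.ndarray:
        return self.a.sum(axis=1).astype(int)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.a, index=pd.Index(self.labels, name="abbrev"),
                     columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, threshold_used: float = DEFAULT_THRESHOLD) -> "AdjacencyMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(s) for s in df.index],
                   a=df.to_numpy(dtype=np.int8), threshold_used=threshold_used)


def compute_cp_matrix(counts: StreamlineCounts) -> ConnectivityMatrix:
    """CP(i -> j) = connecting[i, j] / launched[i]."""
    cp = counts.connecting / counts.launched[:, None]
    return ConnectivityMatrix(seeds=list(counts.seeds),
                              targets=list(counts.targets), cp=cp)


def log_transform(c: ConnectivityMatrix) -> np.ma.MaskedArray:
    """log10 of CP for display; zero entries are masked, not -inf.

    Streamline likelihood decays with path length, so a log scale makes
    weak long-distance connections visible alongside strong local ones.
    """
    cp = c.cp
    masked = np.ma.masked_where(cp <= 0, cp)
    return np.ma.log10(masked)


def symmetrize(block: np.ndarray, mode: str = "max") -> np.ndarray:
    """Reconcile the two directed CP estimates of each seed pair.

    ``max`` (and its alias ``directed_or``): an edge detected from either
    seeding direction counts at its stronger value.  ``mean``: average of
    the two directions.
    """
    if mode not in SYMMETRIZATION_MODES:
        raise ConfigError(f"unknown symmetrization mode {mode!r}; "
                          f"choose from {SYMMETRIZATION_MODES}")
    block = np.asarray(block, dtype=float)
    if block.shape[0] != block.shape[1]:
        raise ValidationError("symmetrize requires a square block")
    if mode == "mean":
        return (block + block.T) / 2.0
    return np.maximum(block, block.T)


def binarize(c: ConnectivityMatrix, th: float = DEFAULT_THRESHOLD,
             mode: str = "max") -> AdjacencyMatrix:
    """Threshold the symmetrized seed block: edge iff CP strictly > ``th``."""
    if not (0 <= th < 1):
        raise ConfigError(f"threshold must satisfy 0 <= th < 1, got {th}")
    sym = symmetrize(c.seed_block(), mode=mode)
    a = (sym > th).astype(np.int8)
    np.fill_diagonal(a, 0)
    adj = AdjacencyMatrix(labels=list(c.seeds), a=a, threshold_used=th)
    assert (adj.a == adj.a.T).all() and not np.diag(adj.a).any()
    return adj


def order_rostrocaudal(c: ConnectivityMatrix, rois: RoiTable) -> ConnectivityMatrix:
    """Permute rows and columns from rostral (top/left) to caudal."""
    unknown = [s for s in set(c.seeds) | set(c.targets) if s not in rois]
    if unknown:
        raise ValidationError(f"ROIs absent from ROI table: {sorted(unknown)}")
    seed_order = rois.rostrocaudal_order(c.seeds)
    extra = [t for t in c.targets if t not in c.seeds]
    target_order = seed_order + rois.rostrocaudal_order(extra)
    ri = [c.seeds.index(s) for s in seed_order]
    ci = [c.targets.index(t) for t in target_order]
    return ConnectivityMatrix(seeds=seed_order, targets=target_order,
                              cp=c.cp[np.ix_(ri, ci)])
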
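"""End-to-end orchestration with reproducible run metadata.

``run_subject`` takes one subject's streamline counts and geometry and
writes the CP matrix, adjacency, node metrics and range profiles;
``run_cohort`` adds the cross-age sequence graph and group degree
summary.  Every run writes a JSON metadata file capturing all thresholds,
modes and seeds plus a hash of the configuration, so a run is fully
reconstructible from metadata + inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .connectivity import (DEFAULT_THRESHOLD, LOG_BASE, StreamlineCounts,
                           binarize, compute_cp_matrix, order_rostrocaudal)
from .devtypes import (DEFAULT_TH_PRESENT, CohortManifest, sequence_graph,
                       types_to_frame, write_sequence_graph_json)
from .errors import ConfigError
from .metrics import group_degree_summary, node_metrics
from .ranges import DEFAULT_BANDS, Band, band_profiles, default_thq, profiles_to_frame
from .rois import (DistanceMatrix, LabelVolume, RoiTable, barycenters_from_csv,
                   compute_all_barycenters, compute_distance_matrix)

log = logging.getLogger("aanconn")


@dataclass
class RunConfig:
    """All analysis knobs, each with its documented default.

    ``threshold``: CP cut for graph construction (0.5).
    ``th_present``: CP cut for developmental presence calls (0.2).
    ``bands``: CP bands for range profiling, half-open (lo, hi].
    ``thq_mode``: "median" (per-subject median pairwise barycenter
    distance) or "absolute_mm" with ``thq_mm`` set.
    """

    threshold: float = DEFAULT_THRESHOLD
    th_present: float = DEFAULT_TH_PRESENT
    bands: tuple[Band, ...] = DEFAULT_BANDS
    thq_mode: str = "median"
    thq_mm: float | None = None
    symmetrization: str = "max"
    log_base: int = LOG_BASE
    rng_seed: int = 0
    space_name: str = "native"

    def __post_init__(self) -> None:
        if self.thq_mode not in ("median", "absolute_mm"):
            raise ConfigError(f"unknown thq_mode {self.thq_mode!r}")
        if self.thq_mode == "absolute_mm" and not self.thq_mm:
            raise ConfigError("thq_mode=absolute_mm requires thq_mm")
        self.bands = tuple(Band(*b) for b in self.bands)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _resolve_thq(config: RunConfig, t: DistanceMatrix) -> float:
    if config.thq_mode == "absolute_mm":
        return float(config.thq_mm)
    return default_thq(t)


def run_subject(config: RunConfig, counts: StreamlineCounts, rois: RoiTable,
                barycenters: Mapping[str, np.ndarray], outdir,
                subject_id: str) -> dict:
    """One subject: CP matrix, adjacency, node metrics, range profiles."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    c = order_rostrocaudal(compute_cp_matrix(counts), rois)
    adj = binarize(c, th=config.threshold, mode=config.symmetrization)
    log.info("%s: %d seeds, %d targets, %d edges at th=%.2f", subject_id,
             c.n_seeds, len(c.targets), int(adj.a.sum() // 2), config.threshold)
    metrics = node_metrics(adj)
    t = compute_distance_matrix(
        {a: barycenters[a] for a in c.seeds}).submatrix(c.seeds)
    thq = _resolve_thq(config, t)
    profiles = band_profiles(c, t, thq=thq, bands=config.bands,
                             mode=config.symmetrization)

    c.to_csv(outdir / f"{subject_id}_cp.csv")
    adj.to_csv(outdir / f"{subject_id}_adjacency.csv")
    metrics.to_csv(outdir / f"{subject_id}_metrics.csv", index=False)
    ranges_df = profiles_to_frame(profiles)
    ranges_df.to_csv(outdir / f"{subject_id}_ranges.csv", index=False)
    meta = {
        "subject_id": subject_id,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "thq_mm": thq,
        "n_seeds": c.n_seeds,
        "n_targets": len(c.targets),
        "n_edges": int(adj.a.sum() // 2),
        "outputs": [f"{subject_id}_{s}.csv"
                    for s in ("cp", "adjacency", "metrics", "ranges")],
    }
    with open(outdir / f"{subject_id}_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return {"cp": c, "adjacency": adj, "metrics": metrics,
            "ranges": ranges_df, "thq_mm": thq, "metadata": meta}


def run_cohort(config: RunConfig, manifest: CohortManifest,
               counts: Mapping[str, StreamlineCounts], rois: RoiTable,
               barycenters: Mapping[str, Mapping[str, np.ndarray]],
               outdir) -> dict:
    """Whole cohort: per-subject outputs plus sequence graph and summaries."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {}
    for sid, _ in manifest.subjects:
        results[sid] = run_subject(config, counts[sid], rois,
                                   barycenters[sid], outdir, sid)
    matrices = {sid: results[sid]["cp"] for sid, _ in manifest.subjects}
    types = sequence_graph(matrices, manifest, th_present=config.th_present,
                           rois=rois)
    log.info("sequence graph: %d typed connections across %d subjects",
             len(types), len(manifest.subjects))
    types_df = types_to_frame(types)
    types_df.to_csv(outdir / "connection_types.csv", index=False)
    write_sequence_graph_json(types, rois, outdir / "sequence_graph.json",
                              th_present=config.th_present)
    adjacencies = {sid: results[sid]["adjacency"]
                   for sid, _ in manifest.subjects}
    groups = dict(manifest.subjects)
    summary = group_degree_summary(adjacencies, groups)
    summary.to_csv(outdir / "group_degree_summary.csv")
    meta = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "subjects": manifest.subjects,
        "n_typed_connections": len(types),
        "outputs": ["connection_types.csv", "sequence_graph.json",
                    "group_degree_summary.csv"],
    }
    with open(outdir / "cohort_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return {"subjects": results, "types": types, "types_frame": types_df,
            "group_degree_summary": summary, "metadata": meta}


def load_cohort_dir(path) -> tuple[CohortManifest, RoiTable,
                                   dict[str, StreamlineCounts],
                                   dict[str, dict[str, np.ndarray]]]:
    """Read the on-disk layout produced by ``aanconn simulate``.

    Barycenters come from per-subject label volumes when present,
    otherwise from a ``<id>_barycenters.csv`` sidecar.
    """
    path = Path(path)
    manifest = CohortManifest.from_yaml(path / "manifest.yaml")
    rois = RoiTable.from_csv(path / "rois.csv")
    counts: dict[str, StreamlineCounts] = {}
    bary: dict[str, dict[str, np.ndarray]] = {}
    for sid, _ in manifest.subjects:
        counts[sid] = StreamlineCounts.from_tsv(path / f"{sid}_counts.tsv",
                                                path / f"{sid}_launched.tsv")
        nii = path / f"{sid}_labels.nii.gz"
        csv = path / f"{sid}_barycenters.csv"
        if nii.exists():
            vol = LabelVolume.from_nifti(nii)
            vol.validate_against(rois)
            bary[sid] = compute_all_barycenters(vol, rois, subset=rois.seeds())
        elif csv.exists():
            bary[sid] = barycenters_from_csv(csv)
        else:
            raise ConfigError(f"subject {sid}: no label volume or barycenter "
                              f"file under {path}")
    return manifest, rois, counts, bary
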
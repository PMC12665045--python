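"""Synthetic cohort generator with planted cluster/hub structure.

Emulates probabilistic-tractography count tables for a developmental
cohort (3 fetal, 2 infant, 2 adult subjects by default) without any
imaging data, so every pipeline stage is testable end-to-end.  The
generative model plants the qualitative structure the pipeline is meant
to recover:

* four anatomical clusters (medulla Me, pons P, midbrain Mi,
  diencephalon/forebrain DF) whose rostro-caudally adjacent members are
  strongly connected at every age (CP = ``p_within``);
* two hub nuclei (dorsal raphe DR and ventral tegmental area VTA by
  default) connected to every other region (CP = ``p_hub``);
* between-cluster connections that emerge with age: each remaining pair
  has CP ``p_between_base`` plus an age-gated increment toward
  ``p_between_adult``, where the nearest pairs (by barycenter distance
  rank) unlock first and the longest pairs only as the age factor
  approaches 1.  The per-subject age factor alpha defaults to 0.1
  (fetal), 0.5 (infant) and 0.9 (adult), so long-range connectivity
  appears predominantly postnatally.

Counts are drawn binomially around a per-subject logit-jittered CP, so
the count-ratio estimator is exactly the CP definition, and the two
directions of a pair are drawn independently (tractography is run per
seed), exercising symmetrization downstream.  All randomness flows from
one root seed via per-subject derived seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import rankdata

from .connectivity import ConnectivityMatrix, StreamlineCounts
from .devtypes import (CohortManifest, ConnectionType, DEFAULT_TH_PRESENT,
                       sequence_graph)
from .errors import ValidationError
from .rois import LabelVolume, RoiDefinition, RoiTable

# The 27 AAN seed regions: (abbrev stem, full name, system, cluster,
# lateralized?) ordered rostral -> caudal.  Lateralized stems expand to
# _L/_R twins.
_AAN_SEED_SPEC = [
    ("BF", "Basal forebrain", "ACh", "DF", True),
    ("Th", "Thalamus", "diencephalic", "DF", True),
    ("HY", "Hypothalamus", "diencephalic", "DF", True),
    ("VTA", "Ventral tegmental area", "DA_NE", "Mi", False),
    ("PAG", "Periaqueductal gray", "PAG", "Mi", False),
    ("mRt", "Mesencephalic reticular formation", "reticular", "Mi", True),
    ("PTg", "Pedunculotegmental nucleus", "ACh", "Mi", True),
    ("LDTg", "Laterodorsal tegmental nucleus", "ACh", "P", True),
    ("PnO", "Pontine reticular formation (pontis oralis)", "reticular", "P", True),
    ("PBC", "Parabrachial complex", "reticular", "P", True),
    ("LC", "Locus coeruleus", "DA_NE", "P", True),
    ("DR", "Dorsal raphe", "serotonin", "P", False),
    ("MnR", "Median raphe", "serotonin", "P", False),
    ("PGCL", "Paragigantocellularis lateralis", "respiratory", "Me", True),
    ("CR", "Caudal raphe", "serotonin", "Me", False),
    ("VC", "Vagal complex", "respiratory", "Me", True),
]

#: Number of cortical target regions in the whole-brain (85-node) analysis.
N_CORTICAL_TARGETS = 58

#: Global geometry scale per age group (adult = 1); fetal brains are smaller.
AGE_SCALE = {"fetal": 0.55, "infant": 0.8, "adult": 1.0}

#: Isotropic voxel size of the synthetic label volumes, mm per age group.
AGE_VOXEL_MM = {"fetal": 0.4, "infant": 0.7, "adult": 0.75}

DEFAULT_SUBJECTS = [("F1", "fetal"), ("F2", "fetal"), ("F3", "fetal"),
                    ("N1", "infant"), ("N2", "infant"),
                    ("A1", "adult"), ("A2", "adult")]


def default_roi_table(n_cortical: int = 0) -> RoiTable:
    """The 27 AAN seed regions, optionally plus generic cortical targets."""
    rois: list[RoiDefinition] = []
    idx = 0
    label = 1
    for stem, name, system, cluster, lateral in _AAN_SEED_SPEC:
        if lateral:
            for suffix, hemi in (("_L", "left"), ("_R", "right")):
                rois.append(RoiDefinition(label, stem + suffix, name, hemi,
                                          system, cluster, idx))
                idx += 1
                label += 1
        else:
            rois.append(RoiDefinition(label, stem, name, "midline", system,
                                      cluster, idx))
            idx += 1
            label += 1
    for k in range(n_cortical):
        pair, side = divmod(k, 2)
        suffix, hemi = (("_L", "left"), ("_R", "right"))[side]
        # odd trailing target without a twin would break L/R pairing
        if k == n_cortical - 1 and side == 0:
            suffix, hemi = "", "midline"
        rois.append(RoiDefinition(label, f"Ctx{pair + 1:02d}{suffix}",
                                  f"Cortical target {pair + 1}{suffix}", hemi,
                                  "cortical", "cortical", idx))
        idx += 1
        label += 1
    return RoiTable(rois)


def _generic_roi_table(n_nodes: int, n_cortical: int = 0) -> RoiTable:
    """Midline-only table for arbitrary sizes, clusters in 4 contiguous blocks."""
    clusters = ("DF", "Mi", "P", "Me")
    rois = []
    for i in range(n_nodes):
        cluster = clusters[min(i * 4 // max(n_nodes, 1), 3)]
        rois.append(RoiDefinition(i + 1, f"R{i:02d}", f"Region {i}", "midline",
                                  "reticular", cluster, i))
    for k in range(n_cortical):
        rois.append(RoiDefinition(n_nodes + k + 1, f"Ctx{k:02d}",
                                  f"Cortical target {k}", "midline",
                                  "cortical", "cortical", n_nodes + k))
    return RoiTable(rois)


def canonical_positions(rois: RoiTable) -> dict[str, np.ndarray]:
    """Unit-scale (adult-sized) barycenter layout in mm.

    Seed nuclei sit on a rostro-caudal axis (4 mm between anatomical
    levels, L/R twins offset +-4 mm laterally); cortical targets form a
    rostro-dorsal shell above the seed column.
    """
    base_first: dict[str, int] = {}
    for r in rois:
        if r.cluster == "cortical":
            continue
        base_first.setdefault(r.base_abbrev, r.rostrocaudal_index)
    level_of = {b: rank for rank, b in
                enumerate(sorted(base_first, key=base_first.get))}
    lateral = {"left": -4.0, "right": 4.0, "midline": 0.0}
    pos: dict[str, np.ndarray] = {}
    n_ctx_seen = 0
    for r in rois:
        if r.cluster == "cortical":
            pair, side = divmod(n_ctx_seen, 2)
            x = (5.0 + 1.2 * pair) * (1 if side else -1)
            pos[r.abbrev] = np.array([x, 10.0 + 0.6 * pair, 25.0])
            n_ctx_seen += 1
        else:
            level = level_of[r.base_abbrev]
            pos[r.abbrev] = np.array([lateral[r.hemisphere], -4.0 * level, 0.0])
    return pos


@dataclass
class GenerativeSpec:
    """Parameters of the planted-structure cohort model.

    Probabilities are CP values in [0, 1]; ``age_alpha`` maps each age
    group to its developmental factor alpha in [0, 1]; launched totals
    per seed are ``voxels_per_roi * seeds_per_voxel``.
    """

    n_nodes: int = 27
    roi_table: RoiTable | None = None
    cluster_assignment: Mapping[str, str] | None = None
    hub_set: tuple[str, ...] = ("DR", "VTA")
    p_within: float = 0.8
    p_hub: float = 0.6
    p_between_base: float = 0.05
    p_between_adult: float = 0.55
    age_alpha: Mapping[str, float] = field(
        default_factory=lambda: {"fetal": 0.1, "infant": 0.5, "adult": 0.9})
    subject_jitter_sd: float = 0.3
    voxels_per_roi: int = 20
    seeds_per_voxel: int = 5000
    rng_seed: int = 0
    n_cortical_targets: int = 0

    def __post_init__(self) -> None:
        if self.roi_table is None:
            if self.n_nodes == 27:
                self.roi_table = default_roi_table(self.n_cortical_targets)
            else:
                self.roi_table = _generic_roi_table(self.n_nodes,
                                                    self.n_cortical_targets)
        seeds = self.roi_table.seeds()
        if len(seeds) != self.n_nodes:
            raise ValidationError(
                f"ROI table has {len(seeds)} seed regions, expected {self.n_nodes}")
        for p in (self.p_within, self.p_hub, self.p_between_base,
                  self.p_between_adult):
            if not (0 <= p <= 1):
                raise ValidationError(f"probability parameter {p} outside [0, 1]")
        if self.p_within <= self.p_between_base:
            raise ValidationError("p_within must exceed p_between_base")
        unknown = [h for h in self.hub_set if h not in seeds]
        if unknown:
            raise ValidationError(f"hub_set members not in node set: {unknown}")
        if self.cluster_assignment is None:
            self.cluster_assignment = {a: self.roi_table.cluster_of(a)
                                       for a in seeds}
        for g, a in self.age_alpha.items():
            if not (0 <= a <= 1):
                raise ValidationError(f"age factor for {g} outside [0, 1]: {a}")

    @property
    def launched_per_seed(self) -> int:
        return self.voxels_per_roi * self.seeds_per_voxel


def _emergence(alpha: float, r: np.ndarray) -> np.ndarray:
    """Age gate for between-cluster pairs.

    ``r`` is the normalized distance rank in [0, 1].  The gate rises from
    0 to 1 over a narrow alpha window that shifts with r: the nearest
    pairs (r = 0) are fully emerged by alpha = 0.1 and the longest only
    at alpha = 1, giving a sharp short-to-long-range developmental wave.
    At alpha = 0 every pair sits at the base level.
    """
    return np.clip((alpha - 1.5 * r) / 0.1, 0.0, 1.0)


def _pair_geometry(spec: GenerativeSpec):
    """Classify seed pairs and precompute distance ranks (cached on spec)."""
    cached = getattr(spec, "_pair_cache", None)
    if cached is not None:
        return cached
    rois = spec.roi_table
    seeds = rois.rostrocaudal_order(rois.seeds())
    targets = seeds + rois.rostrocaudal_order(
        [r.abbrev for r in rois if r.cluster == "cortical"])
    pos = canonical_positions(rois)
    n = len(seeds)
    rc = {a: rois[a].rostrocaudal_index for a in seeds}
    cluster = spec.cluster_assignment
    hubs = set(spec.hub_set)

    within = np.zeros((n, n), dtype=bool)
    hub = np.zeros((n, n), dtype=bool)
    for i, si in enumerate(seeds):
        for j, sj in enumerate(seeds):
            if i == j:
                continue
            if cluster[si] == cluster[sj] and abs(rc[si] - rc[sj]) <= 2:
                within[i, j] = True
            elif si in hubs or sj in hubs:
                hub[i, j] = True
    other = ~within & ~hub & ~np.eye(n, dtype=bool)

    # normalized distance rank among the age-gated ("other") pairs
    iu, ju = np.where(np.triu(other))
    dists = np.array([np.linalg.norm(pos[seeds[i]] - pos[seeds[j]])
                      for i, j in zip(iu, ju)])
    rmat = np.zeros((n, n))
    if dists.size:
        ranks = rankdata(dists, method="average") - 1.0
        ranks = ranks / max(ranks.max(), 1.0)
        rmat[iu, ju] = ranks
        rmat[ju, iu] = ranks

    # cortical columns: hubs project strongly; others age-gated by distance rank
    m = len(targets)
    ctx_r = np.zeros((n, m - n))
    ctx_hub = np.zeros((n, m - n), dtype=bool)
    if m > n:
        cd = np.array([[np.linalg.norm(pos[s] - pos[t]) for t in targets[n:]]
                       for s in seeds])
        cranks = rankdata(cd.ravel(), method="average") - 1.0
        ctx_r = (cranks / max(cranks.max(), 1.0)).reshape(cd.shape)
        ctx_hub = np.array([[s in hubs for _ in targets[n:]] for s in seeds])
    cache = (seeds, targets, within, hub, other, rmat, ctx_hub, ctx_r)
    spec._pair_cache = cache
    return cache


def generate_true_cp(spec: GenerativeSpec, alpha: float) -> ConnectivityMatrix:
    """Noiseless CP matrix of the planted model at age factor ``alpha``."""
    seeds, targets, within, hub, other, rmat, ctx_hub, ctx_r = _pair_geometry(spec)
    n, m = len(seeds), len(targets)
    cp = np.zeros((n, m))
    block = cp[:, :n]
    block[within] = spec.p_within
    block[hub] = spec.p_hub
    g = _emergence(alpha, rmat)
    block[other] = (spec.p_between_base
                    + g[other] * (spec.p_between_adult - spec.p_between_base))
    if m > n:
        gctx = _emergence(alpha, ctx_r)
        ext = (spec.p_between_base
               + gctx * (spec.p_between_adult - spec.p_between_base))
        ext[ctx_hub] = spec.p_hub
        cp[:, n:] = ext
    return ConnectivityMatrix(seeds=list(seeds), targets=list(targets), cp=cp)


def sample_counts(true_cp: ConnectivityMatrix, spec: GenerativeSpec,
                  subject_seed: int) -> StreamlineCounts:
    """Binomial streamline counts around logit-jittered true CP.

    Each directed entry gets an independent Normal(0, subject_jitter_sd)
    perturbation on the log-odds scale (degenerate CP of exactly 0 or 1
    is left untouched), then ``launched`` Bernoulli trials.  Reproducible
    given the spec's root seed and the subject seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        (int(spec.rng_seed), int(subject_seed))))
    cp = true_cp.cp
    p = cp.copy()
    interior = (cp > 0) & (cp < 1)
    if spec.subject_jitter_sd > 0:
        eps = rng.normal(0.0, spec.subject_jitter_sd, size=cp.shape)
        p[interior] = expit(logit(cp[interior]) + eps[interior])
    launched_total = spec.launched_per_seed
    connecting = rng.binomial(launched_total, p)
    launched = np.full(len(true_cp.seeds), launched_total, dtype=np.int64)
    return StreamlineCounts(seeds=list(true_cp.seeds),
                            targets=list(true_cp.targets),
                            connecting=connecting.astype(np.int64),
                            launched=launched)


def generate_true_types(spec: GenerativeSpec,
                        th_present: float = DEFAULT_TH_PRESENT) -> list[ConnectionType]:
    """Ground-truth developmental types from the noiseless age-gated model."""
    groups = list(spec.age_alpha)
    pseudo = CohortManifest([(f"_{g}", g) for g in groups])
    matrices = {f"_{g}": generate_true_cp(spec, spec.age_alpha[g])
                for g in groups}
    return sequence_graph(matrices, pseudo, th_present=th_present,
                          rois=spec.roi_table)


@dataclass
class GroundTruth:
    """Noiseless model outputs recorded alongside every generated cohort."""

    true_cp: dict[str, ConnectivityMatrix]
    true_types: list[ConnectionType]
    hub_set: tuple[str, ...]


@dataclass
class Cohort:
    """A generated cohort: inputs for every pipeline stage plus ground truth."""

    spec: GenerativeSpec
    manifest: CohortManifest
    roi_table: RoiTable
    counts: dict[str, StreamlineCounts]
    barycenters: dict[str, dict[str, np.ndarray]]
    volumes: dict[str, LabelVolume] | None
    ground_truth: GroundTruth


def _make_label_volume(positions: Mapping[str, np.ndarray], rois: RoiTable,
                       voxel_mm: float, radius_mm: float) -> LabelVolume:
    """Digital spheres at the given world positions on a regular grid."""
    pts = np.array(list(positions.values()))
    margin = radius_mm + 3 * voxel_mm
    origin = pts.min(axis=0) - margin
    extent = pts.max(axis=0) + margin - origin
    shape = np.ceil(extent / voxel_mm).astype(int) + 1
    vox = np.zeros(tuple(shape), dtype=np.int16)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = origin
    rv = radius_mm / voxel_mm
    w = int(np.ceil(rv))
    for abbrev, pos in positions.items():
        c = (np.asarray(pos) - origin) / voxel_mm
        lo = np.maximum(np.floor(c).astype(int) - w, 0)
        hi = np.minimum(np.floor(c).astype(int) + w + 1, shape)
        grid = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        inside = ((grid - c.reshape(3, 1, 1, 1)) ** 2).sum(axis=0) <= rv ** 2
        sub = vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = rois[abbrev].label_id
    return LabelVolume(voxels=vox, affine=affine)


def generate_cohort(spec: GenerativeSpec,
                    manifest: CohortManifest | None = None,
                    volumes: bool = True) -> Cohort:
    """Full cohort: counts, geometry and ground truth for every subject.

    Subject geometry is the canonical layout scaled by the age group's
    global factor (fetal brains smaller), with label volumes as digital
    spheres at age-appropriate voxel sizes.  Subject seeds derive from
    the root seed and the subject's position in the manifest.
    """
    if manifest is None:
        manifest = CohortManifest(list(DEFAULT_SUBJECTS))
    rois = spec.roi_table
    pos = canonical_positions(rois)
    seed_pos = {a: pos[a] for a in rois.seeds()}
    true_cp = {g: generate_true_cp(spec, spec.age_alpha[g])
               for g in manifest.groups}
    counts: dict[str, StreamlineCounts] = {}
    bary: dict[str, dict[str, np.ndarray]] = {}
    vols: dict[str, LabelVolume] = {}
    for idx, (sid, group) in enumerate(manifest.subjects):
        counts[sid] = sample_counts(true_cp[group], spec, subject_seed=idx + 1)
        scale = AGE_SCALE[group]
        scaled = {a: p * scale for a, p in seed_pos.items()}
        if volumes:
            vol = _make_label_volume(scaled, rois, AGE_VOXEL_MM[group],
                                     radius_mm=1.5 * scale)
            vols[sid] = vol
            from .rois import compute_all_barycenters
            bary[sid] = compute_all_barycenters(vol, rois, subset=rois.seeds())
        else:
            bary[sid] = scaled
    gt = GroundTruth(true_cp=true_cp, true_types=generate_true_types(spec),
                     hub_set=tuple(spec.hub_set))
    return Cohort(spec=spec, manifest=manifest, roi_table=rois, counts=counts,
                  barycenters=bary, volumes=vols if volumes else None,
                  ground_truth=gt)


def write_cohort(cohort: Cohort, outdir) -> None:
    """On-disk layout consumed by the pipeline CLI.

    Per subject: ``<id>_counts.tsv`` + ``<id>_launched.tsv`` (+ optional
    ``<id>_labels.nii.gz``); plus ``rois.csv``, ``manifest.yaml`` and
    ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.roi_table.to_csv(outdir / "rois.csv")
    cohort.manifest.to_yaml(outdir / "manifest.yaml")
    for sid, _ in cohort.manifest.subjects:
        sc = cohort.counts[sid]
        sc.to_tsv(outdir / f"{sid}_counts.tsv", outdir / f"{sid}_launched.tsv")
        if cohort.volumes is not None:
            cohort.volumes[sid].to_nifti(outdir / f"{sid}_labels.nii.gz")
    gt = cohort.ground_truth
    payload = {
        "hub_set": list(gt.hub_set),
        "true_cp": {g: {"seeds": m.seeds, "targets": m.targets,
                        "cp": m.cp.tolist()} for g, m in gt.true_cp.items()},
        "true_types": [{"seed": t.seed, "target": t.target,
                        "pattern": t.pattern_str, "type_label": t.type_label,
                        "support": t.support} for t in gt.true_types],
        "derived_seed_scheme": "SeedSequence((rng_seed, subject_index + 1))",
        "rng_seed": cohort.spec.rng_seed,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(payload, fh)
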
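"""ROI definitions, label volumes, barycenters and inter-ROI distances.

Regions of interest (ROIs) are brainstem / diencephalic nuclei of the
ascending arousal network (AAN), optionally extended with cortical target
regions.  Each ROI carries a label id (its integer value in a NIfTI label
volume), an abbreviation such as ``DR`` or ``LC_L``, a neurotransmitter
system, an anatomical cluster (medulla ``Me``, pons ``P``, midbrain ``Mi``,
diencephalon/forebrain ``DF``, or ``cortical``), and a rostro-caudal
ordering key used to sort matrices from head to tail.

Distances between regions are Euclidean distances between ROI barycenters
(unweighted centers of mass of the label's voxel centers) in world
millimeter coordinates, so that subjects with different voxel sizes are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import EmptyRoiError, IncompleteGeometryError, ValidationError

HEMISPHERES = ("left", "right", "midline")
SYSTEMS = ("ACh", "serotonin", "DA_NE", "respiratory", "reticular",
           "diencephalic", "PAG", "cortical")
CLUSTERS = ("Me", "P", "Mi", "DF", "cortical")

ROI_CSV_COLUMNS = ["label_id", "abbrev", "name", "hemisphere", "system",
                   "cluster", "rostrocaudal_index"]


@dataclass(frozen=True)
class RoiDefinition:
    """One region of interest.

    ``rostrocaudal_index`` is an integer ordering key, 0 = most rostral.
    Lateralized regions use ``_L`` / ``_R`` abbreviation suffixes.
    """

    label_id: int
    abbrev: str
    name: str
    hemisphere: str
    system: str
    cluster: str
    rostrocaudal_index: int

    def __post_init__(self) -> None:
        if self.label_id <= 0:
            raise ValidationError(f"label_id must be positive, got {self.label_id}")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"unknown hemisphere {self.hemisphere!r} for {self.abbrev}")
        if self.system not in SYSTEMS:
            raise ValidationError(f"unknown system {self.system!r} for {self.abbrev}")
        if self.cluster not in CLUSTERS:
            raise ValidationError(f"unknown cluster {self.cluster!r} for {self.abbrev}")

    @property
    def base_abbrev(self) -> str:
        if self.abbrev.endswith(("_L", "_R")):
            return self.abbrev[:-2]
        return self.abbrev


class RoiTable:
    """An ordered collection of ROI definitions with schema validation.

    Invariants enforced at construction: unique abbreviations and label ids,
    non-cortical ROIs carry an anatomical cluster in {Me, P, Mi, DF}, and
    lateralized ROIs come in L/R pairs sharing a base abbreviation.
    """

    def __init__(self, rois: Iterable[RoiDefinition]):
        self.rois: list[RoiDefinition] = list(rois)
        abbrevs = [r.abbrev for r in self.rois]
        if len(set(abbrevs)) != len(abbrevs):
            dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise ValidationError(f"duplicate abbreviations: {dupes}")
        ids = [r.label_id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate label ids")
        for r in self.rois:
            if r.cluster == "cortical" and r.system != "cortical":
                raise ValidationError(f"{r.abbrev}: cortical cluster requires cortical system")
            if r.system == "cortical" and r.cluster != "cortical":
                raise ValidationError(f"{r.abbrev}: cortical system requires cortical cluster")
        by_abbrev = {r.abbrev: r for r in self.rois}
        for r in self.rois:
            if r.hemisphere == "left":
                twin = r.base_abbrev + "_R"
                if twin not in by_abbrev:
                    raise ValidationError(f"lateralized ROI {r.abbrev} lacks right twin {twin}")
            elif r.hemisphere == "right":
                twin = r.base_abbrev + "_L"
                if twin not in by_abbrev:
                    raise ValidationError(f"lateralized ROI {r.abbrev} lacks left twin {twin}")
        self._by_abbrev = by_abbrev
        self._by_id = {r.label_id: r for r in self.rois}

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __contains__(self, abbrev: str) -> bool:
        return abbrev in self._by_abbrev

    def __getitem__(self, abbrev: str) -> RoiDefinition:
        try:
            return self._by_abbrev[abbrev]
        except KeyError:
            raise KeyError(f"unknown ROI abbreviation {abbrev!r}") from None

    def by_label_id(self, label_id: int) -> RoiDefinition:
        return self._by_id[label_id]

    @property
    def abbrevs(self) -> list[str]:
        return [r.abbrev for r in self.rois]

    def rostrocaudal_order(self, subset: Sequence[str] | None = None) -> list[str]:
        """Abbreviations sorted from rostral to caudal (ascending index)."""
        pool = self.rois if subset is None else [self[a] for a in subset]
        return [r.abbrev for r in sorted(pool, key=lambda r: r.rostrocaudal_index)]

    def seeds(self) -> list[str]:
        """Non-cortical (AAN seed) abbreviations in table order."""
        return [r.abbrev for r in self.rois if r.cluster != "cortical"]

    def cluster_of(self, abbrev: str) -> str:
        return self[abbrev].cluster

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.label_id, r.abbrev, r.name, r.hemisphere, r.system, r.cluster,
              r.rostrocaudal_index) for r in self.rois],
            columns=ROI_CSV_COLUMNS,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RoiTable":
        df = pd.read_csv(path)
        missing = set(ROI_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"ROI table {path}: missing columns {sorted(missing)}")
        return cls(
            RoiDefinition(int(row.label_id), str(row.abbrev), str(row.name),
                          str(row.hemisphere), str(row.system), str(row.cluster),
                          int(row.rostrocaudal_index))
            for row in df.itertuples(index=False)
        )


@dataclass
class LabelVolume:
    """Integer label image (0 = background) with a voxel-to-world affine.

    Voxel indices are 0-based; world coordinates in mm are obtained by
    applying the affine to integer voxel indices (voxel-center convention,
    matching NIfTI).
    """

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValidationError("label volume must be 3-D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValidationError("label volume must have an integer dtype")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.voxels)
        return ids[ids != 0]

    def validate_against(self, rois: RoiTable) -> None:
        unknown = [int(i) for i in self.label_ids() if i not in rois._by_id]
        if unknown:
            raise ValidationError(f"label ids absent from ROI table: {unknown}")

    @classmethod
    def from_nifti(cls, path) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise ValidationError(f"{path}: label volume has non-integer values")
            data = rounded.astype(np.int32)
        return cls(voxels=data, affine=img.affine)

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.voxels.astype(np.int16), self.affine)
        nib.save(img, str(path))


def compute_barycenter(volume: LabelVolume, label_id: int) -> np.ndarray:
    """Unweighted mean world-mm coordinate of all voxel centers with ``label_id``.

    All voxels of a label contribute equally (binary annotation, no
    partial-volume weighting).  Raises :class:`EmptyRoiError` if the label
    has no voxels — an empty ROI is an error, never a zero vector.
    """
    idx = np.argwhere(volume.voxels == label_id)
    if idx.size == 0:
        raise EmptyRoiError(f"empty ROI: label {label_id} has no voxels")
    world = nib.affines.apply_affine(volume.affine, idx)
    return world.mean(axis=0)


def compute_all_barycenters(volume: LabelVolume, rois: RoiTable,
                            subset: Sequence[str] | None = None) -> dict[str, np.ndarray]:
    """Barycenters for every requested ROI, keyed by abbreviation."""
    abbrevs = subset if subset is not None else rois.abbrevs
    out: dict[str, np.ndarray] = {}
    for a in abbrevs:
        out[a] = compute_barycenter(volume, rois[a].label_id)
    return out


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of inter-barycenter Euclidean distances in mm."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise IncompleteGeometryError(f"incomplete geometry: no distances for {missing}")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def compute_distance_matrix(barycenters: Mapping[str, np.ndarray]) -> DistanceMatrix:
    """Pairwise Euclidean distances between ROI barycenters.

    Coincident barycenters are allowed (distance 0).  At least two points
    are required.
    """
    if len(barycenters) < 2:
        raise IncompleteGeometryError("incomplete geometry: need at least 2 barycenters")
    labels = list(barycenters)
    pts = np.asarray([np.asarray(barycenters[l], dtype=float) for l in labels])
    if pts.shape[1] != 3:
        raise ValidationError("barycenters must be 3-vectors")
    return DistanceMatrix(labels, squareform(pdist(pts)))


def barycenters_to_csv(barycenters: Mapping[str, np.ndarray], path) -> None:
    df = pd.DataFrame(
        [(a, *np.asarray(v, dtype=float)) for a, v in barycenters.items()],
        columns=["abbrev", "x_mm", "y_mm", "z_mm"],
    )
    df.to_csv(path, index=False)


def barycenters_from_csv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {str(r.abbrev): np.array([r.x_mm, r.y_mm, r.z_mm], dtype=float)
            for r in df.itertuples(index=False)}
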
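"""Developmental typing of connections across a fetal/infant/adult cohort.

Each directed seed->target connection is called *present* in a subject
when its CP exceeds ``th_present`` (default 0.2, moderate-to-strong).
Typing is directed — the CP matrix is not symmetrized here, because a
seed->target estimate and its reverse are independent tractography runs
and the sequence graph draws directed arrows.

A connection's presence pattern is the set of age groups with at least
one presenting subject; the seven nonempty patterns map bijectively to
type labels:

    {fetal, infant, adult} -> core          {fetal}         -> fetal_only
    {fetal, infant}        -> fetal_infant  {infant}        -> infant_only
    {fetal, adult}         -> fetal_adult   {infant, adult} -> postnatal
                                            {adult}         -> adult_only

Support is *solid* when every subject of every group in the pattern shows
the connection, *dotted* when at least one subject per group does.
Connections absent everywhere are omitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .connectivity import ConnectivityMatrix
from .errors import ValidationError
from .rois import RoiTable

AGE_GROUPS = ("fetal", "infant", "adult")

DEFAULT_TH_PRESENT = 0.2

TYPE_LABELS: dict[frozenset, str] = {
    frozenset({"fetal", "infant", "adult"}): "core",
    frozenset({"fetal"}): "fetal_only",
    frozenset({"fetal", "infant"}): "fetal_infant",
    frozenset({"fetal", "adult"}): "fetal_adult",
    frozenset({"infant"}): "infant_only",
    frozenset({"infant", "adult"}): "postnatal",
    frozenset({"adult"}): "adult_only",
}


@dataclass
class CohortManifest:
    """Subject ids with their age-group assignment, in acquisition order."""

    subjects: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids in manifest")
        bad = [(s, g) for s, g in self.subjects if g not in AGE_GROUPS]
        if bad:
            raise ValidationError(f"unknown age groups in manifest: {bad}")
        if not self.subjects:
            raise ValidationError("manifest is empty")

    @property
    def groups(self) -> list[str]:
        """Age groups present, in canonical fetal->infant->adult order."""
        present = {g for _, g in self.subjects}
        return [g for g in AGE_GROUPS if g in present]

    def subjects_in(self, group: str) -> list[str]:
        return [s for s, g in self.subjects if g == group]

    def group_of(self, subject_id: str) -> str:
        for s, g in self.subjects:
            if s == subject_id:
                return g
        raise KeyError(f"unknown subject {subject_id!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"subjects": [{"id": s, "age_group": g}
                                         for s, g in self.subjects]}, fh)

    @classmethod
    def from_yaml(cls, path) -> "CohortManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls([(str(e["id"]), str(e["age_group"])) for e in raw["subjects"]])


@dataclass(frozen=True)
class ConnectionType:
    """Developmental classification of one directed ROI pair."""

    seed: str
    target: str
    pattern: frozenset
    type_label: str
    support: str

    @property
    def pattern_str(self) -> str:
        return "+".join(g for g in AGE_GROUPS if g in self.pattern)


def connection_present(c: ConnectivityMatrix, seed: str, target: str,
                       th_present: float = DEFAULT_TH_PRESENT) -> bool:
    """Directed presence: CP(seed -> target) strictly above ``th_present``."""
    return c.loc(seed, target) > th_present


def classify_connection(presences: Mapping[str, bool],
                        manifest: CohortManifest) -> tuple[frozenset, str, str] | None:
    """Pattern, type label and solid/dotted support for one ROI pair.

    Returns None when no subject presents the connection.  Support is
    independent of subject ordering within groups.
    """
    missing = [s for s, _ in manifest.subjects if s not in presences]
    if missing:
        raise ValidationError(f"presence calls missing for subjects {missing}")
    pattern = set()
    all_present_within = True
    for group in manifest.groups:
        calls = [presences[s] for s in manifest.subjects_in(group)]
        if any(calls):
            pattern.add(group)
            if not all(calls):
                all_present_within = False
    if not pattern:
        return None
    pattern = frozenset(pattern)
    support = "solid" if all_present_within else "dotted"
    return pattern, TYPE_LABELS[pattern], support


def sequence_graph(matrices: Mapping[str, ConnectivityMatrix],
                   manifest: CohortManifest,
                   th_present: float = DEFAULT_TH_PRESENT,
                   rois: RoiTable | None = None) -> list[ConnectionType]:
    """Type every directed ROI pair with a nonempty presence pattern.

    Output order is deterministic: seeds rostral-to-caudal, then targets
    rostral-to-caudal (matrix order when no ROI table is supplied).
    """
    missing = [s for s, _ in manifest.subjects if s not in matrices]
    if missing:
        raise ValidationError(f"missing connectivity matrix for subject(s) {missing}")
    first = matrices[manifest.subjects[0][0]]
    seeds, targets = first.seeds, first.targets
    for subj, _ in manifest.subjects:
        m = matrices[subj]
        if m.seeds != seeds or m.targets != targets:
            raise ValidationError(f"subject {subj}: ROI ordering differs across cohort")
    if rois is not None:
        seed_order = rois.rostrocaudal_order(seeds)
        target_order = rois.rostrocaudal_order(targets)
    else:
        seed_order, target_order = seeds, targets

    out: list[ConnectionType] = []
    for seed in seed_order:
        for target in target_order:
            if seed == target:
                continue
            presences = {s: connection_present(matrices[s], seed, target, th_present)
                         for s, _ in manifest.subjects}
            result = classify_connection(presences, manifest)
            if result is None:
                continue
            pattern, label, support = result
            out.append(ConnectionType(seed=seed, target=target, pattern=pattern,
                                      type_label=label, support=support))
    return out


def types_to_frame(types: Sequence[ConnectionType]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.seed, t.target, t.pattern_str, t.type_label, t.support) for t in types],
        columns=["seed", "target", "pattern", "type_label", "support"],
    )


def sequence_graph_json(types: Sequence[ConnectionType], rois: RoiTable,
                        th_present: float = DEFAULT_TH_PRESENT) -> dict:
    """Plot-ready export: nodes with cluster annotation, typed directed edges."""
    node_abbrevs = sorted({t.seed for t in types} | {t.target for t in types},
                          key=lambda a: rois[a].rostrocaudal_index)
    return {
        "th_present": th_present,
        "direction": "seed_to_target",
        "nodes": [{"abbrev": a, "cluster": rois[a].cluster,
                   "system": rois[a].system} for a in node_abbrevs],
        "edges": [{"seed": t.seed, "target": t.target, "pattern": t.pattern_str,
                   "type": t.type_label, "support": t.support} for t in types],
    }


def write_sequence_graph_json(types: Sequence[ConnectionType], rois: RoiTable,
                              path, th_present: float = DEFAULT_TH_PRESENT) -> None:
    with open(path, "w") as fh:
        json.dump(sequence_graph_json(types, rois, th_present), fh, indent=2)
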
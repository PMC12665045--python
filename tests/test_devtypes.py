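"""Developmental connection typing across the fetal/infant/adult cohort."""

import numpy as np
import pytest

from aanconn.connectivity import ConnectivityMatrix
from aanconn.devtypes import (CohortManifest, TYPE_LABELS, classify_connection,
                              connection_present, sequence_graph,
                              sequence_graph_json, types_to_frame)
from aanconn.errors import ValidationError
from aanconn.synthetic import default_roi_table

MANIFEST = CohortManifest([("F1", "fetal"), ("F2", "fetal"), ("F3", "fetal"),
                           ("N1", "infant"), ("N2", "infant"),
                           ("A1", "adult"), ("A2", "adult")])


def _cp(block, seeds=("a", "b")):
    block = np.asarray(block, dtype=float)
    return ConnectivityMatrix(seeds=list(seeds), targets=list(seeds), cp=block)


class TestPresence:
    @pytest.mark.parametrize("cp,expected", [(0.25, True), (0.2, False),
                                             (0.0, False)])
    def test_strictly_above_threshold(self, cp, expected):
        c = _cp([[0.0, cp], [0.0, 0.0]])
        assert connection_present(c, "a", "b") is expected

    def test_directed_no_symmetrization(self):
        c = _cp([[0.0, 0.9], [0.0, 0.0]])
        assert connection_present(c, "a", "b")
        assert not connection_present(c, "b", "a")

    def test_unknown_roi_rejected(self):
        with pytest.raises(KeyError):
            connection_present(_cp([[0.0, 0.0], [0.0, 0.0]]), "a", "zzz")


class TestClassify:
    def test_present_everywhere_is_core_solid(self):
        presences = {s: True for s, _ in MANIFEST.subjects}
        assert classify_connection(presences, MANIFEST) == (
            frozenset({"fetal", "infant", "adult"}), "core", "solid")

    def test_partial_fetal_infant_is_dotted(self):
        presences = {"F1": True, "F2": False, "F3": False,
                     "N1": True, "N2": False, "A1": False, "A2": False}
        assert classify_connection(presences, MANIFEST) == (
            frozenset({"fetal", "infant"}), "fetal_infant", "dotted")

    def test_both_adults_only_is_solid(self):
        presences = {s: g == "adult" for s, g in MANIFEST.subjects}
        assert classify_connection(presences, MANIFEST) == (
            frozenset({"adult"}), "adult_only", "solid")

    def test_absent_everywhere_returns_none(self):
        presences = {s: False for s, _ in MANIFEST.subjects}
        assert classify_connection(presences, MANIFEST) is None

    def test_missing_subject_rejected(self):
        with pytest.raises(ValidationError):
            classify_connection({"F1": True}, MANIFEST)

    def test_invariant_to_subject_order_within_groups(self, rng):
        for _ in range(20):
            calls = dict(zip([s for s, _ in MANIFEST.subjects],
                             rng.random(7) < 0.5))
            shuffled = CohortManifest(
                [MANIFEST.subjects[i]
                 for i in rng.permutation(len(MANIFEST.subjects))])
            assert (classify_connection(calls, MANIFEST)
                    == classify_connection(calls, shuffled))

    def test_partial_cohort_restricts_patterns(self):
        two_group = CohortManifest([("F1", "fetal"), ("A1", "adult")])
        got = classify_connection({"F1": True, "A1": False}, two_group)
        assert got == (frozenset({"fetal"}), "fetal_only", "solid")


class TestSequenceGraph:
    def _cohort(self, block_by_subject, seeds=("a", "b")):
        return {s: _cp(block_by_subject[s], seeds)
                for s, _ in MANIFEST.subjects}

    def test_all_empty_matrices_give_empty_list(self):
        mats = self._cohort({s: np.zeros((2, 2))
                             for s, _ in MANIFEST.subjects})
        assert sequence_graph(mats, MANIFEST) == []

    def test_single_universal_connection_is_one_core_solid(self):
        block = np.array([[0.0, 0.9], [0.0, 0.0]])
        mats = self._cohort({s: block for s, _ in MANIFEST.subjects})
        types = sequence_graph(mats, MANIFEST)
        assert len(types) == 1
        t = types[0]
        assert (t.seed, t.target, t.type_label, t.support) == \
            ("a", "b", "core", "solid")

    def test_missing_matrix_names_subject(self):
        mats = self._cohort({s: np.zeros((2, 2))
                             for s, _ in MANIFEST.subjects})
        del mats["N2"]
        with pytest.raises(ValidationError, match="N2"):
            sequence_graph(mats, MANIFEST)

    def test_type_labels_partition_random_cohorts(self, rng):
        """Every emitted connection gets exactly one of the seven labels
        and its label matches its pattern bijectively."""
        seeds = [f"n{i}" for i in range(6)]
        for _ in range(30):
            mats = {s: _cp(rng.random((6, 6)) * 0.5, seeds)
                    for s, _ in MANIFEST.subjects}
            types = sequence_graph(mats, MANIFEST)
            for t in types:
                assert TYPE_LABELS[t.pattern] == t.type_label
            assert len({(t.seed, t.target) for t in types}) == len(types)

    def test_raising_threshold_shrinks_patterns(self, rng):
        seeds = [f"n{i}" for i in range(5)]
        mats = {s: _cp(rng.random((5, 5)) * 0.6, seeds)
                for s, _ in MANIFEST.subjects}
        lo = {(t.seed, t.target): t.pattern
              for t in sequence_graph(mats, MANIFEST, th_present=0.2)}
        hi = {(t.seed, t.target): t.pattern
              for t in sequence_graph(mats, MANIFEST, th_present=0.4)}
        for pair, pattern in hi.items():
            assert pattern <= lo[pair]

    def test_output_order_is_rostrocaudal(self):
        rois = default_roi_table()
        seeds = rois.rostrocaudal_order()[:4]
        block = np.full((4, 4), 0.9)
        np.fill_diagonal(block, 0)
        mats = {s: _cp(block, seeds) for s, _ in MANIFEST.subjects}
        types = sequence_graph(mats, MANIFEST, rois=rois)
        order = [(rois[t.seed].rostrocaudal_index,
                  rois[t.target].rostrocaudal_index) for t in types]
        assert order == sorted(order)

    def test_json_export_structure(self):
        rois = default_roi_table()
        block = np.array([[0.0, 0.9], [0.0, 0.0]])
        mats = self._cohort({s: block for s, _ in MANIFEST.subjects},
                            seeds=("DR", "VTA"))
        types = sequence_graph(mats, MANIFEST, rois=rois)
        out = sequence_graph_json(types, rois)
        assert {n["abbrev"] for n in out["nodes"]} == {"DR", "VTA"}
        assert out["edges"][0]["type"] == "core"
        assert out["nodes"][0]["cluster"] in {"Me", "P", "Mi", "DF"}
        df = types_to_frame(types)
        assert list(df.columns) == ["seed", "target", "pattern", "type_label",
                                    "support"]


class TestManifest:
    def test_yaml_round_trip(self, tmp_path):
        MANIFEST.to_yaml(tmp_path / "m.yaml")
        back = CohortManifest.from_yaml(tmp_path / "m.yaml")
        assert back.subjects == MANIFEST.subjects

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            CohortManifest([("X1", "toddler")])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            CohortManifest([("F1", "fetal"), ("F1", "adult")])
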
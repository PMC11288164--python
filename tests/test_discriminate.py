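"""Outgroup score-ratio rule, indel inspection, distances, NJ and the cascade."""

from __future__ import annotations

import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from ndescan import (
    ProteinRecord,
    ReferencePanel,
    align_local,
    annotate,
    compute_ref_out_scores,
    indel_inspection,
    kimura_distance,
    nj_tree,
    patristic_distance,
    score_ratio_decision,
    tree_filter,
)
from ndescan.discriminate import distance_decision
from ndescan.model import CandidateNDE, FilterParams
from ndescan.simulate import evolve_protein, random_protein

from reference_impls import patristic_matrix, random_unrooted_tree


class TestRefOutScores:
    def test_identical_to_reference(self, small_panel):
        cand = ProteinRecord("c", small_panel.references[0].sequence)
        score_ref, score_out = compute_ref_out_scores(cand, small_panel)
        self_hit = align_local(small_panel.references[0], cand)
        assert score_ref == self_hit.bit_score
        # the outgroup is an unrelated random protein: best case a weak local hit
        assert score_out is None or score_out < score_ref / 3

    def test_empty_outgroups_give_absent_score(self, rng):
        ref = random_protein(rng, 100, id="r")
        panel = ReferencePanel("NicA2", (ref,))
        _, score_out = compute_ref_out_scores(ProteinRecord("c", ref.sequence), panel)
        assert score_out is None

    def test_score_ref_is_max_over_references(self, rng):
        ref1 = random_protein(rng, 150, id="r1")
        ref2 = evolve_protein(ref1, 0.6, rng=rng, new_id="r2")
        panel = ReferencePanel("NicX", (ref1, ref2))
        cand = ProteinRecord("c", ref2.sequence)
        score_ref, _ = compute_ref_out_scores(cand, panel)
        bits = [align_local(r, cand).bit_score for r in panel.references]
        assert score_ref == max(bits)

    def test_unrelated_candidate_raises(self, rng):
        ref = ProteinRecord("r", "AAAAAAA")
        panel = ReferencePanel("NicX", (ref,))
        with pytest.raises(ValueError, match="cannot be a candidate"):
            compute_ref_out_scores(ProteinRecord("c", "WWWWWWW"), panel)


class TestScoreRatioRule:
    def test_equality_at_ratio_boundary_keeps(self):
        # exclusion is strict: ScoreRef exactly 1.2 * ScoreOut is kept
        assert score_ratio_decision(60.0, 50.0, 1.2) is True

    def test_below_ratio_excludes(self):
        assert score_ratio_decision(59.9, 50.0, 1.2) is False

    def test_absent_outgroup_score_keeps(self):
        assert score_ratio_decision(12.0, None, 1.2) is True

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ref, out = float(rng.uniform(5, 100)), float(rng.uniform(5, 100))
            base = score_ratio_decision(ref, out)
            for c in (0.25, 3.0, 117.0):
                assert score_ratio_decision(c * ref, c * out) == base


class TestIndelInspection:
    def test_identical_sequences_have_zero_runs(self, rng):
        ref = random_protein(rng, 200, id="r")
        res = indel_inspection(ProteinRecord("c", ref.sequence), ref)
        assert res.keep and res.longest_insertion == 0 and res.longest_deletion == 0

    def test_long_insertion_excluded(self, rng):
        ref = random_protein(rng, 300, id="r")
        block = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        seq = ref.sequence[:150] + block + ref.sequence[150:]
        res = indel_inspection(ProteinRecord("c", seq), ref, max_indel_run=50)
        assert not res.keep
        assert res.longest_insertion == 60

    def test_short_deletion_kept(self, rng):
        ref = random_protein(rng, 300, id="r")
        seq = ref.sequence[:150] + ref.sequence[160:]
        res = indel_inspection(ProteinRecord("c", seq), ref, max_indel_run=50)
        assert res.keep
        assert res.longest_deletion == 10

    def test_terminal_overhangs_ignored(self, rng):
        # a 70-residue truncation is an overhang, not an internal deletion
        ref = random_protein(rng, 300, id="r")
        res = indel_inspection(ProteinRecord("c", ref.sequence[70:]), ref, max_indel_run=50)
        assert res.keep
        assert res.longest_deletion == 0


class TestKimuraDistance:
    def test_identical_sequences(self, rng):
        a = random_protein(rng, 120, id="a")
        assert kimura_distance(a, ProteinRecord("b", a.sequence)) == 0.0

    def test_half_divergent_closed_form(self, rng):
        # p = 0.5 -> d = -ln(1 - 0.5 - 0.2*0.25) = -ln(0.45)
        a = random_protein(rng, 200, id="a")
        seq = list(a.sequence)
        for i in range(0, 200, 2):
            seq[i] = "A" if seq[i] != "A" else "C"
        b = ProteinRecord("b", "".join(seq))
        d = kimura_distance(a, b)
        assert d == pytest.approx(-math.log(0.45), abs=0.05)

    def test_saturation_ceiling(self):
        # unalignable sequences saturate at the fixed ceiling
        a = ProteinRecord("a", "AAAAAAAAAA" * 10)
        b = ProteinRecord("b", "WYWYWYWYWY" * 10)
        assert kimura_distance(a, b) == 5.0


class TestNeighborJoining:
    def test_four_leaf_additive_matrix(self):
        dm = DistanceMatrix(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
            ["A", "B", "C", "D"],
        )
        tree = nj_tree(dm)
        # generating tree: A:2, B:3 joined; C:4, D:5 joined; internal edge 1
        lengths = {tip.name: tip.length for tip in tree.tips()}
        assert lengths == pytest.approx({"A": 2, "B": 3, "C": 4, "D": 5})
        assert patristic_distance(tree, "A", "B") == pytest.approx(5.0)
        assert patristic_distance(tree, "A", "C") == pytest.approx(7.0)
        internal = [
            n.length for n in tree.traverse(include_self=False) if not n.is_tip()
        ]
        assert sorted(internal) == pytest.approx([1.0])

    def test_three_leaf_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["A", "B", "C"])
        tree = nj_tree(dm)
        # a = (dAB + dAC - dBC)/2 = 1, b = 2, c = 3
        lengths = {tip.name: tip.length for tip in tree.tips()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3})

    def test_round_trip_on_random_five_leaf_trees(self):
        """Patristic matrix in -> NJ -> same patristic matrix out (<= 1e-9),
        over 100 random trees with branch lengths in [0.1, 2]."""
        rng = np.random.default_rng(99)
        leaves = [f"L{i}" for i in range(5)]
        for _ in range(100):
            edges = random_unrooted_tree(rng, 5)
            want = patristic_matrix(edges, leaves)
            tree = nj_tree(DistanceMatrix(want, leaves))
            got = np.array(
                [[patristic_distance(tree, a, b) for b in leaves] for a in leaves]
            )
            assert np.abs(got - want).max() <= 1e-9

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0.0, 1.0], [1.0, 0.0]], ["A", "B"]))

    def test_patristic_identity_and_symmetry(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["A", "B", "C"])
        tree = nj_tree(dm)
        assert patristic_distance(tree, "B", "B") == 0.0
        assert patristic_distance(tree, "A", "C") == patristic_distance(tree, "C", "A")
        with pytest.raises(KeyError):
            patristic_distance(tree, "A", "Z")


class TestTreeFilter:
    def test_distance_rule_boundaries(self):
        assert distance_decision(0.0, 1.0, 0.9) is True
        assert distance_decision(1.0, 1.0, 0.9) is False  # equality excluded
        assert distance_decision(1.0, 1.0, 1.0) is False  # under any margin <= 1
        assert distance_decision(0.89, 1.0, 0.9) is True

    def test_keep_set_shrinks_as_margin_decreases(self, rng):
        d_pairs = [(float(rng.uniform(0, 2)), float(rng.uniform(0.1, 2))) for _ in range(100)]
        previous = None
        for margin in (1.0, 0.9, 0.5, 0.2):
            kept = {i for i, (dr, do) in enumerate(d_pairs) if distance_decision(dr, do, margin)}
            if previous is not None:
                assert kept <= previous
            previous = kept

    @staticmethod
    def _candidate(panel, protein):
        hit = align_local(panel.references[0], protein)
        cand = CandidateNDE(protein, panel.nde_type, hit, score_ref=hit.bit_score)
        cand.add_decision("thresholds", True)
        cand.add_decision("score_ratio", True)
        cand.add_decision("indel_inspection", True)
        return cand

    def test_candidate_identical_to_reference_kept(self, rng):
        ref = random_protein(rng, 200, id="ref")
        out = random_protein(rng, 200, id="out")
        panel = ReferencePanel("NicX", (ref,), (out,))
        cand = self._candidate(panel, ProteinRecord("c", ref.sequence, source_id="G1"))
        (res,), tree = tree_filter([cand], panel)
        assert res.kept
        assert res.d_ref == pytest.approx(0.0, abs=1e-9)
        assert res.d_out > 0

    def test_candidate_inside_outgroup_clade_excluded(self, rng):
        founder = random_protein(rng, 300, id="f")
        out_founder = evolve_protein(founder, 0.55, rng=rng, new_id="of")
        ref = evolve_protein(founder, 0.9, rng=rng, new_id="ref")
        out = evolve_protein(out_founder, 0.9, rng=rng, new_id="out")
        panel = ReferencePanel("NicX", (ref,), (out,))
        decoy = evolve_protein(out, 0.9, rng=rng, new_id="decoy")
        decoy = ProteinRecord(decoy.id, decoy.sequence, source_id="G1")
        (res,), _ = tree_filter([self._candidate(panel, decoy)], panel)
        assert not res.kept
        assert res.d_out < res.d_ref

    def test_no_outgroups_bypass(self, rng):
        ref = random_protein(rng, 150, id="ref")
        panel = ReferencePanel("NicA2", (ref,))
        cand = self._candidate(panel, ProteinRecord("c", ref.sequence, source_id="G1"))
        results, tree = tree_filter([cand], panel)
        assert tree is None
        assert results[0].kept and results[0].d_ref is None


class TestAnnotateCascade:
    def test_empty_proteomes_give_empty_table(self, small_panel):
        result = annotate([small_panel], {})
        assert result.table.empty

    def test_benchmark_homologs_annotated_decoys_excluded(
        self, default_benchmark, default_annotation
    ):
        from ndescan import score_benchmark

        score = score_benchmark(default_benchmark.truth, default_annotation.table)
        assert score.precision == 1.0
        assert score.recall >= 0.9
        assert score.stage_agreement == 1.0

    def test_every_surviving_candidate_has_full_trace(self, default_annotation):
        for cand in default_annotation.candidates:
            stages = [d.stage for d in cand.decisions]
            if cand.final_status == "annotated":
                assert stages == ["thresholds", "score_ratio", "indel_inspection", "tree_filter"]
                assert all(d.passed for d in cand.decisions)
            else:
                assert not cand.decisions[-1].passed

    def test_gates_never_bypassed_downstream(self, default_annotation):
        annotated = default_annotation.annotated()
        assert (annotated["identity_pct"] >= 30).all()
        assert (annotated["ref_coverage_pct"] >= 40).all()

    def test_stage_counts_self_consistent(self, default_annotation):
        counts = default_annotation.stage_counts
        assert (counts["entered"] == counts["kept"] + counts["excluded"]).all()
        # each later stage enters exactly what the previous stage kept
        for nde_type, sub in counts.groupby("nde_type"):
            sub = sub.reset_index(drop=True)
            for i in range(1, len(sub)):
                assert sub.loc[i, "entered"] == sub.loc[i - 1, "kept"]

    def test_rerun_is_deterministic(self, default_benchmark, default_annotation):
        types = ("NicA1", "NicA2")
        panels = [p for p in default_benchmark.panels if p.nde_type in types]
        once = annotate(panels, default_benchmark.proteomes)
        again = annotate(panels, default_benchmark.proteomes)
        assert once.table.equals(again.table)
        expected = default_annotation.table
        expected = expected[expected["nde_type"].isin(types)].reset_index(drop=True)
        assert once.table.equals(expected)
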
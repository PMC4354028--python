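import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import epipluri as ep
from epipluri.exceptions import MissingValueError, SelectionError
from epipluri.markers import HYPER, HYPO

from _brute import brute_rank


def _matrix(rows: dict[str, list[float]], samples: list[str]) -> ep.BetaMatrix:
    return ep.BetaMatrix(pd.DataFrame.from_dict(
        rows, orient="index", columns=samples, dtype=float,
    ))


def _annotations(labels: dict[str, str]) -> list[ep.SampleAnnotation]:
    return [ep.SampleAnnotation(s, l) for s, l in labels.items()]


class TestComputeMargin:
    def test_separated_groups(self):
        c = ep.compute_margin([0.1, 0.2], [0.6, 0.9])
        assert c.margin == pytest.approx(0.4)
        assert c.direction == HYPO
        assert c.cutoff == pytest.approx(0.4)

    def test_overlapping_ranges_negative_margin(self):
        c = ep.compute_margin([0.1, 0.7], [0.5, 0.9])
        assert c.margin == pytest.approx(-0.2)
        assert c.cutoff is None

    def test_degenerate_equal_points(self):
        c = ep.compute_margin([0.5], [0.5])
        assert c.margin == 0.0
        assert c.cutoff is None

    def test_hyper_direction(self):
        c = ep.compute_margin([0.8, 0.9], [0.1, 0.3])
        assert c.direction == HYPER
        assert c.margin == pytest.approx(0.5)
        assert c.cutoff == pytest.approx(0.55)

    def test_empty_group_errors(self):
        with pytest.raises(SelectionError, match="empty"):
            ep.compute_margin([], [0.5])

    def test_missing_value_names_sample(self):
        with pytest.raises(MissingValueError, match="S2"):
            ep.compute_margin([0.1, float("nan")], [0.9],
                              group1_sample_ids=["S1", "S2"])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8),
           st.lists(st.floats(0, 1), min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    def test_margin_invariant_under_within_group_permutation(self, g1, g2, rnd):
        base = ep.compute_margin(g1, g2)
        p1, p2 = list(g1), list(g2)
        rnd.shuffle(p1)
        rnd.shuffle(p2)
        perm = ep.compute_margin(p1, p2)
        assert perm.margin == base.margin
        assert perm.direction == base.direction

    def test_cutoff_inside_gap_whenever_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            g1 = rng.uniform(0, 1, size=rng.integers(1, 6))
            g2 = rng.uniform(0, 1, size=rng.integers(1, 6))
            c = ep.compute_margin(g1, g2)
            if c.margin > 0:
                lo, hi = ((g1.max(), g2.min()) if c.direction == HYPO
                          else (g2.max(), g1.min()))
                assert lo < c.cutoff < hi


class TestRankByMargin:
    def test_planted_separator_ranked_first_vs_brute_force(self):
        rng = np.random.default_rng(42)
        samples = [f"P{i}" for i in range(5)] + [f"S{i}" for i in range(8)]
        labels = {s: ("pluripotent" if s.startswith("P") else "somatic")
                  for s in samples}
        rows = {f"cg{i:03d}": rng.uniform(0, 1, len(samples)).tolist()
                for i in range(100)}
        rows["cg_planted"] = [0.05] * 5 + [0.8] * 8
        matrix = _matrix(rows, samples)
        ranked = ep.rank_by_margin(matrix, _annotations(labels))
        oracle = brute_rank(matrix, _annotations(labels))
        assert ranked[0].cpg_id == "cg_planted"
        assert [c.cpg_id for c in ranked] == [t[0] for t in oracle]
        for c, (cpg, margin, direction, _) in zip(ranked, oracle):
            assert c.margin == pytest.approx(margin)
            assert c.direction == direction

    def test_all_constant_matrix_orders_lexicographically(self):
        samples = ["P1", "S1"]
        matrix = _matrix({"cgB": [0.5, 0.5], "cgA": [0.5, 0.5]}, samples)
        ranked = ep.rank_by_margin(
            matrix, _annotations({"P1": "pluripotent", "S1": "somatic"}))
        assert [c.cpg_id for c in ranked] == ["cgA", "cgB"]
        assert all(c.margin == 0 for c in ranked)

    def test_identical_rows_tie_broken_by_id(self):
        samples = ["P1", "P2", "S1"]
        row = [0.1, 0.15, 0.8]
        matrix = _matrix({"cgZ": row, "cgA": row}, samples)
        ranked = ep.rank_by_margin(matrix, _annotations(
            {"P1": "pluripotent", "P2": "pluripotent", "S1": "somatic"}))
        assert [c.cpg_id for c in ranked] == ["cgA", "cgZ"]

    def test_missing_value_errors_unless_allowed(self):
        samples = ["P1", "S1", "S2"]
        matrix = _matrix({"cg1": [0.1, np.nan, 0.9]}, samples)
        anns = _annotations(
            {"P1": "pluripotent", "S1": "somatic", "S2": "somatic"})
        with pytest.raises(MissingValueError, match="S1"):
            ep.rank_by_margin(matrix, anns)
        ranked = ep.rank_by_margin(matrix, anns, allow_missing=True)
        assert ranked[0].margin == pytest.approx(0.8)

    def test_absent_label_errors(self):
        matrix = _matrix({"cg1": [0.1]}, ["P1"])
        with pytest.raises(SelectionError, match="somatic"):
            ep.rank_by_margin(matrix, _annotations({"P1": "pluripotent"}))


class TestCriterion2:
    def _candidate(self, direction=HYPER, cutoff=0.5):
        return ep.MarkerCandidate("cgX", direction, 0.3, cutoff)

    def test_fifteen_of_eighteen(self):
        # hyper-in-pluripotent marker: non-pluripotent side is below cutoff
        values = [0.2] * 15 + [0.9] * 3
        frac = ep.criterion2_fraction(self._candidate(), values)
        assert frac == pytest.approx(15 / 18)
        assert round(100 * frac) == 83

    def test_all_on_pluripotent_side_is_zero(self):
        assert ep.criterion2_fraction(self._candidate(), [0.9, 0.8]) == 0.0

    def test_strictly_beyond_cutoff_counts(self):
        c = self._candidate(direction=HYPO, cutoff=0.4)
        assert ep.criterion2_fraction(c, [0.41, 0.5, 0.99]) == 1.0
        assert ep.criterion2_fraction(c, [0.4]) == 0.0  # on the cutoff

    def test_requires_positive_margin(self):
        bad = ep.MarkerCandidate("cgX", HYPER, -0.1, None)
        with pytest.raises(SelectionError):
            ep.criterion2_fraction(bad, [0.5])

    def test_no_differentiated_samples_errors(self):
        with pytest.raises(SelectionError):
            ep.criterion2_fraction(self._candidate(), [])


class TestSelectScorePair:
    def _cohort(self):
        samples = (["P1", "P2", "P3"], ["S1", "S2", "S3"], ["D1", "D2"])
        labels = {}
        for group, label in zip(samples,
                                ("pluripotent", "somatic", "differentiated")):
            labels.update({s: label for s in group})
        flat = [s for g in samples for s in g]
        rows = {
            # planted hypo-in-pluripotent, margin 0.4
            "cg_hypo": [0.1, 0.15, 0.2] + [0.6, 0.7, 0.9] + [0.5, 0.65],
            # planted hyper, margin 0.3, both differentiated below cutoff
            "cg_hyper": [0.8, 0.85, 0.9] + [0.3, 0.4, 0.5] + [0.55, 0.6],
            # decoy hyper with identical margin but worse criterion-2
            "cg_decoy": [0.8, 0.85, 0.9] + [0.3, 0.4, 0.5] + [0.8, 0.6],
            "cg_flat": [0.5] * 8,
        }
        return _matrix(rows, flat), _annotations(labels)

    def test_recovers_planted_pair_over_decoy(self):
        matrix, anns = self._cohort()
        hypo, hyper = ep.select_score_pair(matrix, anns)
        assert hypo.cpg_id == "cg_hypo"
        assert hyper.cpg_id == "cg_hyper"
        assert hyper.criterion2_fraction == 1.0
        # exhaustive check: no hyper candidate beats the chosen one
        ranked = ep.rank_by_margin(matrix, anns)
        for c in ranked:
            if c.direction == HYPER and c.margin > 0:
                diff = matrix.data.loc[c.cpg_id, ["D1", "D2"]]
                assert (ep.criterion2_fraction(c, diff)
                        <= hyper.criterion2_fraction)

    def test_zero_tolerance_reduces_to_margin_maximisation(self):
        matrix, anns = self._cohort()
        _, hyper = ep.select_score_pair(matrix, anns, margin_tolerance=0.0)
        # cg_hyper and cg_decoy tie on margin exactly; criterion 2 breaks it
        assert hyper.cpg_id == "cg_hyper"

    def test_requires_differentiated_samples(self):
        matrix, anns = self._cohort()
        anns = [a for a in anns if a.label != "differentiated"]
        with pytest.raises(SelectionError, match="criterion 2"):
            ep.select_score_pair(matrix, anns)

    def test_requires_positive_margin_in_both_directions(self):
        samples = ["P1", "S1", "D1"]
        anns = _annotations({"P1": "pluripotent", "S1": "somatic",
                             "D1": "differentiated"})
        only_hypo = _matrix({"cg1": [0.1, 0.9, 0.5]}, samples)
        with pytest.raises(SelectionError, match="hyper"):
            ep.select_score_pair(only_hypo, anns)


class TestGeneRestrictedSelection:
    def test_best_cpg_per_gene(self):
        samples = ["P1", "S1"]
        anns = _annotations({"P1": "pluripotent", "S1": "somatic"})
        matrix = _matrix({
            "cg_a1": [0.4, 0.5],   # margin 0.1
            "cg_a2": [0.3, 0.6],   # margin 0.3 -> best in geneA
            "cg_b1": [0.45, 0.55],
            "cg_global": [0.0, 1.0],
        }, samples)
        gene_map = {"cg_a1": "geneA", "cg_a2": "geneA", "cg_b1": "geneB"}
        best = ep.best_cpg_in_genes(matrix, anns, gene_map,
                                    ["geneA", "geneB", "geneC"])
        assert best["geneA"].cpg_id == "cg_a2"
        # reported per gene even though cg_global has a larger margin
        assert best["geneB"].cpg_id == "cg_b1"
        assert best["geneC"] is None

    def test_single_cpg_gene_returned_regardless_of_sign(self):
        samples = ["P1", "P2", "S1"]
        anns = _annotations({"P1": "pluripotent", "P2": "pluripotent",
                             "S1": "somatic"})
        matrix = _matrix({"cg_only": [0.1, 0.9, 0.5]}, samples)
        best = ep.best_cpg_in_genes(matrix, anns, {"cg_only": "g"}, ["g"])
        assert best["g"].cpg_id == "cg_only"
        assert best["g"].margin < 0


class TestPerfectSeparators:
    def test_exactly_planted_separators_returned(self):
        rng = np.random.default_rng(7)
        samples = [f"P{i}" for i in range(6)] + [f"S{i}" for i in range(6)]
        anns = _annotations({s: ("pluripotent" if s.startswith("P")
                                 else "somatic") for s in samples})
        rows = {}
        planted = set()
        for i in range(50):
            # class-independent draws: overlapping with high probability
            rows[f"cg{i:03d}"] = rng.uniform(0.2, 0.8, 12).tolist()
        for i in range(4):
            cpg = f"cg_sep{i}"
            planted.add(cpg)
            rows[cpg] = ([rng.uniform(0, 0.2) for _ in range(6)]
                         + [rng.uniform(0.7, 1) for _ in range(6)])
        matrix = _matrix(rows, samples)
        found = ep.enumerate_perfect_separators(matrix, anns)
        found_ids = {c.cpg_id for c in found}
        assert planted <= found_ids
        # oracle: exhaustive scan agrees exactly
        oracle_ids = {t[0] for t in brute_rank(matrix, anns) if t[1] > 0}
        assert found_ids == oracle_ids

    def test_zero_margin_excluded_and_overlap_gives_empty(self):
        samples = ["P1", "S1"]
        anns = _annotations({"P1": "pluripotent", "S1": "somatic"})
        matrix = _matrix({"cg1": [0.5, 0.5]}, samples)
        assert ep.enumerate_perfect_separators(matrix, anns) == []

    def test_separator_cutoffs_make_zero_training_errors(self, default_cohort):
        _, matrix, annotations, _ = default_cohort
        pluri = [a.sample_id for a in annotations if a.label == "pluripotent"]
        soma = [a.sample_id for a in annotations if a.label == "somatic"]
        for c in ep.enumerate_perfect_separators(matrix, annotations):
            row = matrix.row(c.cpg_id)
            g1, g2 = row[pluri], row[soma]
            if c.direction == HYPO:
                assert (g1 < c.cutoff).all() and (g2 > c.cutoff).all()
            else:
                assert (g1 > c.cutoff).all() and (g2 < c.cutoff).all()


class TestParthenogenicPair:
    def test_planted_imprinting_pair_recovered(self, default_cohort):
        _, matrix, annotations, truth = default_cohort
        up, down = ep.select_parthenogenic_pair(matrix, annotations)
        assert up.cpg_id == ep.SNURF_CPG
        assert down.cpg_id == ep.H19_CPG
        assert up.direction == HYPER and down.direction == HYPO
        # oracle: exhaustive per-direction scan
        oracle = brute_rank(matrix, annotations,
                            group1="parthenogenic", group2="pluripotent")
        assert oracle[0][0] in {ep.SNURF_CPG, ep.H19_CPG}

    def test_no_positive_margin_errors(self):
        samples = ["E1", "X1"]
        anns = _annotations({"E1": "pluripotent", "X1": "parthenogenic"})
        matrix = _matrix({"cg1": [0.5, 0.5]}, samples)
        with pytest.raises(SelectionError, match="parthenogenic"):
            ep.select_parthenogenic_pair(matrix, anns)

    def test_single_parthenogenic_sample_runs(self):
        samples = ["E1", "E2", "X1"]
        anns = _annotations({"E1": "pluripotent", "E2": "pluripotent",
                             "X1": "parthenogenic"})
        matrix = _matrix({"cg_up": [0.2, 0.3, 0.9],
                          "cg_down": [0.8, 0.7, 0.1]}, samples)
        up, down = ep.select_parthenogenic_pair(matrix, anns)
        assert up.cpg_id == "cg_up" and down.cpg_id == "cg_down"
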
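import numpy as np
import pytest

from plmhomology import (
    auroc,
    judge_results,
    mean_average_precision,
    precision_at_k,
    quadrant_analysis,
    sensitivity_to_first_fp,
    stratum_sizes,
    weighted_pr_curve,
)
from plmhomology.metrics import JudgedHit, average_precision, judge_fold_pair
from plmhomology.pipeline import SearchHit, SearchResult
from plmhomology.records import FoldLabel

from oracles import (
    brute_average_precision,
    brute_p_at_k,
    brute_sensitivity,
    brute_weighted_pr,
)


def hits(*labels, scores=None):
    scores = scores or [1.0 - 0.01 * i for i in range(len(labels))]
    return [JudgedHit(f"t{i}", s, lab) for i, (lab, s) in enumerate(zip(labels, scores))]


LAB = {
    "a": FoldLabel("a", "fam1", "sf1", "fold1"),
    "b": FoldLabel("b", "fam1", "sf1", "fold1"),
    "c": FoldLabel("c", "fam2", "sf1", "fold1"),
    "d": FoldLabel("d", "fam3", "sf2", "fold1"),
    "e": FoldLabel("e", "fam4", "sf3", "fold2"),
}


class TestJudging:
    def test_same_family_pair_labels_per_level(self):
        assert judge_fold_pair(LAB["a"], LAB["b"], "family") == "TP"
        assert judge_fold_pair(LAB["a"], LAB["b"], "superfamily") == "ignore"
        assert judge_fold_pair(LAB["a"], LAB["b"], "fold") == "ignore"

    def test_same_superfamily_different_family(self):
        assert judge_fold_pair(LAB["a"], LAB["c"], "family") == "ignore"
        assert judge_fold_pair(LAB["a"], LAB["c"], "superfamily") == "TP"
        assert judge_fold_pair(LAB["a"], LAB["c"], "fold") == "ignore"

    def test_same_fold_different_superfamily(self):
        assert judge_fold_pair(LAB["a"], LAB["d"], "fold") == "TP"
        assert judge_fold_pair(LAB["a"], LAB["d"], "superfamily") == "ignore"

    def test_different_fold_is_fp_everywhere(self):
        for level in ("family", "superfamily", "fold"):
            assert judge_fold_pair(LAB["a"], LAB["e"], level) == "FP"

    def test_tm_level_strict_threshold_and_self_ignored(self):
        results = [
            SearchResult(
                "a",
                (
                    SearchHit("a", 1.0, 1, is_self=True),
                    SearchHit("b", 0.9, 2),
                    SearchHit("c", 0.8, 3),
                ),
            )
        ]
        tm = {("a", "b"): 0.5, ("a", "c"): 0.51}
        judged = judge_results(results, "tm_score", tm_scores=tm)
        labels = {h.target_id: h.label for h in judged["a"]}
        assert labels == {"a": "ignore", "b": "FP", "c": "TP"}

    def test_missing_label_errors(self):
        results = [SearchResult("a", (SearchHit("zz", 0.9, 1),))]
        with pytest.raises(KeyError, match="zz"):
            judge_results(results, "fold", fold_labels=LAB)


class TestSensitivity:
    def test_hand_example_two_thirds(self):
        assert sensitivity_to_first_fp(hits("TP", "TP", "FP", "TP")) == pytest.approx(
            2 / 3
        )

    def test_no_fp_full_sensitivity(self):
        assert sensitivity_to_first_fp(hits("TP", "TP", "TP", "TP")) == 1.0

    def test_first_item_fp_zero(self):
        assert sensitivity_to_first_fp(hits("FP", "TP")) == 0.0

    def test_no_tp_excluded(self):
        assert sensitivity_to_first_fp(hits("FP", "FP")) is None

    def test_ignores_removed_before_counting(self):
        with_ignores = hits("TP", "ignore", "TP", "ignore", "FP", "TP")
        assert sensitivity_to_first_fp(with_ignores) == pytest.approx(2 / 3)

    def test_tie_across_boundary_counts_fp_first(self):
        tied = [
            JudgedHit("t1", 0.9, "TP"),
            JudgedHit("t2", 0.5, "TP"),
            JudgedHit("t3", 0.5, "FP"),
        ]
        assert sensitivity_to_first_fp(tied) == pytest.approx(1 / 2)


class TestAuroc:
    def test_mean_of_sensitivities(self):
        judged = {"q1": hits("TP", "TP"), "q2": hits("TP", "FP", "TP")}
        assert auroc(judged) == pytest.approx((1.0 + 0.5) / 2)

    def test_single_query(self):
        assert auroc({"q": hits("TP", "FP", "TP")}) == 0.5

    def test_zero_tp_queries_excluded_from_mean(self):
        judged = {"q1": hits("TP"), "q2": hits("FP", "FP")}
        assert auroc(judged) == 1.0

    def test_no_eligible_queries_errors(self):
        with pytest.raises(ValueError):
            auroc({"q": hits("FP")})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_fixture(self, seed):
        rng = np.random.default_rng(seed)
        judged = {}
        for q in range(6):
            labels = list(rng.choice(["TP", "FP", "ignore"], size=12))
            scores = list(np.sort(rng.uniform(size=12))[::-1])
            judged[f"q{q}"] = hits(*labels, scores=scores)
        expected = [
            brute_sensitivity([h.label for h in hs if h.label != "ignore"])
            for hs in judged.values()
        ]
        expected = [s for s in expected if s is not None]
        assert auroc(judged) == pytest.approx(np.mean(expected))

    def test_invariant_to_monotone_score_transformation(self):
        rng = np.random.default_rng(42)
        labels = list(rng.choice(["TP", "FP"], size=10))
        scores = list(np.sort(rng.uniform(size=10))[::-1])
        j1 = {"q": hits(*labels, scores=scores)}
        j2 = {"q": hits(*labels, scores=[np.exp(3 * s) for s in scores])}
        assert auroc(j1) == auroc(j2)


class TestMapAndPk:
    def test_hand_example_avep(self):
        assert average_precision(hits("TP", "FP", "TP")) == pytest.approx(0.83333, abs=1e-4)

    def test_perfect_ranking(self):
        assert mean_average_precision({"q": hits("TP", "TP", "FP")}) == 1.0

    def test_single_tp_at_last_rank(self):
        n = 6
        labels = ["FP"] * (n - 1) + ["TP"]
        assert average_precision(hits(*labels)) == pytest.approx(1 / n)

    @pytest.mark.parametrize("seed", range(5))
    def test_map_and_pk_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        judged = {}
        for q in range(5):
            labels = list(rng.choice(["TP", "FP"], size=15))
            scores = list(np.sort(rng.uniform(size=15))[::-1])
            judged[f"q{q}"] = hits(*labels, scores=scores)
        label_lists = {q: [h.label for h in hs] for q, hs in judged.items()}
        expected_aps = [
            brute_average_precision(labs) for labs in label_lists.values()
        ]
        expected_aps = [a for a in expected_aps if a is not None]
        assert mean_average_precision(judged) == pytest.approx(np.mean(expected_aps))
        for k in (1, 5, 10):
            expected_pk = np.mean(
                [brute_p_at_k(labs, k) for labs in label_lists.values()]
            )
            assert precision_at_k(judged, k) == pytest.approx(expected_pk)

    def test_pk_short_list_padded_as_nonrelevant(self):
        judged = {"q": hits("TP", "TP")}
        assert precision_at_k(judged, 10) == pytest.approx(0.2)

    def test_pk_mean_over_queries(self):
        judged = {
            "q1": hits(*(["TP"] * 3 + ["FP"] * 2)),
            "q2": hits(*(["TP"] * 4 + ["FP"])),
        }
        assert precision_at_k(judged, 5) == pytest.approx(0.7)


class TestWeightedPr:
    def test_uniform_weights_reduce_to_classic_pr(self):
        rng = np.random.default_rng(0)
        labels = list(rng.choice(["TP", "FP"], size=20))
        scores = list(np.sort(rng.uniform(size=20))[::-1])
        judged = {"q": hits(*labels, scores=scores)}
        r1, p1, a1 = weighted_pr_curve(judged, None)
        r2, p2, a2 = weighted_pr_curve(judged, {"q": 1.0})
        assert np.allclose(r1, r2) and np.allclose(p1, p2) and a1 == a2

    def test_reciprocal_stratum_weights(self):
        labels = {
            "a": FoldLabel("a", "f1", "s1", "x"),
            "b": FoldLabel("b", "f1", "s1", "x"),
            "c": FoldLabel("c", "f2", "s2", "y"),
        }
        sizes = stratum_sizes(labels, "fold")
        assert sizes == {"a": 2, "b": 2, "c": 1}

    @pytest.mark.parametrize("seed", range(4))
    def test_curve_matches_threshold_sweep_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        judged, rows = {}, []
        for q in range(4):
            w = float(rng.uniform(0.2, 1.0))
            labels = list(rng.choice(["TP", "FP"], size=10))
            # distinct scores across all queries so both sweeps visit the
            # same achieved points
            scores = list(rng.permutation(np.linspace(0.1, 0.9, 10)) + q * 1e-3)
            judged[f"q{q}"] = hits(*labels, scores=scores)
            rows += [(s, lab, w) for s, lab in zip(scores, labels)]
        weights = {f"q{q}": rows[q * 10][2] for q in range(4)}
        recall, precision, aupr = weighted_pr_curve(judged, weights)
        o_recall, o_precision, o_aupr = brute_weighted_pr(rows)
        ours = np.array(sorted(zip(recall, precision)))
        oracle = np.array(sorted(zip(o_recall, o_precision)))
        assert ours.shape == oracle.shape
        assert np.allclose(ours, oracle)
        assert aupr == pytest.approx(o_aupr)

    def test_removing_ignore_changes_nothing(self):
        base = hits("TP", "FP", "TP", scores=[0.9, 0.5, 0.2])
        padded = base + [JudgedHit("tx", 0.7, "ignore")]
        for fn in (sensitivity_to_first_fp, average_precision):
            assert fn(base) == fn(padded)
        _, _, a1 = weighted_pr_curve({"q": base})
        _, _, a2 = weighted_pr_curve({"q": padded})
        assert a1 == a2


class TestQuadrants:
    def test_remote_recalled_case(self):
        counts = quadrant_analysis([(0.74, 0.216, True)])
        assert counts["remote_recalled"] == 1

    def test_easy_quadrant(self):
        counts = quadrant_analysis([(0.8, 0.5, True), (0.9, 0.4, False)])
        assert counts["easy_recalled"] == 1 and counts["easy_missed"] == 1

    def test_low_tm_not_a_homolog(self):
        counts = quadrant_analysis([(0.4, 0.9, True)])
        assert counts["non_homolog"] == 1
        assert counts["easy_recalled"] == counts["remote_recalled"] == 0
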
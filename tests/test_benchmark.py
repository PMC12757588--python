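import itertools

import numpy as np
import pandas as pd
import pytest

from popinfer import (
    ReferenceNetwork,
    ValidationError,
    build_evaluable_predictions,
    early_prc,
    run_benchmark,
)


def ranked_df(labels, scores=None):
    """Candidate list from a TP/FP pattern; distinct scores unless given."""
    n = len(labels)
    scores = np.linspace(1, 0.1, n) if scores is None else np.asarray(scores, float)
    return pd.DataFrame(
        {
            "regulator": [f"r{i}" for i in range(n)],
            "target": [f"t{i}" for i in range(n)],
            "score": scores,
        }
    ), {(f"r{i}", f"t{i}") for i, lab in enumerate(labels) if lab == "TP"}


def brute_force_auprc(labels, r_max=1.0):
    """Walk a distinct-score ranking one prediction at a time and
    accumulate precision x recall-increment, truncated at r_max."""
    P = labels.count("TP")
    tp = 0
    area = 0.0
    r_prev = 0.0
    for i, lab in enumerate(labels, start=1):
        if lab == "TP":
            tp += 1
            recall = tp / P
            if recall > r_prev:
                area += (tp / i) * (min(recall, r_max) - r_prev)
                r_prev = min(recall, r_max)
            if r_prev >= r_max:
                break
    return area / r_max


class TestCandidateRestriction:
    def test_universe_restriction(self):
        net = pd.DataFrame(
            np.full((3, 3), 0.5) - np.eye(3) * 0.5,
            index=["A", "B", "C"], columns=["A", "B", "C"],
        )
        ref = ReferenceNetwork.from_edges([("A", "B"), ("A", "C")])
        ranked = build_evaluable_predictions(net, ref)
        assert len(ranked) == 2
        assert set(ranked.regulator) == {"A"}

    def test_all_zero_scores_form_one_tie_group(self):
        net = pd.DataFrame(np.zeros((3, 3)), index=list("ABC"), columns=list("ABC"))
        ref = ReferenceNetwork.from_edges([("A", "B"), ("B", "C")])
        ranked = build_evaluable_predictions(net, ref)
        assert ranked.score.nunique() == 1

    def test_no_overlap_raises(self):
        net = pd.DataFrame(np.zeros((2, 2)), index=["X", "Y"], columns=["X", "Y"])
        ref = ReferenceNetwork.from_edges([("A", "B")])
        with pytest.raises(ValidationError, match="no evaluable"):
            build_evaluable_predictions(net, ref)


class TestEarlyPRC:
    def test_perfect_ranking_for_any_rmax(self):
        ranked, pos = ranked_df(["TP", "TP", "FP", "FP"])
        for r_max in (0.015, 0.1, 0.5, 1.0):
            assert early_prc(ranked, pos, r_max).aueprc == pytest.approx(1.0)

    def test_worked_example_full_range(self):
        ranked, pos = ranked_df(["TP", "FP", "TP", "FP"])
        result = early_prc(ranked, pos, 1.0)
        assert result.aueprc == pytest.approx(1 * 0.5 + (2 / 3) * 0.5)

    def test_worked_example_half_range(self):
        ranked, pos = ranked_df(["TP", "FP", "TP", "FP"])
        assert early_prc(ranked, pos, 0.5).aueprc == pytest.approx(1.0)

    def test_exhaustive_against_brute_force_oracle(self):
        # all placements of 4 positives among 8 candidates, two recall ranges
        for positions in itertools.combinations(range(8), 4):
            labels = ["TP" if i in positions else "FP" for i in range(8)]
            ranked, pos = ranked_df(labels)
            for r_max in (1.0, 0.5):
                assert early_prc(ranked, pos, r_max).aueprc == pytest.approx(
                    brute_force_auprc(labels, r_max)
                ), (labels, r_max)

    def test_tie_group_enters_atomically(self):
        # TP and FP share a score: the curve point sees both at once
        ranked, pos = ranked_df(["TP", "FP"], scores=[0.5, 0.5])
        result = early_prc(ranked, pos, 1.0)
        assert result.precision_points.tolist() == [0.5]
        assert result.aueprc == pytest.approx(0.5)

    def test_invariant_to_order_within_tie_group(self):
        ranked1, pos = ranked_df(["TP", "FP", "TP"], scores=[0.9, 0.5, 0.5])
        ranked2 = ranked1.iloc[[0, 2, 1]].reset_index(drop=True)
        a1 = early_prc(ranked1, pos, 1.0).aueprc
        a2 = early_prc(ranked2, pos, 1.0).aueprc
        assert a1 == pytest.approx(a2)

    def test_invariant_to_gene_relabeling(self):
        ranked, pos = ranked_df(["TP", "FP", "TP", "FP", "TP"])
        mapping = {n: f"x_{n}" for n in set(ranked.regulator) | set(ranked.target)}
        renamed = ranked.assign(
            regulator=ranked.regulator.map(mapping), target=ranked.target.map(mapping)
        )
        renamed_pos = {(mapping[r], mapping[t]) for r, t in pos}
        assert early_prc(ranked, pos, 0.7).aueprc == pytest.approx(
            early_prc(renamed, renamed_pos, 0.7).aueprc
        )

    def test_recall_points_non_decreasing_and_area_bounded(self):
        rng = np.random.default_rng(0)
        labels = ["TP" if rng.random() < 0.3 else "FP" for _ in range(40)]
        if "TP" not in labels:
            labels[0] = "TP"
        ranked, pos = ranked_df(labels)
        res = early_prc(ranked, pos, 0.25)
        assert np.all(np.diff(res.recall_points) >= 0)
        assert 0.0 <= res.aueprc <= 1.0

    def test_no_positive_among_candidates_raises(self):
        ranked, _ = ranked_df(["FP", "FP"])
        with pytest.raises(ValidationError):
            early_prc(ranked, {("a", "b")}, 1.0)


class TestRunBenchmark:
    def test_identical_networks_identical_score(self):
        net = pd.DataFrame(
            [[0.0, 0.9], [0.2, 0.0]], index=["A", "B"], columns=["A", "B"]
        )
        ref = ReferenceNetwork.from_edges([("A", "B"), ("B", "A")])
        table = run_benchmark({"x": net, "y": net.copy()}, ref, 1.0)
        assert table.aueprc[0] == table.aueprc[1]

    def test_informative_beats_shuffled_scores(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(8)]
        truth = [("g0", "g4"), ("g1", "g5"), ("g2", "g6"), ("g3", "g7")]
        ref = ReferenceNetwork.from_edges(truth)
        W = pd.DataFrame(0.0, index=genes, columns=genes)
        for r, t in truth:
            W.at[r, t] = 0.9
        perfect = run_benchmark({"net": W}, ref, 1.0).aueprc[0]
        shuffled_scores = []
        for _ in range(50):
            Ws = W.copy()
            vals = Ws.to_numpy().ravel()
            rng.shuffle(vals)
            Ws.iloc[:, :] = vals.reshape(Ws.shape)
            np.fill_diagonal(Ws.values, 0.0)
            shuffled_scores.append(run_benchmark({"net": Ws}, ref, 1.0).aueprc[0])
        assert perfect == pytest.approx(1.0)
        assert perfect >= np.mean(shuffled_scores)

    def test_random_scores_approach_positive_rate(self):
        # with random rankings, mean AUEPRC ~ fraction of positives
        # (approached from above: random-ranking AUPRC has a positive
        # finite-sample bias that shrinks with the candidate count)
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(20)]
        pairs = [(a, b) for a in genes for b in genes if a != b]
        pos = set(map(tuple, rng.choice(pairs, size=100, replace=False)))
        rate = len(pos) / len(pairs)
        means = []
        for _ in range(200):
            scores = rng.random(len(pairs))
            ranked = pd.DataFrame(
                {"regulator": [p[0] for p in pairs],
                 "target": [p[1] for p in pairs],
                 "score": scores}
            ).sort_values("score", ascending=False)
            means.append(early_prc(ranked, pos, 1.0).aueprc)
        assert np.mean(means) == pytest.approx(rate, abs=0.03)
        assert np.mean(means) >= rate

    def test_failing_network_reported_not_fatal(self):
        good = pd.DataFrame([[0.0, 0.9], [0.1, 0.0]], index=["A", "B"], columns=["A", "B"])
        bad = pd.DataFrame([[0.0, 0.9], [0.1, 0.0]], index=["X", "Y"], columns=["X", "Y"])
        ref = ReferenceNetwork.from_edges([("A", "B")])
        table = run_benchmark({"good": good, "bad": bad}, ref, 1.0)
        assert not np.isnan(table.set_index("name").at["good", "aueprc"])
        assert np.isnan(table.set_index("name").at["bad", "aueprc"])
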
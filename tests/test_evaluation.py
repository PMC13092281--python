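"""Deduplicated ranking metrics, baselines and Fisher enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from phagedefense.evaluation import (
    ScoredGene,
    cosine_nn_baseline,
    dedup_top_per_group,
    fisher_enrichment_p,
    guilt_by_association,
    pr_curve_and_ap,
    prospective_system_summary,
    signed_best_hit_baseline,
    top_k_precision,
)
from phagedefense.model import PredictionRecord

from conftest import make_gene, make_genome


def _sg(gene_id, score, label, group=""):
    return ScoredGene(gene_id=gene_id, score=score, label=label, dedup_group=group)


# ---------------------------------------------------------------------------
# dedup


def test_dedup_keeps_top_scorer_per_group():
    out = dedup_top_per_group([_sg("a", 0.9, 1, "g"), _sg("b", 0.2, 1, "g")])
    assert [e.gene_id for e in out] == ["a"]


def test_dedup_singletons_are_identity():
    entries = [_sg("a", 0.3, 0), _sg("b", 0.5, 1)]
    out = dedup_top_per_group(entries)
    assert {e.gene_id for e in out} == {"a", "b"}


def test_dedup_tie_breaks_to_smallest_id():
    out = dedup_top_per_group([_sg("b", 0.7, 1, "g"), _sg("a", 0.7, 0, "g")])
    assert [e.gene_id for e in out] == ["a"]


def test_dedup_never_increases_positives_and_preserves_labels(rng):
    for _ in range(20):
        entries = [
            _sg(f"g{i}", float(rng.random()), int(rng.random() < 0.3), f"grp{int(rng.integers(5))}")
            for i in range(30)
        ]
        out = dedup_top_per_group(entries)
        assert sum(e.label for e in out) <= sum(e.label for e in entries)
        by_id = {e.gene_id: e.label for e in entries}
        assert all(by_id[e.gene_id] == e.label for e in out)


# ---------------------------------------------------------------------------
# PR / AP / AUROC


def _ranking(labels_in_order):
    n = len(labels_in_order)
    return [
        _sg(f"g{i}", float(n - i), int(l)) for i, l in enumerate(labels_in_order)
    ]


def test_ap_matches_hand_computed_example():
    ev = pr_curve_and_ap(_ranking([1, 0, 1, 0]))
    assert ev.ap == pytest.approx((1 + 2 / 3) / 2)


def test_perfect_and_reversed_rankings():
    perfect = pr_curve_and_ap(_ranking([1, 1, 0, 0]))
    assert perfect.ap == 1.0 and perfect.auroc == 1.0
    reversed_ = pr_curve_and_ap(_ranking([0, 0, 1, 1]))
    assert reversed_.auroc == 0.0


def test_recall_is_nondecreasing_and_single_class_rejected():
    ev = pr_curve_and_ap(_ranking([1, 0, 0, 1, 0, 1]))
    assert np.all(np.diff(ev.recall) >= 0)
    with pytest.raises(ValueError):
        pr_curve_and_ap(_ranking([1, 1]))


def _brute_force_ap(scores, labels):
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    precisions = [
        labels[: i + 1].mean() for i, l in enumerate(labels) if l == 1
    ]
    return float(np.mean(precisions))


def _brute_force_auroc(scores, labels):
    wins = total = 0
    for i, (si, li) in enumerate(zip(scores, labels)):
        for sj, lj in zip(scores, labels):
            if li == 1 and lj == 0:
                total += 1
                if si > sj:
                    wins += 1
                elif si == sj:
                    wins += 0.5
    return wins / total


def test_ap_and_auroc_match_brute_force_oracles_on_random_rankings():
    """200 random rankings of length <= 50, distinct scores: exact agreement."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    rng = np.random.default_rng(0)
    for rep in range(200):
        n = int(rng.integers(4, 51))
        labels = rng.random(n) < rng.uniform(0.2, 0.8)
        if labels.all() or not labels.any():
            labels[0], labels[1] = True, False
        scores = rng.permutation(n).astype(float)  # distinct
        entries = [
            _sg(f"g{i}", float(s), int(l)) for i, (s, l) in enumerate(zip(scores, labels))
        ]
        ev = pr_curve_and_ap(entries)
        assert ev.ap == pytest.approx(_brute_force_ap(scores, labels), abs=1e-12)
        assert ev.auroc == pytest.approx(_brute_force_auroc(scores, labels), abs=1e-12)
        if rep < 25:  # independent library cross-check on a subset
            assert ev.ap == pytest.approx(average_precision_score(labels, scores), abs=1e-12)
            assert ev.auroc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_auroc_handles_ties_as_half_wins():
    entries = [_sg("a", 1.0, 1), _sg("b", 1.0, 0), _sg("c", 0.0, 0)]
    ev = pr_curve_and_ap(entries)
    assert ev.auroc == pytest.approx(_brute_force_auroc([1.0, 1.0, 0.0], [1, 0, 0]))


@pytest.mark.parametrize(
    "labels, k, expected",
    [([1, 1, 0], 2, 1.0), ([1, 0, 0], 3, 1 / 3), ([1, 0], 1, 1.0)],
)
def test_top_k_precision(labels, k, expected):
    assert top_k_precision(_ranking(labels), k) == pytest.approx(expected)


def test_top_k_beyond_length_warns_and_uses_full_list(caplog):
    with caplog.at_level("WARNING"):
        assert top_k_precision(_ranking([1, 0]), 10) == 0.5
    assert "exceeds" in caplog.text


# ---------------------------------------------------------------------------
# baselines


def test_cosine_nn_signed_scores():
    ref = {"d": np.array([1.0, 0.0]), "c": np.array([0.0, 1.0])}
    labels = {"d": 1, "c": 0}
    scores = cosine_nn_baseline(
        {"q_def": np.array([1.0, 0.0]), "q_ctrl": np.array([0.0, 2.0])}, ref, labels
    )
    assert scores["q_def"] == pytest.approx(1.0)
    assert scores["q_ctrl"] == pytest.approx(-1.0)


def test_cosine_nn_zero_vector_scores_zero():
    ref = {"d": np.array([1.0, 0.0]), "c": np.array([0.0, 1.0])}
    with pytest.warns(UserWarning, match="zero-vector"):
        scores = cosine_nn_baseline({"q": np.zeros(2)}, ref, {"d": 1, "c": 0})
    assert scores["q"] == 0.0


def test_cosine_tie_prefers_defense_neighbor():
    ref = {"a_ctrl": np.array([1.0, 0.0]), "b_def": np.array([2.0, 0.0])}
    scores = cosine_nn_baseline({"q": np.array([3.0, 0.0])}, ref, {"a_ctrl": 0, "b_def": 1})
    assert scores["q"] == pytest.approx(1.0)


def test_signed_best_hit_rules():
    hits = pd.DataFrame(
        {"query": ["q1", "q2", "q2"], "target": ["d", "c", "d"], "score": [100.0, 80.0, 40.0]}
    )
    labels = {"d": 1, "c": 0}
    scores = signed_best_hit_baseline(hits, labels, ["q1", "q2", "q3"])
    assert scores == {"q1": 100.0, "q2": -80.0, "q3": 0.0}


def test_signed_best_hit_tie_prefers_defense():
    hits = pd.DataFrame({"query": ["q", "q"], "target": ["c", "d"], "score": [50.0, 50.0]})
    assert signed_best_hit_baseline(hits, {"d": 1, "c": 0}, ["q"])["q"] == 50.0


# ---------------------------------------------------------------------------
# Fisher / guilt by association


def _hypergeom_tail(a, b, c, d):
    N, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) for x in range(a, min(n, K) + 1)
    ) / denom


def test_fisher_p_matches_printed_example():
    assert fisher_enrichment_p(8, 2, 2, 8) == pytest.approx(2126 / 184756, rel=1e-9)


def test_fisher_matches_hypergeometric_tail_for_all_small_tables():
    """Exhaustive check against the tail-sum oracle, margins <= 30."""
    for n1 in range(0, 16):
        for a in range(n1 + 1):
            b = n1 - a
            for n2 in range(0, 16):
                for c in range(0, n2 + 1, max(1, n2 // 3)):
                    d = n2 - c
                    if n1 == 0 and n2 == 0:
                        continue
                    assert fisher_enrichment_p(a, b, c, d) == pytest.approx(
                        _hypergeom_tail(a, b, c, d), rel=1e-9, abs=1e-12
                    ), (a, b, c, d)


def _gba_genome():
    # contig layout: d0 (defense) at rank 0, then controls
    genes = [make_gene(f"g{i}", "c1", i * 100, i * 100 + 60) for i in range(25)]
    return make_genome(genes)


def test_guilt_by_association_window_and_ranking():
    genome = _gba_genome()
    defense = {"g0": 1}
    clusters = {f"g{i}": ("near" if 1 <= i <= 10 else "far") for i in range(1, 25)}
    results = guilt_by_association([genome], clusters, defense, window=10)
    by_id = {r.cluster_id: r for r in results}
    assert by_id["near"].a == 10 and by_id["near"].b == 0
    assert by_id["far"].a == 0
    assert results[0].cluster_id == "near"
    assert by_id["far"].p_value == pytest.approx(1.0)


def test_guilt_by_association_same_system_neighbors_ignored():
    genome = _gba_genome()
    defense = {"g0": 1}
    system_map = {"g0": "sysA", "g1": "sysA"}
    clusters = {"g1": "cl1"}
    (res,) = guilt_by_association(
        [genome], clusters, defense, system_map=system_map, window=10
    )
    assert res.a == 0  # its only defensive neighbor is same-system


def test_guilt_by_association_same_fold_neighbors_ignored():
    genome = _gba_genome()
    defense = {"g0": 1}
    clusters = {"g1": "cl1", "g2": "cl2"}
    fold_map = {"g0": 1, "g1": 1, "g2": 2}
    results = guilt_by_association(
        [genome], clusters, defense, fold_map=fold_map, window=10
    )
    by_id = {r.cluster_id: r for r in results}
    assert by_id["cl1"].a == 0  # same fold as its defensive neighbor
    assert by_id["cl2"].a == 1


def test_guilt_by_association_rejects_bad_window():
    with pytest.raises(ValueError):
        guilt_by_association([_gba_genome()], {}, {}, window=0)


# ---------------------------------------------------------------------------
# system-level summary


def test_prospective_system_summary_rules():
    preds = {
        "a": PredictionRecord.from_probability("a", 0.99),
        "b": PredictionRecord.from_probability("b", 0.768),  # log-odds ~ 1.2
        "c": PredictionRecord.from_probability("c", 0.3),
    }
    instances = pd.DataFrame(
        {
            "instance_id": ["i1", "i1", "i2", "i2"],
            "system_id": ["S", "S", "T", "T"],
            "gene_id": ["a", "b", "b", "c"],
        }
    )
    summary = prospective_system_summary(preds, instances)
    assert summary.instance_complete == {"i1": True, "i2": False}
    assert summary.instance_max_log_odds["i1"] == pytest.approx(preds["a"].log_odds)
    assert summary.system_max_probability["S"] == pytest.approx(0.99)
    assert summary.n_systems_above_p50 == 2
    assert summary.n_systems_above_p98 == 1


def test_prospective_summary_requires_all_predictions():
    instances = pd.DataFrame(
        {"instance_id": ["i"], "system_id": ["S"], "gene_id": ["missing"]}
    )
    with pytest.raises(KeyError):
        prospective_system_summary({}, instances)
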
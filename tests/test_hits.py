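"""Filter cascade, consensus classification, and clustering."""

import numpy as np
import pandas as pd
import pytest

from ctlscreen.differential import DifferentialTable
from ctlscreen.hits import (
    HitSelectionError,
    Thresholds,
    apply_filters,
    consensus_hits,
    heatmap_matrix,
    hierarchical_cluster,
    survivors,
)
from ctlscreen.normalize import ScoreTable


def _toy_tables(rows):
    """rows: gene -> (via, tox, ctg, d) applied identically to all screens."""
    genes = pd.Index(sorted(rows), name="gene_id")
    screens = ["s1", "s2", "s3"]
    scores = pd.DataFrame(index=genes)
    for s in screens:
        scores[(s, "without_ctl")] = [rows[g][0] for g in genes]
        scores[(s, "with_ctl")] = [rows[g][1] for g in genes]
    scores.columns = pd.MultiIndex.from_tuples(scores.columns)
    ctg = pd.Series([rows[g][2] for g in genes], index=genes)
    d = pd.DataFrame({s: [rows[g][3] for g in genes] for s in screens}, index=genes)
    table = ScoreTable(scores=scores, replicate_scores=scores, control_scores=pd.DataFrame())
    return table, DifferentialTable(d=d), ctg


def test_filter_rules_hand_applied():
    # A passes all filters; B fails the effect requirement; C is CTG-excluded
    table, diff, ctg = _toy_tables(
        {"A": (0.1, 1.2, 0.3, 1.0), "B": (0.1, 0.2, 0.3, 1.0), "C": (0.1, 1.2, 1.8, 1.0)}
    )
    ht = apply_filters(table, diff, ctg)
    assert survivors(ht).to_dict() == {"A": True, "B": False, "C": False}
    assert not ht["viability_excluded"].any()
    assert ht.loc["C", "ctg_excluded"]


def test_viability_exclusion_any_screen():
    table, diff, ctg = _toy_tables({"A": (3.0, 1.2, 0.3, 1.0), "B": (0.0, 1.2, 0.3, 1.0)})
    ht = apply_filters(table, diff, ctg)
    assert ht.loc["A", "viability_excluded"]
    assert not ht.loc["B", "viability_excluded"]


def test_thresholds_are_strict_inequalities():
    table, diff, ctg = _toy_tables({"A": (2.0, 0.5, 1.5, 1.0)})
    ht = apply_filters(table, diff, ctg)
    assert not ht.loc["A", "viability_excluded"]  # exactly 2.0 stays
    assert not ht.loc["A", "effect_pass"]         # exactly 0.5 does not pass
    assert not ht.loc["A", "ctg_excluded"]        # exactly 1.5 stays


def test_clause_polarity_switchable():
    table, diff, ctg = _toy_tables({"A": (3.0, 1.2, 0.3, 1.0), "B": (0.0, 0.2, 0.3, 1.0)})
    thr = Thresholds(viability_excludes=False, effect_requires=False)
    ht = apply_filters(table, diff, ctg, thr)
    assert not ht.loc["A", "viability_excluded"]
    assert ht.loc["B", "effect_pass"]


def test_universe_mismatch_reported():
    table, diff, ctg = _toy_tables({"A": (0, 1, 0, 1.0), "B": (0, 1, 0, 1.0)})
    with pytest.raises(HitSelectionError, match="B"):
        apply_filters(table, diff, ctg.drop("B"))


def test_filter_order_independence():
    """Flags are independent predicates: survivor set is one conjunction."""
    rng = np.random.default_rng(5)
    rows = {
        f"G{i}": tuple(rng.normal(0, 1.5, 3)) + (rng.normal(),) for i in range(60)
    }
    table, diff, ctg = _toy_tables(rows)
    ht = apply_filters(table, diff, ctg)
    conj = ~ht["viability_excluded"] & ht["effect_pass"] & ~ht["ctg_excluded"]
    conj2 = ~ht["ctg_excluded"] & ~ht["viability_excluded"] & ht["effect_pass"]
    assert (survivors(ht) == conj).all() and (conj == conj2).all()


def test_consensus_classification_rules():
    table, diff, ctg = _toy_tables({"A": (0.1, 1.2, 0.3, 0.0)})
    ht = apply_filters(table, diff, ctg)
    d = pd.DataFrame(
        {"s1": [1.2, 1.2, 0.3, -1.0], "s2": [0.9, -0.9, 0.9, -0.7],
         "s3": [1.5, 1.5, 1.5, -2.0]},
        index=pd.Index(["A", "B", "C", "D"], name="gene_id"),
    )
    ht4 = pd.concat([ht] * 4).set_index(d.index)
    out = consensus_hits(ht4, DifferentialTable(d=d))
    assert out.loc["A", "hit_class"] == "suppressor_candidate"  # (+1.2,+0.9,+1.5)
    assert out.loc["B", "hit_class"] == "none"                  # sign disagreement
    assert out.loc["C", "hit_class"] == "none"                  # min |d| < 0.5
    assert out.loc["D", "hit_class"] == "activator_candidate"


def test_excluded_genes_never_classified():
    table, diff, ctg = _toy_tables({"A": (3.0, 1.2, 0.3, 2.0), "B": (0.1, 1.2, 1.8, 2.0)})
    ht = consensus_hits(apply_filters(table, diff, ctg), diff)
    assert (ht["hit_class"] == "none").all()
    assert ht["consensus"].all()  # consensus flag reflects d alone


def test_cluster_identical_rows_merge_at_zero():
    d = pd.DataFrame([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]],
                     index=["A", "B", "C"], columns=["s1", "s2"])
    res = hierarchical_cluster(d, n_clusters=2)
    assert res.linkage[0, 2] == 0.0
    assert res.labels["A"] == res.labels["B"] != res.labels["C"]


def test_cluster_two_group_recovery():
    rng = np.random.default_rng(8)
    pos = rng.normal(1.0, 0.05, (5, 3))
    neg = rng.normal(-1.0, 0.05, (5, 3))
    d = pd.DataFrame(np.vstack([pos, neg]),
                     index=[f"G{i}" for i in range(10)],
                     columns=["s1", "s2", "s3"])
    res = hierarchical_cluster(d, n_clusters=2)
    first = set(res.labels[[f"G{i}" for i in range(5)]])
    second = set(res.labels[[f"G{i}" for i in range(5, 10)]])
    assert len(first) == 1 and len(second) == 1 and first != second
    # brute-force check: every within-group distance < every between-group one
    X = d.to_numpy()
    within = [np.linalg.norm(X[i] - X[j]) for i in range(5) for j in range(i + 1, 5)]
    between = [np.linalg.norm(X[i] - X[j]) for i in range(5) for j in range(5, 10)]
    assert max(within) < min(between)


def test_cluster_single_gene():
    d = pd.DataFrame([[0.5, 0.5]], index=["A"], columns=["s1", "s2"])
    res = hierarchical_cluster(d)
    assert res.labels.tolist() == [1]
    assert res.linkage.shape == (0, 4)
    assert res.leaf_order == ["A"]


def test_cluster_row_order_invariance():
    rng = np.random.default_rng(9)
    d = pd.DataFrame(rng.standard_normal((30, 3)),
                     index=[f"G{i:02d}" for i in range(30)],
                     columns=["s1", "s2", "s3"])
    res1 = hierarchical_cluster(d, n_clusters=4)
    res2 = hierarchical_cluster(d.sample(frac=1, random_state=1), n_clusters=4)
    assert res1.leaf_order == res2.leaf_order
    pd.testing.assert_series_equal(res1.labels, res2.labels)


def test_heatmap_matrix_in_leaf_order():
    d = pd.DataFrame([[1.0, 1.0], [5.0, 5.0], [1.1, 1.1]],
                     index=pd.Index(["A", "B", "C"], name="gene_id"),
                     columns=["s1", "s2"])
    res = hierarchical_cluster(d, n_clusters=2)
    hm = heatmap_matrix(DifferentialTable(d=d), res)
    assert list(hm.index) == res.leaf_order
    assert "cluster_id" in hm.columns


def test_planted_suppressors_classified_end_to_end(default_run):
    """PD-L1-like planted suppressors come out as suppressor candidates."""
    truth = default_run.truth
    ht = default_run.hit_table
    sup = truth.genes_of_class("suppressor")
    assert (ht.loc[sup, "hit_class"] == "suppressor_candidate").sum() >= 8
    act = truth.genes_of_class("activator")
    assert (ht.loc[act, "hit_class"] == "activator_candidate").sum() >= 8
    lethal = truth.genes_of_class("lethal")
    assert ht.loc[lethal, "viability_excluded"].all()
    assert (ht.loc[lethal, "hit_class"] == "none").all()
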
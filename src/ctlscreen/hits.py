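"""Hit selection: the published filter cascade, consensus across screens,
and hierarchical clustering of differential scores.

Three independent per-gene predicates are computed from the score tables
(strict inequalities throughout, so a score exactly at a threshold never
trips a rule):

* ``viability_excluded`` — |without-CTL score| > 2 in *any* screen: the
  knockdown moves viability on its own, so any CTL-condition signal is
  confounded.
* ``effect_pass`` — |with-CTL score| > 0.5 in *every* screen: there is a
  reproducible effect under CTL pressure at all.
* ``ctg_excluded`` — |ATP-readout viability score| > 1.5: the orthogonal
  viability screen flags the gene as generally affecting cell viability.

A surviving gene becomes a classified *consensus* hit when its differential
score has the same sign in all screens and a magnitude of at least
``min_abs_d`` in each: consistently positive d -> ``suppressor_candidate``
(knockdown enhances CTL-mediated killing, PD-L1-like), consistently negative
d -> ``activator_candidate`` (knockdown dampens killing). Because the flags
are independent predicates, the survivor set does not depend on the order in
which the filters are applied.

Clustering of the gene x screen differential matrix (agglomerative,
Euclidean / complete linkage by default) is used for the heatmap view of
cross-screen consistency; rows are pre-sorted lexicographically by gene so
the merge order is deterministic and invariant to input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .differential import DifferentialTable
from .normalize import ScoreTable

logger = logging.getLogger(__name__)

HIT_CLASSES = ("suppressor_candidate", "activator_candidate", "none")


class HitSelectionError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    """Filter cutoffs (absolute values, strict inequalities).

    ``viability_excludes``/``effect_requires`` switch the polarity of the two
    luciferase-score clauses; the defaults exclude on intrinsic-viability
    scores and require a with-CTL effect.
    """

    viability: float = 2.0
    effect: float = 0.5
    ctg: float = 1.5
    viability_excludes: bool = True
    effect_requires: bool = True

    def validate(self) -> "Thresholds":
        if min(self.viability, self.effect, self.ctg) <= 0:
            raise HitSelectionError("thresholds must be positive")
        return self


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series          # gene_id -> cluster_id (1-based)
    leaf_order: list[str]      # gene ids in dendrogram leaf order


def _check_universe(name_a: str, a, name_b: str, b) -> None:
    sa, sb = set(a), set(b)
    if sa != sb:
        diff = sorted(sa ^ sb)
        raise HitSelectionError(
            f"gene universes of {name_a} and {name_b} differ: {diff[:10]}"
            + ("..." if len(diff) > 10 else "")
        )


def apply_filters(
    score_table: ScoreTable,
    differential_table: DifferentialTable,
    ctg_scores: pd.Series,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Compute the per-gene filter flags and assemble the hit table.

    Returns one row per library gene with per-screen condition scores,
    differential scores, the ATP-readout score, and the three boolean flags.
    """
    thr = (thresholds or Thresholds()).validate()
    screens = differential_table.screens
    scores = score_table.scores
    genes = scores.index
    _check_universe("scores", genes, "differential", differential_table.d.index)
    _check_universe("scores", genes, "ctg", ctg_scores.index)

    via = pd.DataFrame({s: scores[(s, "without_ctl")] for s in screens})
    tox = pd.DataFrame({s: scores[(s, "with_ctl")] for s in screens})
    ctg = ctg_scores.reindex(genes)

    via_extreme = (via.abs() > thr.viability).any(axis=1)
    tox_all = (tox.abs() > thr.effect).all(axis=1)
    out = pd.DataFrame(index=genes)
    for s in screens:
        out[f"score_{s}_without_ctl"] = via[s]
        out[f"score_{s}_with_ctl"] = tox[s]
    out["ctg_score"] = ctg
    for s in screens:
        out[f"d_{s}"] = differential_table.d[s]
    out["viability_excluded"] = via_extreme if thr.viability_excludes else ~via_extreme
    out["effect_pass"] = tox_all if thr.effect_requires else ~tox_all
    out["ctg_excluded"] = ctg.abs() > thr.ctg
    out.index.name = "gene_id"
    return out


def survivors(hit_table: pd.DataFrame) -> pd.Series:
    """Genes passing the whole cascade (order-independent conjunction)."""
    return (
        ~hit_table["viability_excluded"]
        & hit_table["effect_pass"]
        & ~hit_table["ctg_excluded"]
    )


def consensus_hits(
    hit_table: pd.DataFrame,
    differential_table: DifferentialTable,
    min_abs_d: float = 0.5,
) -> pd.DataFrame:
    """Classify filter survivors with cross-screen consensus.

    consensus <=> sign(d) identical in all screens and min |d| >= min_abs_d.
    Classified genes are consensus survivors; excluded genes are never
    classified.
    """
    d = differential_table.d.reindex(hit_table.index)
    finite = d.notna().all(axis=1)
    all_pos = finite & (d > 0).all(axis=1) & (d.abs().min(axis=1) >= min_abs_d)
    all_neg = finite & (d < 0).all(axis=1) & (d.abs().min(axis=1) >= min_abs_d)

    out = hit_table.copy()
    out["consensus"] = all_pos | all_neg
    ok = survivors(out) & out["consensus"]
    out["hit_class"] = "none"
    out.loc[ok & all_pos, "hit_class"] = "suppressor_candidate"
    out.loc[ok & all_neg, "hit_class"] = "activator_candidate"
    logger.info(
        "hit selection: %d genes, %d survive filters, %d consensus, %d classified",
        len(out),
        int(survivors(out).sum()),
        int(out["consensus"].sum()),
        int((out["hit_class"] != "none").sum()),
    )
    return out


def hierarchical_cluster(
    differential_matrix: pd.DataFrame,
    *,
    metric: str = "euclidean",
    method: str = "complete",
    n_clusters: int | None = None,
    height: float | None = None,
) -> ClusterResult:
    """Agglomerative clustering of gene rows of the differential matrix.

    Rows with missing values are dropped with a warning. The flat cut uses
    ``n_clusters`` (maxclust) if given, else ``height`` (distance), else a
    single cluster. A single gene yields the trivial one-cluster result.
    """
    dm = differential_matrix.dropna(axis=0)
    if len(dm) < len(differential_matrix):
        logger.warning(
            "dropping %d genes with missing differential scores before clustering",
            len(differential_matrix) - len(dm),
        )
    if len(dm) == 0:
        raise HitSelectionError("no complete rows to cluster")
    dm = dm.sort_index(kind="mergesort")  # deterministic, row-order invariant
    genes = list(dm.index)
    if len(dm) == 1:
        return ClusterResult(
            linkage=np.empty((0, 4)),
            labels=pd.Series([1], index=dm.index, name="cluster_id"),
            leaf_order=genes,
        )
    dist = pdist(dm.to_numpy(), metric=metric)
    link = hierarchy.linkage(dist, method=method)
    if n_clusters is not None:
        flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    elif height is not None:
        flat = hierarchy.fcluster(link, t=height, criterion="distance")
    else:
        flat = np.ones(len(dm), dtype=int)
    leaves = hierarchy.leaves_list(link)
    return ClusterResult(
        linkage=link,
        labels=pd.Series(flat, index=dm.index, name="cluster_id"),
        leaf_order=[genes[i] for i in leaves],
    )


def heatmap_matrix(
    differential_table: DifferentialTable, cluster: ClusterResult
) -> pd.DataFrame:
    """Differential matrix in dendrogram leaf order plus cluster ids."""
    out = differential_table.d.loc[cluster.leaf_order].copy()
    out["cluster_id"] = cluster.labels.reindex(out.index)
    out.index.name = "gene_id"
    return out
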
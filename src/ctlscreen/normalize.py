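"""Per-plate robust scoring of raw intensities and replicate-level QC.

Each plate is scored independently on the log2 scale with a robust z-score
over its *sample* wells:

    score_w = (median - log2 I_w) / (1.4826 * MAD)

where median and MAD (median absolute deviation) are taken over the plate's
sample wells only; control wells receive scores on the same sample-derived
scale but never influence it. The sign is flipped relative to a plain
z-score so that *low* intensity (fewer surviving tumour cells) maps to a
*positive* score: positive score = reduced cancer-cell viability. The factor
1.4826 makes the MAD a consistent estimate of a normal standard deviation, so
scores are comparable across plates with different spreads.

Because the score depends on intensities only through log2 ratios to the
plate median, it is invariant under any positive rescaling of the plate
(plate-reader gain, reagent batch), which is what licenses comparing scores
across plates, replicates and screens.

Replicate scores are summarized per gene (arithmetic mean by default) into a
gene x (screen, condition) score table; replicate agreement is reported as
both Pearson and Spearman correlation over genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ScreenDataset, flatten_score_columns, write_table

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826
MIN_SAMPLE_WELLS = 8


class DegeneratePlateError(ValueError):
    """A plate whose sample wells have no spread (MAD = 0) cannot be scored."""


class ScoreError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Normalized robust scores at gene resolution.

    ``scores``: genes x (screen_id, condition), replicate-summarized.
    ``replicate_scores``: genes x (screen_id, condition, replicate), kept for
    QC. ``control_scores``: long-format per-well scores of control wells on
    the sample-derived scale.
    """

    scores: pd.DataFrame
    replicate_scores: pd.DataFrame
    control_scores: pd.DataFrame

    @property
    def screens(self) -> list[str]:
        return sorted({s for s, _ in self.scores.columns})

    def condition_vector(self, screen: str, condition: str) -> pd.Series:
        return self.scores[(screen, condition)]

    def write(self, path) -> None:
        write_table(flatten_score_columns(self.scores).rename_axis("gene_id"), path)


def plate_scores(
    intensities: np.ndarray,
    sample_mask: np.ndarray,
    *,
    plate_name: str = "?",
) -> np.ndarray:
    """Robust scores for every well of one plate.

    ``intensities`` are raw (linear-scale) readings; ``sample_mask`` flags
    the library wells that define the plate's location and scale. Requires at
    least 8 sample wells with finite positive intensity and nonzero spread.
    """
    intensities = np.asarray(intensities, dtype=float)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    if intensities.shape != sample_mask.shape:
        raise ScoreError("intensities and sample_mask must have the same shape")

    with np.errstate(divide="ignore"):
        x = np.log2(intensities)
    x[~np.isfinite(x)] = np.nan

    xs = x[sample_mask]
    xs = xs[np.isfinite(xs)]
    if xs.size < MIN_SAMPLE_WELLS:
        raise ScoreError(
            f"plate {plate_name}: only {xs.size} usable sample wells "
            f"(need >= {MIN_SAMPLE_WELLS})"
        )
    med = np.median(xs)
    mad = np.median(np.abs(xs - med))
    if mad == 0:
        raise DegeneratePlateError(
            f"plate {plate_name}: zero MAD over sample wells (no spread)"
        )
    return (med - x) / (MAD_SCALE * mad)


def score_dataset(
    dataset: ScreenDataset, *, summarize: str = "mean"
) -> ScoreTable:
    """Score every plate of a dataset and summarize replicates per gene."""
    w = dataset.wells
    gene_rows: list[pd.DataFrame] = []
    ctrl_rows: list[pd.DataFrame] = []
    for (screen, cond, rep, plate), grp in w.groupby(
        ["screen_id", "condition", "replicate", "plate_id"], sort=True
    ):
        mask = (grp["content"] == "sample").to_numpy()
        sc = plate_scores(
            grp["intensity"].to_numpy(),
            mask,
            plate_name=f"{screen}/{cond}/r{rep}/{plate}",
        )
        gene_rows.append(
            pd.DataFrame(
                {
                    "gene_id": grp.loc[mask, "gene_id"].to_numpy(),
                    "screen_id": screen,
                    "condition": cond,
                    "replicate": rep,
                    "score": sc[mask],
                }
            )
        )
        ctrl_mask = grp["content"].str.startswith("control_").to_numpy()
        ctrl_rows.append(
            pd.DataFrame(
                {
                    "screen_id": screen,
                    "condition": cond,
                    "replicate": rep,
                    "plate_id": plate,
                    "well": grp.loc[ctrl_mask, "well"].to_numpy(),
                    "content": grp.loc[ctrl_mask, "content"].to_numpy(),
                    "score": sc[ctrl_mask],
                }
            )
        )

    long = pd.concat(gene_rows, ignore_index=True)
    replicate_scores = long.pivot_table(
        index="gene_id",
        columns=["screen_id", "condition", "replicate"],
        values="score",
        aggfunc="mean",
    )
    replicate_scores = replicate_scores.reindex(list(dataset.library.genes))
    replicate_scores.index.name = "gene_id"

    scores = summarize_replicates(replicate_scores, method=summarize)
    control_scores = pd.concat(ctrl_rows, ignore_index=True)
    return ScoreTable(
        scores=scores, replicate_scores=replicate_scores, control_scores=control_scores
    )


def summarize_replicates(
    replicate_scores: pd.DataFrame, *, method: str = "mean"
) -> pd.DataFrame:
    """Collapse the replicate level of a gene x (screen, condition, replicate)
    frame by arithmetic mean (default) or median.

    Genes missing in every replicate of a condition stay missing; a warning
    is logged naming them.
    """
    if method not in ("mean", "median"):
        raise ScoreError(f"unknown replicate summary {method!r}")
    out = replicate_scores.T.groupby(level=[0, 1]).agg(method).T
    missing = out.index[out.isna().any(axis=1)]
    if len(missing):
        logger.warning(
            "%d genes missing in all replicates of some condition: %s",
            len(missing),
            list(missing[:10]),
        )
    return out


def replicate_correlation(
    score_table: ScoreTable, screen: str, condition: str
) -> tuple[float, float]:
    """(Pearson, Spearman) correlation of the two replicate score vectors.

    Pearson (product-moment) is the primary coefficient; Spearman is reported
    alongside because rank-based agreement is the common robust alternative
    for screen replicates. Requires exactly two replicates and nonzero
    variance in both vectors.
    """
    reps = score_table.replicate_scores[(screen, condition)]
    if reps.shape[1] != 2:
        raise ScoreError(
            f"{screen}/{condition}: need exactly 2 replicates, have {reps.shape[1]}"
        )
    a, b = reps.iloc[:, 0], reps.iloc[:, 1]
    keep = a.notna() & b.notna()
    a, b = a[keep].to_numpy(), b[keep].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ScoreError(f"{screen}/{condition}: zero variance, correlation undefined")
    if np.allclose(a, b, rtol=1e-9, atol=1e-12):
        # agreement is exact; scipy's estimate would only add rounding noise
        return 1.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pear = stats.pearsonr(a, b).statistic
        spear = stats.spearmanr(a, b).statistic
    return float(pear), float(spear)


def qc_report(score_table: ScoreTable) -> pd.DataFrame:
    """Per-(screen, condition) replicate-agreement table."""
    rows = []
    for screen, cond in sorted(
        {(s, c) for s, c, _ in score_table.replicate_scores.columns}
    ):
        n_rep = score_table.replicate_scores[(screen, cond)].shape[1]
        if n_rep == 2:
            pear, spear = replicate_correlation(score_table, screen, cond)
        else:  # pragma: no cover - non-default replicate counts
            pear = spear = np.nan
        rows.append((screen, cond, n_rep, pear, spear))
    return pd.DataFrame(
        rows, columns=["screen_id", "condition", "n_replicates", "pearson", "spearman"]
    )
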
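"""Differential scores: CTL-dependent killing beyond intrinsic viability.

A gene that merely kills (or protects) tumour cells moves both condition
scores together; a genuine immune modulator moves the with-CTL (toxicity)
score away from what its without-CTL (viability) score predicts. The
differential score isolates that excess in two steps:

1. the toxicity and viability score vectors of one screen are **quantile
   normalized against each other** — each vector is mapped onto the mean of
   the two sorted vectors by rank, so both share one distribution and a
   difference of zero is the global null;
2. toxicity is regressed on viability with **loess** (locally weighted
   polynomial regression, tricube weights) and each gene's differential
   score is its residual:

       d_g = tox'_g - loess(via' -> tox')(via'_g)

Positive d means knockdown of the gene enhances CTL-mediated killing beyond
any viability effect — the signature of an immune suppressor on the tumour
cell. A plain ``simple_difference`` mode (d = tox - via) is provided as the
first-order version of the same contrast.

The loess here is the classic local regression: at each point the
``ceil(span * n)`` nearest neighbours (ties at the boundary all included)
are fit with a weighted polynomial, tricube weights
``w = (1 - (dist/d_max)^3)^3``, and the fit is evaluated at the point. The
defaults (span 2/3, degree 1, no robustness iterations) follow the classic
lowess formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .normalize import ScoreTable

DEFAULT_SPAN = 2.0 / 3.0
DEFAULT_DEGREE = 1

METHODS = ("loess_residual", "simple_difference")


class DifferentialError(ValueError):
    pass


@dataclass
class DifferentialTable:
    """Gene x screen differential scores with the method that produced them."""

    d: pd.DataFrame  # index gene_id, one column per screen
    method: str = "loess_residual"
    span: float = DEFAULT_SPAN
    degree: int = DEFAULT_DEGREE

    @property
    def screens(self) -> list[str]:
        return list(self.d.columns)


def quantile_normalize_pair(
    x: np.ndarray | pd.Series, y: np.ndarray | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile normalize two equal-length vectors against each other.

    The common target distribution is the elementwise mean of the two sorted
    vectors; each value is replaced by the target at its rank. Ties within a
    vector receive the mean of their tied ranks' targets (so for tie-free
    input the sorted outputs of both vectors are identical).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DifferentialError("x and y must be 1-d vectors of equal length")
    if x.size < 2:
        raise DifferentialError("need at least 2 values to quantile normalize")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DifferentialError("inputs must be finite")

    target = (np.sort(x) + np.sort(y)) / 2.0

    def _map(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="mergesort")
        out = np.empty_like(target)
        out[order] = target
        # average targets over tie groups
        sv = v[order]
        ties = np.flatnonzero(sv[1:] == sv[:-1])
        if ties.size:
            grp = np.zeros(v.size, dtype=int)
            grp[1:] = np.cumsum(sv[1:] != sv[:-1])
            sums = np.bincount(grp, weights=target)
            cnts = np.bincount(grp)
            out[order] = (sums / cnts)[grp]
        return out

    return _map(x), _map(y)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
) -> np.ndarray:
    """Fitted loess values at every observed x.

    At each x_i, the ``k = ceil(span * n)`` nearest points by |x_j - x_i|
    (all boundary ties included) are fit with a polynomial of the given
    degree under tricube weights; the fitted value is the polynomial at x_i.
    Deterministic; no robustness iterations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.shape != x.shape or x.ndim != 1:
        raise DifferentialError("x and y must be 1-d vectors of equal length")
    if not 0 < span <= 1:
        raise DifferentialError(f"span must lie in (0, 1], got {span}")
    if degree < 0:
        raise DifferentialError("degree must be >= 0")
    if n < max(4, degree + 2):
        raise DifferentialError(f"need at least {max(4, degree + 2)} points")
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise DifferentialError(
            f"span {span} gives {k} neighbours, too few for degree {degree}"
        )

    fitted = np.empty(n)
    for i in range(n):
        dist = np.abs(x - x[i])
        d_max = np.partition(dist, k - 1)[k - 1]
        if d_max == 0.0:
            # all neighbours coincide with x_i: flat weighted mean
            sel = dist == 0.0
            fitted[i] = y[sel].mean()
            continue
        sel = dist <= d_max
        u = x[sel] - x[i]
        w = (1.0 - (np.abs(u) / d_max) ** 3) ** 3
        sw = np.sqrt(w)
        basis = np.vander(u, N=degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(basis * sw[:, None], y[sel] * sw, rcond=None)
        fitted[i] = coef[0]
    return fitted


def differential_scores(
    score_table: ScoreTable,
    screens: Iterable[str] | None = None,
    *,
    method: str = "loess_residual",
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
) -> DifferentialTable:
    """Per-screen differential scores from a replicate-summarized score table.

    Screens default to every screen carrying both a with-CTL and a
    without-CTL condition. Genes missing either condition get a missing
    differential score.
    """
    if method not in METHODS:
        raise DifferentialError(f"unknown method {method!r}; expected one of {METHODS}")
    scores = score_table.scores
    if screens is None:
        screens = [
            s
            for s in score_table.screens
            if (s, "with_ctl") in scores.columns and (s, "without_ctl") in scores.columns
        ]
    screens = list(screens)
    if not screens:
        raise DifferentialError("no screen has both conditions scored")

    cols = {}
    for s in screens:
        for cond in ("with_ctl", "without_ctl"):
            if (s, cond) not in scores.columns:
                raise DifferentialError(f"screen {s!r} lacks condition {cond!r}")
        tox = scores[(s, "with_ctl")]
        via = scores[(s, "without_ctl")]
        keep = tox.notna() & via.notna()
        t, v = tox[keep].to_numpy(), via[keep].to_numpy()
        if method == "simple_difference":
            d = t - v
        else:
            t_qn, v_qn = quantile_normalize_pair(t, v)
            d = t_qn - loess_fit(v_qn, t_qn, span=span, degree=degree)
        col = pd.Series(np.nan, index=scores.index)
        col[keep] = d
        cols[s] = col
    table = pd.DataFrame(cols)
    table.index.name = "gene_id"
    return DifferentialTable(d=table, method=method, span=span, degree=degree)
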
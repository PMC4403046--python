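"""Quantile normalization, loess, and the differential score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctlscreen.differential import (
    DifferentialError,
    differential_scores,
    loess_fit,
    quantile_normalize_pair,
)
from .conftest import brute_force_loess


# ---------------------------------------------------------------------------
# quantile normalization

def test_qn_identity():
    x = np.array([3.0, 1.0, 2.0])
    xq, yq = quantile_normalize_pair(x, x.copy())
    np.testing.assert_array_equal(xq, x)
    np.testing.assert_array_equal(yq, x)


def test_qn_hand_example():
    xq, yq = quantile_normalize_pair([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
    np.testing.assert_array_equal(xq, [2.0, 3.0, 4.0])
    np.testing.assert_array_equal(yq, [2.0, 3.0, 4.0])


def test_qn_respects_ranks():
    x = np.array([10.0, -1.0, 5.0, 2.0])
    y = np.array([0.0, 1.0, 2.0, 3.0])
    xq, yq = quantile_normalize_pair(x, y)
    assert np.argsort(xq).tolist() == np.argsort(x).tolist()
    assert np.argsort(yq).tolist() == np.argsort(y).tolist()


def test_qn_ties_get_mean_target():
    xq, _ = quantile_normalize_pair([1.0, 1.0, 5.0], [0.0, 2.0, 4.0])
    # targets: mean order stats ((1+0)/2, (1+2)/2, (5+4)/2) = (.5, 1.5, 4.5)
    np.testing.assert_allclose(xq, [1.0, 1.0, 4.5])


@given(seed=st.integers(0, 500), n=st.integers(2, 60))
@settings(max_examples=40, deadline=None)
def test_qn_law(seed, n):
    """Sorted outputs are the identical mean-order-statistic vector."""
    rng = np.random.default_rng(seed)
    x, y = rng.standard_normal(n), 2 + 3 * rng.standard_normal(n)
    xq, yq = quantile_normalize_pair(x, y)
    target = (np.sort(x) + np.sort(y)) / 2
    np.testing.assert_array_equal(np.sort(xq), target)
    np.testing.assert_array_equal(np.sort(yq), target)


def test_qn_rejects_bad_input():
    with pytest.raises(DifferentialError):
        quantile_normalize_pair([1.0, 2.0], [1.0])
    with pytest.raises(DifferentialError):
        quantile_normalize_pair([1.0, np.nan], [1.0, 2.0])


# ---------------------------------------------------------------------------
# loess

def test_loess_reproduces_global_line():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 10, 30)
    y = 2 * x + 1
    for span in (0.3, 2 / 3, 1.0):
        np.testing.assert_allclose(loess_fit(x, y, span=span, degree=1), y, atol=1e-10)


def test_loess_constant():
    x = np.linspace(0, 1, 20)
    np.testing.assert_allclose(loess_fit(x, np.full(20, 3.5)), 3.5, atol=1e-12)


def test_loess_quadratic_with_degree_two():
    x = np.linspace(-2, 2, 25)
    y = x**2 - x + 0.5
    np.testing.assert_allclose(loess_fit(x, y, span=0.5, degree=2), y, atol=1e-9)


@given(seed=st.integers(0, 300))
@settings(max_examples=30, deadline=None)
def test_loess_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 51))
    x = rng.uniform(0, 1, n)
    y = np.sin(3 * x) + 0.3 * rng.standard_normal(n)
    got = loess_fit(x, y, span=0.5, degree=1)
    want = brute_force_loess(x, y, span=0.5, degree=1)
    assert np.abs(got - want).max() < 1e-8


def test_loess_matches_reference_lowess():
    """Degree-1 loess agrees with the classic lowess implementation."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(7)
    x = np.sort(rng.uniform(0, 4, 40))
    y = np.cos(x) + 0.2 * rng.standard_normal(40)
    ours = loess_fit(x, y, span=0.6, degree=1)
    ref = sm.nonparametric.lowess(y, x, frac=0.6, it=0, return_sorted=False)
    np.testing.assert_allclose(ours, ref, atol=1e-7)


def test_loess_duplicate_x_ties_included():
    """Tied x values are all included in the neighbourhood without jitter; a
    fully tied neighbourhood degenerates to the flat mean of its y values."""
    x = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    got = loess_fit(x, y, span=0.5, degree=1)
    np.testing.assert_allclose(got[:3], 2.0, atol=1e-12)
    assert np.isfinite(got).all()


def test_loess_parameter_errors():
    x = np.arange(10.0)
    with pytest.raises(DifferentialError, match="span"):
        loess_fit(x, x, span=1.5)
    with pytest.raises(DifferentialError, match="too few"):
        loess_fit(x, x, span=0.1, degree=2)
    with pytest.raises(DifferentialError):
        loess_fit(x[:3], x[:3])


# ---------------------------------------------------------------------------
# differential scores

def _score_table_from(tox, via, genes=None):
    from ctlscreen.normalize import ScoreTable
    genes = genes or [f"G{i:04d}" for i in range(len(tox))]
    idx = pd.Index(genes, name="gene_id")
    scores = pd.DataFrame(
        {("s1", "with_ctl"): tox, ("s1", "without_ctl"): via}, index=idx
    )
    return ScoreTable(scores=scores, replicate_scores=scores, control_scores=pd.DataFrame())


def test_equal_conditions_give_zero_differential():
    rng = np.random.default_rng(3)
    v = rng.standard_normal(100)
    table = differential_scores(_score_table_from(v.copy(), v.copy()))
    assert np.abs(table.d["s1"].to_numpy()).max() < 1e-8


def test_single_offset_gene_recovered():
    """One gene lifted by +2 over an identity trend is found near +2."""
    rng = np.random.default_rng(12)
    via = rng.standard_normal(520)
    tox = via.copy()
    tox[37] += 2.0
    table = differential_scores(_score_table_from(tox, via))
    d = table.d["s1"].to_numpy()
    assert 1.5 <= d[37] <= 2.5
    rest = np.delete(d, 37)
    assert np.abs(rest).max() < 0.3


def test_simple_difference_mode():
    table = differential_scores(
        _score_table_from([1.0, 0.0, 0.5, -0.5], [0.0, 0.0, 0.5, 0.5]),
        method="simple_difference",
    )
    np.testing.assert_allclose(table.d["s1"], [1.0, 0.0, 0.0, -1.0])
    assert table.method == "simple_difference"


def test_unknown_method_rejected(default_run):
    with pytest.raises(DifferentialError, match="method"):
        differential_scores(default_run.score_table, method="magic")


def test_missing_condition_rejected(default_run):
    with pytest.raises(DifferentialError, match="lacks condition"):
        differential_scores(default_run.score_table, screens=["s4"])


def test_residual_mean_near_zero(default_run):
    d = default_run.differential.d
    assert abs(d.to_numpy().mean()) < 0.05


def test_viability_trend_removed(default_run):
    """Loess removes intrinsic-viability signal: lethal (m = 0) genes sit
    nearer zero differential than planted suppressors."""
    truth = default_run.truth
    d = default_run.differential.d
    lethal = truth.genes_of_class("lethal")
    sup = truth.genes_of_class("suppressor")
    assert d.loc[lethal].abs().mean().mean() < d.loc[sup].abs().mean().mean()
    assert d.loc[lethal].abs().mean().mean() < 0.5


def test_differential_metadata_recorded(default_run):
    diff = default_run.differential
    assert diff.method == "loess_residual"
    assert diff.span == pytest.approx(2 / 3)
    assert diff.degree == 1
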
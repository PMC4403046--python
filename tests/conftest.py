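import numpy as np
import pytest

from ctlscreen.design import LibraryDesign, default_library
from ctlscreen.pipeline import PipelineConfig, run_pipeline
from ctlscreen.simulate import SimConfig, generate_screen, generate_truth


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def small_library():
    """A 40-gene library that fits one plate, for fast unit tests."""
    return LibraryDesign(genes=tuple(f"G{i + 1:04d}" for i in range(40)))


@pytest.fixture(scope="session")
def small_sim():
    return SimConfig(
        n_suppressors=3, n_activators=3, n_lethals=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_library, small_sim):
    truth = generate_truth(small_library, small_sim)
    return generate_screen(small_library, truth, small_sim), truth


@pytest.fixture(scope="session")
def default_run():
    """One full default-condition pipeline run, shared across test modules."""
    return run_pipeline(PipelineConfig(seed=0))


@pytest.fixture(scope="session")
def noisefree_run():
    """Noise-free run with planted modulators (sigma = 0, h = 0)."""
    sim = SimConfig(noise_sd=0.0, heterogeneity=0.0)
    return run_pipeline(PipelineConfig(sim=sim, seed=3))


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive re-derivations, kept apart from the
# implementation paths they check)

def brute_force_loess(x, y, span, degree):
    """Tricube-weighted local polynomial fit via explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = int(np.ceil(span * n))
    fitted = np.empty(n)
    for i in range(n):
        dist = np.abs(x - x[i])
        d_max = sorted(dist)[k - 1]
        if d_max == 0:
            fitted[i] = np.mean([y[j] for j in range(n) if dist[j] == 0])
            continue
        idx = [j for j in range(n) if dist[j] <= d_max]
        w = np.array([(1 - (dist[j] / d_max) ** 3) ** 3 for j in idx])
        u = x[idx] - x[i]
        X = np.column_stack([u**p for p in range(degree + 1)])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[idx])
        fitted[i] = beta[0]
    return fitted


def textbook_pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a.mean(), b.mean()
    num = ((a - am) * (b - bm)).sum()
    den = np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum())
    return num / den
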
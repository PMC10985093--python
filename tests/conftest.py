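import numpy as np
import pandas as pd
import pytest

from loopshift import intervals as iv
from loopshift.hic import ContactMatrix, ice_balance
from loopshift.pipeline import run_pipeline
from loopshift.simulate import SimulationConfig, simulate_all


@pytest.fixture
def genome_small() -> iv.GenomeSpec:
    return iv.GenomeSpec((("chr1", 1_000_000), ("chr2", 500_000)))


@pytest.fixture(scope="session")
def sim_bundle() -> dict:
    """One default-config synthetic study shared by recovery-style tests."""
    return simulate_all(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def pipeline_result() -> dict:
    """Full pipeline run on the default synthetic study."""
    return run_pipeline(seed=11)


def poisson_symmetric(n: int, lam, seed: int, chrom: str = "chrS",
                      resolution: int = 50_000) -> ContactMatrix:
    """Poisson-sample a symmetric contact matrix around intensity ``lam``."""
    rng = np.random.default_rng(seed)
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (n, n))
    upper = rng.poisson(np.triu(lam))
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(chrom=chrom, resolution=resolution,
                         counts=counts.astype(float))


def planted_loop_matrix(n: int, n_loops: int, background: float,
                        strength: float, seed: int, gap_lo: int = 10,
                        gap_hi: int = 80, sep: int = 6, margin: int = 12,
                        noise: bool = True):
    """Flat background with 3x3 Gaussian focal peaks; returns (matrix, centers)."""
    rng = np.random.default_rng(seed)
    lam = np.full((n, n), background)
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n_loops and attempts < 100_000:
        attempts += 1
        i = int(rng.integers(margin, n - margin - gap_lo))
        j = i + int(rng.integers(gap_lo, gap_hi))
        if j >= n - margin:
            continue
        if any(max(abs(i - a), abs(j - b)) < sep for a, b in centers):
            continue
        centers.append((i, j))
    assert len(centers) == n_loops
    off = np.arange(-1, 2)
    g = np.exp(-(off[:, None] ** 2 + off[None, :] ** 2) / (2 * 0.7 ** 2))
    kern = 1 + (strength - 1) * g
    for i, j in centers:
        lam[i - 1:i + 2, j - 1:j + 2] *= kern
        lam[j - 1:j + 2, i - 1:i + 2] *= kern.T
    if noise:
        upper = rng.poisson(np.triu(lam))
        counts = (upper + np.triu(upper, 1).T).astype(float)
    else:
        counts = lam.copy()
    m = ContactMatrix(chrom="chrS", resolution=50_000, counts=counts)
    return m, centers
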
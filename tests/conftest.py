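import numpy as np
import pytest

from ectnct import Connectome, SyntheticConfig, generate_cohort, stabilize


def random_symmetric_stable(n: int, rng: np.random.Generator, rho: float = 0.8):
    """Random symmetric Schur-stable system via a normalized random adjacency."""
    from ectnct.controllability import StableSystem

    M = rng.normal(size=(n, n))
    M = 0.5 * (M + M.T)
    lam = np.max(np.abs(np.linalg.eigvalsh(M)))
    return StableSystem(A=M * (rho / lam), source_lambda_max=lam)


def random_binary_connectome(n: int, p: float, rng: np.random.Generator) -> Connectome:
    adj = (rng.random((n, n)) < p).astype(float)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    return Connectome.from_matrix(adj)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but statistically usable synthetic cohort (n=40, 50 nodes)."""
    cfg = SyntheticConfig(n_subjects=40, n_nodes=50, psi_missing_count=4, seed=7)
    return generate_cohort(cfg, include_eeg=False)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A tiny synthetic study written to disk for pipeline tests."""
    out = tmp_path_factory.mktemp("study")
    cfg = SyntheticConfig(
        n_subjects=14, n_nodes=30, psi_missing_count=2,
        eeg_phase_seconds=8.0, seed=11,
    )
    cohort = generate_cohort(cfg, out_dir=out)
    return out, cohort
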
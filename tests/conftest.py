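import numpy as np
import pytest

from phenolink.phenome import QUANTITATIVE, Phenome
from phenolink.simulate import SimConfig, biobank_config, simulate_biobank, simulate_genotypes


@pytest.fixture(scope="session")
def small_biobank():
    """One modest synthetic biobank shared across unit tests."""
    cfg = biobank_config(n_samples=2500, n_snps=400, seed=11)
    panel, full, observed, truth = simulate_biobank(cfg)
    return {"config": cfg, "panel": panel, "full": full,
            "observed": observed, "truth": truth}


@pytest.fixture(scope="session")
def tiny_panel():
    cfg = SimConfig(n_samples=300, n_snps=40, ld_block_size=10, ld_decay=0.8, seed=5)
    return simulate_genotypes(cfg)


def factor_phenome(n=2000, p=20, k=3, loading=0.7, seed=0, noise_cols=0):
    """Complete factor-structured phenome: p columns on k shared factors.

    ``loading`` may be a scalar or a per-factor sequence; distinct per-factor
    loadings avoid the rotation ambiguity of equal-variance factors.
    """
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, k))
    loads = np.broadcast_to(np.asarray(loading, float), (k,))
    lam = np.zeros((p, k))
    for j in range(p - noise_cols):
        lam[j, j % k] = loads[j % k]
    noise_sd = np.sqrt(1 - (lam**2).sum(axis=1))
    vals = Z @ lam.T + rng.standard_normal((n, p)) * noise_sd
    vals[:, p - noise_cols:] = rng.standard_normal((n, noise_cols))
    return Phenome(vals, np.ones_like(vals, dtype=bool),
                   [QUANTITATIVE] * p, [f"c{j}" for j in range(p)],
                   [f"S{i}" for i in range(n)])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
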
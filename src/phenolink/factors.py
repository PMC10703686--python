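"""Diagnostics of the latent phenome factors and factor-score covariates.

The completion fit's singular vectors play the role of phenome-wide latent
factors (eigenvectors of the phenotype covariance).  Two diagnostics rank
them: the fraction of observed phenome variance each explains, and the
split-half *prediction strength* — the squared correlation between matched
column-loading vectors estimated on disjoint sample halves (loadings are
the object comparable across halves; per-sample scores are not).  Factor
scores ``U * d`` serve as covariates for factor-conditioned GWAS scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .impute import ImputationFit, fit_softimpute
from .phenome import Phenome

__all__ = [
    "FactorDiagnostics",
    "variance_explained",
    "prediction_strength",
    "factor_scores",
]


@dataclass
class FactorDiagnostics:
    var_explained: np.ndarray
    prediction_strength: np.ndarray
    k: int


def variance_explained(fit: ImputationFit) -> np.ndarray:
    """Per-factor fraction of phenome variance: d_i^2 / ||X_obs||_F^2.

    The denominator is the total squared mass of the standardized observed
    matrix recorded on the fit, so the fractions are comparable across
    penalties; they are nonincreasing and sum to <= 1.
    """
    if fit.rank < 1:
        raise ValueError("fit has no factors")
    total = fit.total_obs_variance
    if total <= 0:
        raise ValueError("fit records no observed variance")
    frac = fit.d**2 / total
    return frac


def _match_loadings(VA: np.ndarray, VB: np.ndarray) -> np.ndarray:
    """Greedy match of half-B loading vectors to half-A factors.

    Returns, per factor of A in order, the squared correlation with its
    best-aligned unmatched factor of B (invariant to sign flips).
    """
    kA, kB = VA.shape[1], VB.shape[1]
    C = np.zeros((kA, kB))
    for a in range(kA):
        for b in range(kB):
            va, vb = VA[:, a], VB[:, b]
            denom = np.linalg.norm(va) * np.linalg.norm(vb)
            C[a, b] = 0.0 if denom == 0 else abs(va @ vb) / denom
    out = np.zeros(kA)
    used: set = set()
    # greedy over factor order of A (most variance first), best available match
    for a in range(kA):
        avail = [b for b in range(kB) if b not in used]
        if not avail:
            break
        b = max(avail, key=lambda b_: C[a, b_])
        used.add(b)
        out[a] = C[a, b] ** 2
    return out


def prediction_strength(phenome: Phenome, k: int, seed: int = 0,
                        lam: float = 0.0, max_rank: int = 50,
                        tol: float = 1e-5, max_iter: int = 500) -> np.ndarray:
    """Split-half stability of the first k factors.

    Samples are split 50/50 at random (deterministic given seed), the
    completion model is fit on each half at the same penalty, and each
    factor's loading vector in half A is greedily matched to its
    best-aligned factor in half B; the squared correlation of matched
    loadings is returned per factor.
    """
    n = phenome.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half_a, half_b = perm[: n // 2], perm[n // 2 :]

    def sub(idx):
        return Phenome(
            phenome.values[idx],
            phenome.mask[idx],
            list(phenome.col_types),
            list(phenome.col_names),
            [phenome.sample_ids[i] for i in idx],
        )

    fa = fit_softimpute(sub(half_a), lam, max_rank=max_rank, tol=tol,
                        max_iter=max_iter, seed=seed)
    fb = fit_softimpute(sub(half_b), lam, max_rank=max_rank, tol=tol,
                        max_iter=max_iter, seed=seed + 1)
    kk = min(k, fa.rank, fb.rank)
    if kk < k:
        warnings.warn(f"requested {k} factors but only {kk} fitted; truncating")
    if fa.V.shape[0] != fb.V.shape[0]:
        # column sets may differ if a half dropped thin columns; align by name
        common = [nm for nm in fa.col_names if nm in fb.col_names]
        ia = [fa.col_names.index(nm) for nm in common]
        ib = [fb.col_names.index(nm) for nm in common]
        VA, VB = fa.V[ia, :kk], fb.V[ib, :kk]
    else:
        VA, VB = fa.V[:, :kk], fb.V[:, :kk]
    return _match_loadings(VA, VB)


def factor_scores(fit: ImputationFit, k: int | None = None) -> np.ndarray:
    """Sample-level factor scores U * d with orthogonal columns.

    Suitable as covariates in association scans; ``k`` truncates to the
    leading factors (k=0 gives an empty covariate block).
    """
    scores = fit.U * fit.d
    if k is not None:
        scores = scores[:, :k]
    return scores
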
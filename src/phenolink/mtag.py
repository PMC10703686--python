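"""Inverse-covariance-weighted multi-trait combination of GWAS summary stats.

Per SNP, the vector of standardized effect estimates across traits is
combined by generalized least squares under a homogeneous genetic
covariance model: effects are assumed proportional across SNPs with
traits x traits genetic covariance Omega (per-SNP scale, diagonal h2/M) and
estimation-error covariance Sigma_j = D_j S D_j, where D_j holds the
per-trait standard errors at SNP j and S the error-correlation matrix from
cross-trait LD score regression intercepts.  For target trait t::

    gamma   = Omega[:, t] / Omega[t, t]
    A_j     = Omega - Omega[:,t] Omega[t,:] / Omega[t,t] + Sigma_j
    beta_t  = gamma' A_j^-1 bhat_j / (gamma' A_j^-1 gamma)
    se_t    = (gamma' A_j^-1 gamma)^-1/2

A single input trait passes through unchanged; a diagonal Omega (no genetic
correlation) reproduces each input as well.  The power-equivalent sample
size of the combined scan follows the mean-chi-square ratio formula
``n_effect = n_single * (chi2_mtag - 1) / (chi2_single - 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .assoc import FLAG_OK, SummaryStats
from .ldsc import LDScores, estimate_h2

__all__ = [
    "MTAGResult",
    "estimate_omega_sigma",
    "mtag_combine",
    "mtag_effective_n",
]


@dataclass
class MTAGResult:
    adjusted: dict                  # trait label -> SummaryStats (standardized scale)
    omega: np.ndarray
    sigma: np.ndarray
    n_eff: dict                     # trait label -> power-equivalent n


def _project_psd(A: np.ndarray, floor: float = 0.0, tol: float = 1e-8) -> np.ndarray:
    """Symmetrize and clip eigenvalues to make A positive semidefinite."""
    A = (A + A.T) / 2
    vals, vecs = np.linalg.eigh(A)
    if vals.min() < -tol * max(abs(vals).max(), 1.0):
        warnings.warn("covariance projected to nearest PSD matrix")
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _standardized_effects(stats_list):
    """Align SNPs across traits; return (snp index, b_hat, se) on z/sqrt(n) scale."""
    tables = []
    ref = stats_list[0].ok.set_index("SNP")
    common = ref.index
    for st in stats_list[1:]:
        common = common.intersection(st.ok.set_index("SNP").index)
    common = list(common)
    B = np.empty((len(common), len(stats_list)))
    SE = np.empty_like(B)
    for k, st in enumerate(stats_list):
        t = st.ok.set_index("SNP").loc[common]
        if k == 0:
            sign = np.ones(len(common))
        else:
            match = (t["A1"].to_numpy() == ref.loc[common, "A1"].to_numpy())
            swap = (t["A1"].to_numpy() == ref.loc[common, "A2"].to_numpy())
            sign = np.where(match, 1.0, np.where(swap, -1.0, np.nan))
        z = (t["BETA"] / t["SE"]).to_numpy() * sign
        n = t["N"].to_numpy().astype(float)
        B[:, k] = z / np.sqrt(n)
        SE[:, k] = 1.0 / np.sqrt(n)
        tables.append(t)
    keep = np.all(np.isfinite(B), axis=1)
    return [c for c, k in zip(common, keep) if k], B[keep], SE[keep], ref


def estimate_omega_sigma(stats_list: list, scores: LDScores, M: int | None = None):
    """Genetic (Omega) and error (Sigma) trait covariances from LDSC.

    Omega diagonal = per-SNP h2/M from single-trait LDSC; off-diagonals from
    cross-trait genetic covariance.  Sigma diagonal = LDSC intercepts,
    off-diagonals = cross-trait intercepts (sample overlap / shared
    confounding).  Both are projected to the nearest PSD matrix.
    """
    T = len(stats_list)
    if M is None:
        M = len(scores.table)
    omega = np.zeros((T, T))
    sigma = np.zeros((T, T))
    h2s = []
    for i, st in enumerate(stats_list):
        est = estimate_h2(st, scores, M=M)
        h2s.append(est)
        omega[i, i] = max(est.h2_obs, 1e-12) / M
        sigma[i, i] = max(est.intercept, 0.05)
    for i in range(T):
        for j in range(i + 1, T):
            ta = stats_list[i].ok.set_index("SNP")
            tb = stats_list[j].ok.set_index("SNP")
            common = ta.index.intersection(tb.index)
            ta, tb = ta.loc[common], tb.loc[common]
            za = (ta["BETA"] / ta["SE"]).to_numpy()
            zb = (tb["BETA"] / tb["SE"]).to_numpy()
            flip = tb["A1"].to_numpy() == ta["A2"].to_numpy()
            zb = zb * np.where(flip, -1.0, 1.0)
            l2 = scores.aligned(common)
            n_a = float(np.median(ta["N"]))
            n_b = float(np.median(tb["N"]))
            x = np.sqrt(n_a * n_b) * l2 / M
            w = 1.0 / np.maximum(l2, 1.0)
            X = np.column_stack([np.ones_like(x), x])
            Xw = X * w[:, None]
            icpt, slope = np.linalg.solve(X.T @ Xw, Xw.T @ (za * zb))
            omega[i, j] = omega[j, i] = slope / M
            sigma[i, j] = sigma[j, i] = icpt
    omega = _project_psd(omega, floor=0.0)
    # keep the diagonal strictly positive after projection
    omega[np.diag_indices(T)] = np.maximum(np.diag(omega), 1e-12 / M)
    sigma = _project_psd(sigma, floor=1e-6)
    if np.linalg.eigvalsh(sigma).min() <= 0:
        raise ValueError("sigma not positive definite after projection")
    return omega, sigma


def mtag_combine(stats_list: list, omega: np.ndarray, sigma: np.ndarray) -> MTAGResult:
    """GLS combination of aligned summary statistics for every target trait.

    Outputs adjusted BETA/SE/P on the standardized-genotype scale
    (inputs are converted via ``z / sqrt(n)``); P and downstream consumers
    (LD score regression, clumping, scoring, loci) are scale-free.  SNPs
    with a singular weighting matrix are passed through unadjusted and
    flagged.  With more than 10 input scans a warning is emitted: combining
    many traits is known to admit nonspecific false positives.
    """
    T = len(stats_list)
    if omega.shape != (T, T) or sigma.shape != (T, T):
        raise ValueError("omega/sigma must be traits x traits")
    if T > 10:
        warnings.warn("more than 10 input GWAS: expect inflated false positives")
    if T == 1:
        st = stats_list[0]
        n_eff = {st.trait_label: float(np.median(st.ok["N"]))}
        return MTAGResult({st.trait_label: st}, omega, sigma, n_eff)

    snps, B, SE, ref = _standardized_effects(stats_list)
    m = len(snps)
    adjusted = {}
    # Sigma_j = D_j S D_j, batched
    Sj = SE[:, :, None] * sigma[None, :, :] * SE[:, None, :]
    for t_idx, st in enumerate(stats_list):
        gamma = omega[:, t_idx] / omega[t_idx, t_idx]
        A = omega[None, :, :] - np.outer(omega[:, t_idx], omega[t_idx, :])[None] / omega[
            t_idx, t_idx
        ] + Sj
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        flags = np.array([FLAG_OK] * m, dtype=object)
        try:
            Ainv_g = np.linalg.solve(A, np.broadcast_to(gamma, (m, T))[..., None])[..., 0]
            denom = Ainv_g @ gamma
            num = np.einsum("mt,mt->m", Ainv_g, B)
            good = denom > 0
            beta[good] = num[good] / denom[good]
            se[good] = 1.0 / np.sqrt(denom[good])
            flags[~good] = "SINGULAR"
        except np.linalg.LinAlgError:
            # per-SNP fallback
            for j in range(m):
                try:
                    x = np.linalg.solve(A[j], gamma)
                    beta[j] = x @ B[j] / (x @ gamma)
                    se[j] = 1.0 / np.sqrt(x @ gamma)
                except np.linalg.LinAlgError:
                    flags[j] = "SINGULAR"
                    beta[j] = B[j, t_idx]
                    se[j] = SE[j, t_idx]

        tab = ref.loc[snps].reset_index()[["SNP", "CHR", "BP", "A1", "A2", "FRQ"]].copy()
        tab["BETA"] = beta
        tab["SE"] = se
        with np.errstate(divide="ignore", invalid="ignore"):
            tab["P"] = np.maximum(sps.chi2.sf((beta / se) ** 2, 1), np.finfo(float).tiny)
        # N = GLS-precision effective sample size (1/SE^2 on the
        # standardized scale), the sample-size entry downstream LDSC uses
        n_in = st.ok.set_index("SNP").loc[snps, "N"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            n_gls = np.where(np.isfinite(se) & (se > 0),
                             np.round(1.0 / se**2), n_in)
        tab["N"] = n_gls
        tab["TEST"] = "mtag"
        tab["FLAG"] = flags
        label = st.trait_label or f"trait{t_idx}"
        out = SummaryStats(tab, label)
        n_single = float(np.median(st.ok["N"]))
        single_aligned = st.ok.set_index("SNP").loc[snps]
        chi2_single = float(np.mean((single_aligned["BETA"] / single_aligned["SE"]) ** 2))
        chi2_mtag = float(np.mean((beta[np.isfinite(beta)] / se[np.isfinite(beta)]) ** 2))
        adjusted[label] = out
    result = MTAGResult(adjusted, omega, sigma, {})
    for t_idx, st in enumerate(stats_list):
        label = st.trait_label or f"trait{t_idx}"
        try:
            result.n_eff[label] = mtag_effective_n(st, adjusted[label])
        except ValueError:
            result.n_eff[label] = np.nan
    return result


def mtag_effective_n(stats_single: SummaryStats, stats_mtag: SummaryStats,
                     n_single: float | None = None) -> float:
    """Power-equivalent n: ``n_single * (chi2_mtag - 1) / (chi2_single - 1)``.

    Mean chi-squares are taken over the shared SNPs; a single-trait mean
    chi-square <= 1 leaves the ratio undefined.
    """
    ta = stats_single.ok.set_index("SNP")
    tb = stats_mtag.ok.set_index("SNP")
    common = ta.index.intersection(tb.index)
    ta, tb = ta.loc[common], tb.loc[common]
    chi_s = float(np.mean((ta["BETA"] / ta["SE"]) ** 2))
    chi_m = float(np.mean((tb["BETA"] / tb["SE"]) ** 2))
    if n_single is None:
        n_single = float(np.median(ta["N"]))
    if chi_s <= 1:
        raise ValueError("mean single-trait chi-square <= 1; effective n undefined")
    return n_single * (chi_m - 1.0) / (chi_s - 1.0)
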
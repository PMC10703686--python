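"""LD score regression: SNP heritability, genetic correlation, liability scale.

Under a polygenic model the expected association chi-square at SNP j is
``1 + n * h2 * l2_j / M`` where ``l2_j`` is the LD score (sum of r^2 with
all SNPs in a window, bias-adjusted, including itself).  Regressing
chi-square on ``n * l2 / M`` with a free intercept therefore estimates h2
on the observed scale while the intercept absorbs confounding; the
cross-trait version regresses ``z_a * z_b`` on ``sqrt(n_a n_b) * l2 / M``
to estimate the genetic covariance and hence the genetic correlation r_g.
Standard errors come from a delete-a-block jackknife over contiguous SNP
blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assoc import SummaryStats
from .phenome import GenotypePanel

__all__ = [
    "LDScores",
    "HeritabilityEstimate",
    "GeneticCorrelation",
    "compute_ld_scores",
    "estimate_h2",
    "liability_transform",
    "estimate_rg",
    "effective_n_cc",
]


@dataclass
class LDScores:
    table: pd.DataFrame          # columns: snp, l2
    window_bp: int
    n_ref: int

    def aligned(self, snps) -> np.ndarray:
        s = self.table.set_index("snp")["l2"]
        return s.loc[list(snps)].to_numpy()


@dataclass
class HeritabilityEstimate:
    h2_obs: float
    h2_se: float
    intercept: float
    intercept_se: float
    h2_liab: float | None = None
    K: float | None = None
    P: float | None = None
    n: float | None = None
    trait_label: str = ""


@dataclass
class GeneticCorrelation:
    rg: float
    se: float
    traits: tuple = ("", "")
    gencov: float = np.nan
    flagged: bool = False        # |rg| > 1.25 suggests a degenerate estimate


def compute_ld_scores(panel: GenotypePanel, window_bp: int = 1_000_000) -> LDScores:
    """Bias-adjusted LD scores within a bp window.

    ``l2_j = sum_k [ r2_jk - (1 - r2_jk) / (n_ref - 2) ]`` over SNPs k on the
    same chromosome with |bp_j - bp_k| <= window, including the self term.
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    n = panel.n_samples
    if n < 3:
        raise ValueError("reference panel too small")
    bp = panel.snp_map["bp"].to_numpy()
    chrom = panel.snp_map["chr"].to_numpy()
    m = panel.n_snps
    l2 = np.zeros(m)
    adj = 1.0 / (n - 2)

    def standardized_cols(cols):
        # local standardization keeps memory bounded at genome scale
        d = panel.dosages[:, cols].astype(float)
        mu = d.mean(axis=0)
        sd = d.std(axis=0)
        sd[sd == 0] = 1.0
        return (d - mu) / (sd * np.sqrt(n))

    for c in pd.unique(chrom):
        idx = np.where(chrom == c)[0]
        cbp = bp[idx]
        # group into "superblocks" of SNPs chained by <= window gaps; SNPs in
        # different superblocks are farther than window apart by construction
        breaks = np.where(np.diff(cbp) > window_bp)[0] + 1
        for grp in np.split(np.arange(len(idx)), breaks):
            gidx = idx[grp]
            sub = standardized_cols(gidx)
            R2 = (sub.T @ sub) ** 2
            gbp = bp[gidx]
            within = np.abs(gbp[:, None] - gbp[None, :]) <= window_bp
            contrib = (R2 - (1 - R2) * adj) * within
            l2[gidx] = contrib.sum(axis=1)
    return LDScores(pd.DataFrame({"snp": panel.snp_map["snp"], "l2": l2}),
                    window_bp, n)


def _jackknife_blocks(m: int, n_blocks: int = 200):
    if m < n_blocks:
        warnings.warn(f"only {m} SNPs; reducing jackknife blocks to {max(m // 2, 2)}")
        n_blocks = max(m // 2, 2)
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_blocks) if edges[i + 1] > edges[i]]


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    X = np.column_stack([np.ones_like(x), x])
    Xw = X * w[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    return float(coef[0]), float(coef[1])


def estimate_h2(stats: SummaryStats, scores: LDScores, n: float | None = None,
                M: int | None = None, n_jackknife: int = 200) -> HeritabilityEstimate:
    """Observed-scale SNP heritability by LD score regression.

    Weighted regression (weights 1/max(l2,1)) of per-SNP chi-square on
    ``n*l2/M`` with a free intercept; the slope is h2_obs.  ``n`` defaults
    to the stats' median N (callers supply the MTAG effective n for MTAG
    inputs); ``M`` defaults to the number of scored SNPs.  SEs by
    delete-a-block jackknife.
    """
    t = stats.ok
    snps = t["SNP"].to_numpy()
    l2 = scores.aligned(snps)
    chi2 = (t["BETA"].to_numpy() / t["SE"].to_numpy()) ** 2
    if n is None:
        n = float(np.median(t["N"].to_numpy()))
    if M is None:
        M = len(scores.table)
    x = n * l2 / M
    w = 1.0 / np.maximum(l2, 1.0)

    icpt, slope = _wls(x, chi2, w)
    blocks = _jackknife_blocks(len(x), n_jackknife)
    th = np.array([
        _wls(np.delete(x, np.s_[a:b]), np.delete(chi2, np.s_[a:b]),
             np.delete(w, np.s_[a:b]))
        for a, b in blocks
    ])
    B = len(blocks)
    se_icpt, se_slope = np.sqrt((B - 1) / B * ((th - th.mean(axis=0)) ** 2).sum(axis=0))
    return HeritabilityEstimate(slope, float(se_slope), icpt, float(se_icpt),
                                n=n, trait_label=stats.trait_label)


def liability_transform(h2_obs: float, K: float, P: float) -> float:
    """Observed-scale to liability-scale heritability with ascertainment.

    ``h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) * phi(t)^2)`` with
    ``t = Phi^-1(1-K)`` the liability threshold and phi the standard normal
    density.
    """
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("K and P must lie in (0, 1)")
    t = sps.norm.ppf(1 - K)
    z = sps.norm.pdf(t)
    return h2_obs * K**2 * (1 - K) ** 2 / (P * (1 - P) * z**2)


def estimate_rg(stats_a: SummaryStats, stats_b: SummaryStats, scores: LDScores,
                n_a: float | None = None, n_b: float | None = None,
                M: int | None = None, n_jackknife: int = 200) -> GeneticCorrelation:
    """Genetic correlation by cross-trait LD score regression.

    The slope of ``z_a * z_b`` on ``sqrt(n_a n_b) * l2 / M`` estimates the
    genetic covariance; r_g divides by the geometric mean of the two h2
    estimates.  The full ratio is jackknifed per block.  Nonpositive h2 in
    either trait leaves r_g undefined (NaN, flagged).
    """
    ta = stats_a.ok.set_index("SNP")
    tb = stats_b.ok.set_index("SNP")
    common = ta.index.intersection(tb.index)
    if len(common) < 200:
        warnings.warn("fewer than 200 shared SNPs; rg estimate will be unstable")
    ta, tb = ta.loc[common], tb.loc[common]
    # align alleles: flip z_b when the allele pair is swapped
    flip = (tb["A1"].to_numpy() == ta["A2"].to_numpy()) & (
        tb["A2"].to_numpy() == ta["A1"].to_numpy()
    )
    match = (tb["A1"].to_numpy() == ta["A1"].to_numpy()) & (
        tb["A2"].to_numpy() == ta["A2"].to_numpy()
    )
    keep = match | flip
    ta, tb, flip = ta[keep], tb[keep], flip[keep]

    za = (ta["BETA"] / ta["SE"]).to_numpy()
    zb = (tb["BETA"] / tb["SE"]).to_numpy() * np.where(flip, -1.0, 1.0)
    l2 = scores.aligned(ta.index)
    if n_a is None:
        n_a = float(np.median(ta["N"]))
    if n_b is None:
        n_b = float(np.median(tb["N"]))
    if M is None:
        M = len(scores.table)

    x_ab = np.sqrt(n_a * n_b) * l2 / M
    x_a = n_a * l2 / M
    x_b = n_b * l2 / M
    w = 1.0 / np.maximum(l2, 1.0)

    def rg_of(sl):
        cov = _wls(x_ab[sl], (za * zb)[sl], w[sl])[1]
        h2a = _wls(x_a[sl], (za**2)[sl], w[sl])[1]
        h2b = _wls(x_b[sl], (zb**2)[sl], w[sl])[1]
        if h2a <= 0 or h2b <= 0:
            return np.nan, cov
        return cov / np.sqrt(h2a * h2b), cov

    full = np.ones(len(za), dtype=bool)
    rg, gencov = rg_of(full)
    blocks = _jackknife_blocks(len(za), n_jackknife)
    reps = []
    for a, b in blocks:
        sl = full.copy()
        sl[a:b] = False
        reps.append(rg_of(sl)[0])
    reps = np.array(reps)
    if np.isnan(rg):
        return GeneticCorrelation(np.nan, np.nan,
                                  (stats_a.trait_label, stats_b.trait_label),
                                  gencov, flagged=True)
    finite = np.isfinite(reps)
    if finite.sum() < len(reps) // 2:
        se = np.nan
    else:
        r = reps[finite]
        B = len(r)
        se = float(np.sqrt((B - 1) / B * np.sum((r - r.mean()) ** 2)))
    return GeneticCorrelation(float(rg), se,
                              (stats_a.trait_label, stats_b.trait_label),
                              float(gencov),
                              flagged=bool(abs(rg) > 1.25 or not finite.all()))


def effective_n_cc(n_cases: float, n_controls: float) -> float:
    """Case-control effective sample size ``4 / (1/n_cases + 1/n_controls)``."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("both counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)
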
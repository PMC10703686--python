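"""Per-SNP association scans and downstream GWAS utilities.

Linear scans use the Frisch–Waugh–Lovell residualization trick (project the
phenotype and every dosage column off the covariates once, then run the
per-SNP simple regressions vectorized), which is numerically identical to
the full OLS per SNP.  Logistic scans run a per-SNP Newton (IRLS) maximum-
likelihood fit warm-started at the covariates-only null fit.  P-values are
two-sided Wald throughout (chi-square on (beta/se)^2).

Also here: the genomic inflation factor lambda_GC, greedy locus definition
at genome-wide significance, fixed/random-effects heterogeneity meta-
analysis (Cochran's Q + DerSimonian–Laird), replication checks with allele
alignment, and genotype principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phenome import GenotypePanel

__all__ = [
    "SummaryStats",
    "LocusSet",
    "linear_scan",
    "logistic_scan",
    "genomic_inflation",
    "define_loci",
    "heterogeneity_meta",
    "replication_check",
    "compute_pcs",
    "align_effects",
]

GENOME_WIDE_P = 5e-8
CHI2_MEDIAN_1DF = float(sps.chi2.ppf(0.5, 1))  # 0.454936...

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FRQ", "BETA", "SE", "P", "N", "TEST"]

FLAG_OK = "OK"
FLAG_MONOMORPHIC = "MONOMORPHIC"
FLAG_SEPARATION = "SEPARATION"
FLAG_NOCONV = "NOCONV"
FLAG_DEGENERATE = "DEGENERATE"


@dataclass
class SummaryStats:
    """Per-SNP association results; the interchange currency of the pipeline.

    ``table`` has columns SNP CHR BP A1 A2 FRQ BETA SE P N TEST plus a FLAG
    column; flagged SNPs carry NaN estimates and are excluded from loci.
    """

    table: pd.DataFrame
    trait_label: str = ""

    def __post_init__(self):
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary stats missing columns: {missing}")
        if "FLAG" not in self.table.columns:
            self.table = self.table.assign(FLAG=FLAG_OK)
        if self.table["SNP"].duplicated().any():
            raise ValueError("summary stats records must be unique by SNP")

    @property
    def ok(self) -> pd.DataFrame:
        return self.table[self.table["FLAG"] == FLAG_OK]

    @property
    def chi2(self) -> np.ndarray:
        t = self.ok
        return (t["BETA"].to_numpy() / t["SE"].to_numpy()) ** 2

    @property
    def lambda_gc(self) -> float:
        return genomic_inflation(self)

    @property
    def mean_chi2(self) -> float:
        return float(np.mean(self.chi2))


@dataclass
class LocusSet:
    """Disjoint merged genome-wide-significant regions."""

    loci: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chr", "bp_start", "bp_end", "lead_snp", "lead_p", "n_snps"]
        )
    )

    def __len__(self) -> int:
        return len(self.loci)


def _check_covariates(covariates, n: int) -> np.ndarray:
    """Validate covariates and prepend an intercept; errors name collinear columns."""
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[-1] == 0):
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cur = X[:, :1]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(j - 1)
            else:
                cur = cand
        raise ValueError(f"rank-deficient covariates (collinear columns: {bad})")
    return X


def _empty_table(panel: GenotypePanel, n: int, test: str) -> pd.DataFrame:
    t = panel.snp_map.iloc[:, :6].copy()
    t.columns = ["SNP", "CHR", "BP", "A1", "A2", "FRQ"]
    t["BETA"] = np.nan
    t["SE"] = np.nan
    t["P"] = np.nan
    t["N"] = n
    t["TEST"] = test
    t["FLAG"] = FLAG_OK
    return t


def linear_scan(panel: GenotypePanel, y: np.ndarray, covariates=None,
                trait_label: str = "") -> SummaryStats:
    """OLS of y on each dosage column plus covariates and intercept.

    Exact per-SNP OLS via residualization; two-sided Wald p from
    (beta/se)^2 ~ chi2(1).  Monomorphic SNPs are flagged and skipped;
    perfect fits are flagged DEGENERATE.
    """
    y = np.asarray(y, dtype=float)
    n = panel.n_samples
    if y.shape != (n,):
        raise ValueError("y must be a complete vector over the panel's samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be complete (no NaN) on analyzed samples")
    X = _check_covariates(covariates, n)
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    m = panel.n_snps
    gg = np.empty(m)
    gy = np.empty(m)
    mono = np.empty(m, dtype=bool)
    # chunked over SNPs to bound memory at genome scale
    for a in range(0, m, 2048):
        G = panel.dosages[:, a : a + 2048].astype(float)
        mono[a : a + 2048] = G.std(axis=0) == 0
        G -= Q @ (Q.T @ G)
        gg[a : a + 2048] = np.einsum("ij,ij->j", G, G)
        gy[a : a + 2048] = G.T @ y_r
    gg_safe = np.where(gg > 0, gg, 1.0)
    beta = gy / gg_safe
    dof = n - X.shape[1] - 1
    if dof <= 0:
        raise ValueError("not enough samples for the covariate count")
    yy = float(y_r @ y_r)
    rss = yy - beta**2 * gg_safe
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / gg_safe)

    t = _empty_table(panel, n, "linear")
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = (beta / se) ** 2
    t["BETA"] = beta
    t["SE"] = se
    t["P"] = np.maximum(sps.chi2.sf(z2, 1), np.finfo(float).tiny)
    degen = (rss <= 1e-12 * max(yy, 1e-300)) | ~np.isfinite(se)
    t.loc[degen & ~mono, "FLAG"] = FLAG_DEGENERATE
    t.loc[mono, "FLAG"] = FLAG_MONOMORPHIC
    t.loc[t["FLAG"] != FLAG_OK, ["BETA", "SE", "P"]] = np.nan
    return SummaryStats(t, trait_label)


def _irls(X: np.ndarray, y: np.ndarray, beta0=None, max_iter: int = 30, tol: float = 1e-10):
    """Newton (IRLS) logistic ML.  Returns (beta, cov, converged, diverged)."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    converged = False
    diverged = False
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            diverged = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 30:
            diverged = True
            break
    if diverged or not converged:
        cov = np.full((p, p), np.nan)
    else:
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = (X * W[:, None]).T @ X
        cov = np.linalg.inv(H)
    return beta, cov, converged, diverged


def logistic_scan(panel: GenotypePanel, y: np.ndarray, covariates=None,
                  trait_label: str = "") -> SummaryStats:
    """Per-SNP maximum-likelihood logistic regression (Newton/IRLS).

    Wald beta/SE/p per SNP; separated or non-converged SNPs are flagged and
    carry no finite estimate.
    """
    y = np.asarray(y, dtype=float)
    n = panel.n_samples
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or len(classes) < 2:
        raise ValueError("y must be binary 0/1 with both classes present")
    C = _check_covariates(covariates, n)
    beta_null, _, conv_null, _ = _irls(C, y)
    if not conv_null:
        raise RuntimeError("null logistic model did not converge")

    t = _empty_table(panel, n, "logistic")
    beta = np.full(panel.n_snps, np.nan)
    se = np.full(panel.n_snps, np.nan)
    flags = np.array([FLAG_OK] * panel.n_snps, dtype=object)
    warm = np.append(beta_null, 0.0)
    X = np.column_stack([C, np.zeros(n)])
    for j in range(panel.n_snps):
        g = panel.dosages[:, j].astype(float)
        if g.std() == 0:
            flags[j] = FLAG_MONOMORPHIC
            continue
        X[:, -1] = g
        b, cov, conv, div = _irls(X, y, beta0=warm)
        if div:
            flags[j] = FLAG_SEPARATION
            continue
        if not conv:
            flags[j] = FLAG_NOCONV
            continue
        beta[j] = b[-1]
        se[j] = np.sqrt(cov[-1, -1])
    t["BETA"] = beta
    t["SE"] = se
    with np.errstate(divide="ignore", invalid="ignore"):
        t["P"] = np.maximum(sps.chi2.sf((beta / se) ** 2, 1), np.finfo(float).tiny)
    t["FLAG"] = flags
    t.loc[t["FLAG"] != FLAG_OK, ["BETA", "SE", "P"]] = np.nan
    return SummaryStats(t, trait_label)


def genomic_inflation(stats: SummaryStats) -> float:
    """lambda_GC = median((beta/se)^2) / median of chi2(1)."""
    chi2 = stats.chi2
    if len(chi2) == 0:
        raise ValueError("no usable SNPs")
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def define_loci(stats: SummaryStats, p_threshold: float = GENOME_WIDE_P,
                merge_window: int = 500_000) -> LocusSet:
    """Greedy merge of significant SNPs within ``merge_window`` bp per chromosome.

    Lead SNP per locus is the smallest p (ties to smaller bp).
    """
    t = stats.ok
    sig = t[t["P"] <= p_threshold].sort_values(["CHR", "BP"], kind="stable")
    rows = []
    for chrom, sub in sig.groupby("CHR", sort=False):
        bp = sub["BP"].to_numpy()
        start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or bp[i] - bp[i - 1] > merge_window:
                grp = sub.iloc[start:i]
                lead = grp.sort_values(["P", "BP"], kind="stable").iloc[0]
                rows.append(
                    {
                        "chr": chrom,
                        "bp_start": int(grp["BP"].min()),
                        "bp_end": int(grp["BP"].max()),
                        "lead_snp": lead["SNP"],
                        "lead_p": float(lead["P"]),
                        "n_snps": len(grp),
                    }
                )
                start = i
    return LocusSet(pd.DataFrame(rows, columns=["chr", "bp_start", "bp_end",
                                                "lead_snp", "lead_p", "n_snps"]))


def align_effects(ref: pd.Series, other: pd.Series):
    """Align an effect to a reference allele pair.

    Returns (sign, ok): sign=+1 if (a1, a2) match, -1 if swapped, ok=False
    if the alleles are unalignable.
    """
    if (other["A1"], other["A2"]) == (ref["A1"], ref["A2"]):
        return 1.0, True
    if (other["A1"], other["A2"]) == (ref["A2"], ref["A1"]):
        return -1.0, True
    return 0.0, False


def heterogeneity_meta(stats_list: list) -> pd.DataFrame:
    """Fixed-effects IVW combination with Cochran's Q and DerSimonian–Laird RE.

    Input studies must be on disjoint samples.  SNPs are aligned to the
    first study's effect allele (beta flipped on a1/a2 swap; unalignable
    records dropped).  SNPs present in a single study are passed through
    with flag ``SINGLE_STUDY`` and Q/p_het NaN.
    """
    if len(stats_list) < 2:
        raise ValueError("need at least two studies")
    ref = stats_list[0].ok.set_index("SNP")
    per_snp: dict = {}
    for k, st in enumerate(stats_list):
        t = st.ok.set_index("SNP")
        for snp, row in t.iterrows():
            sign = 1.0
            if snp in ref.index and k > 0:
                sign, okflag = align_effects(ref.loc[snp], row)
                if not okflag:
                    continue
            per_snp.setdefault(snp, []).append((sign * row["BETA"], row["SE"]))

    rows = []
    for snp, entries in per_snp.items():
        betas = np.array([e[0] for e in entries])
        ses = np.array([e[1] for e in entries])
        k = len(entries)
        if k == 1:
            rows.append({"SNP": snp, "k": 1, "beta_fe": betas[0], "se_fe": ses[0],
                         "Q": np.nan, "p_het": np.nan, "beta_re": betas[0],
                         "se_re": ses[0], "FLAG": "SINGLE_STUDY"})
            continue
        w = 1.0 / ses**2
        beta_fe = float(np.sum(w * betas) / np.sum(w))
        se_fe = float(np.sqrt(1.0 / np.sum(w)))
        Q = float(np.sum(w * (betas - beta_fe) ** 2))
        p_het = float(sps.chi2.sf(Q, k - 1))
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
        w_re = 1.0 / (ses**2 + tau2)
        beta_re = float(np.sum(w_re * betas) / np.sum(w_re))
        se_re = float(np.sqrt(1.0 / np.sum(w_re)))
        rows.append({"SNP": snp, "k": k, "beta_fe": beta_fe, "se_fe": se_fe,
                     "Q": Q, "p_het": p_het, "beta_re": beta_re, "se_re": se_re,
                     "FLAG": FLAG_OK})
    return pd.DataFrame(rows)


def replication_check(discovery_loci: LocusSet, discovery: SummaryStats,
                      replication: list, alpha_family: int | None = None) -> pd.DataFrame:
    """Per discovery lead SNP and replication cohort: sign consistency of the
    aligned beta and a Bonferroni replication flag at 0.05/m.

    ``alpha_family`` defaults to the number of discovery loci.
    """
    m = alpha_family if alpha_family is not None else max(len(discovery_loci), 1)
    disc = discovery.ok.set_index("SNP")
    rows = []
    for _, locus in discovery_loci.loci.iterrows():
        snp = locus["lead_snp"]
        d = disc.loc[snp]
        for ci, rep in enumerate(replication):
            t = rep.ok.set_index("SNP")
            if snp not in t.index:
                rows.append({"locus_lead": snp, "cohort": rep.trait_label or f"rep{ci}",
                             "aligned_beta": np.nan, "sign_consistent": False,
                             "replicated": False, "note": "absent"})
                continue
            r = t.loc[snp]
            sign, okflag = align_effects(d, r)
            if not okflag:
                rows.append({"locus_lead": snp, "cohort": rep.trait_label or f"rep{ci}",
                             "aligned_beta": np.nan, "sign_consistent": False,
                             "replicated": False, "note": "unalignable"})
                continue
            ab = sign * r["BETA"]
            rows.append({
                "locus_lead": snp,
                "cohort": rep.trait_label or f"rep{ci}",
                "aligned_beta": ab,
                "sign_consistent": bool(np.sign(ab) == np.sign(d["BETA"])),
                "replicated": bool(r["P"] < 0.05 / m),
                "note": "",
            })
    return pd.DataFrame(rows)


def compute_pcs(panel: GenotypePanel, k: int, seed: int = 0) -> np.ndarray:
    """Top-k principal components of the column-standardized dosage matrix.

    Returns the n x k score matrix U * S (orthogonal columns), deterministic
    given the seed of the randomized range finder; sign fixed so the largest
    absolute loading of each PC is positive.
    """
    n, m = panel.n_samples, panel.n_snps
    if k > min(n, m):
        raise ValueError("k exceeds matrix rank bound")
    if k == 0:
        return np.zeros((n, 0))
    Gs = panel.standardized()
    rng = np.random.default_rng(seed)
    # randomized subspace iteration
    over = min(10, m - k)
    Omega = rng.standard_normal((m, k + over))
    Y = Gs @ Omega
    for _ in range(3):
        Y = Gs @ (Gs.T @ Y)
        Y, _ = np.linalg.qr(Y)
    Q, _ = np.linalg.qr(Y)
    B = Q.T @ Gs
    Ub, s, _ = np.linalg.svd(B, full_matrices=False)
    U = Q @ Ub[:, :k]
    scores = U * s[:k]
    # deterministic sign convention
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores
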
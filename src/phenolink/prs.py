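"""Clumping + thresholding polygenic scores and the PRS-pleiotropy metric.

A PRS is built PRSice-style: greedy LD clumping by ascending p-value, then
a p-value threshold chosen on training data; the score is the weighted
dosage sum.  Accuracy is the *incremental* fit over a covariates-only
model: Nagelkerke's pseudo-R^2 for binary phenotypes, partial R^2 for
quantitative ones.  ``crossval_pipeline`` jointly cross-validates the whole
chain — imputation, secondary GWAS, multi-trait combination, threshold
selection — inside each training fold, so held-out accuracy is honest.

The specificity metric *PRS pleiotropy* is the ratio of a score's accuracy
on a secondary phenotype to its accuracy on the target; *excess* pleiotropy
subtracts the spectrum of a baseline (deep-target) PRS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import impute as _impute
from . import mtag as _mtag
from .assoc import _irls, linear_scan, logistic_scan
from .ldsc import compute_ld_scores
from .phenome import BINARY, GenotypePanel, Phenome

__all__ = [
    "PRSModel",
    "PRSEvaluation",
    "PleiotropySpectrum",
    "PRSConfig",
    "clump",
    "build_and_score",
    "nagelkerke_r2",
    "incremental_r2",
    "crossval_pipeline",
    "pleiotropy_spectrum",
    "excess_pleiotropy",
]

DEFAULT_P_GRID = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class PRSModel:
    """Scoring file: retained SNPs, effect alleles and weights."""

    weights: pd.DataFrame            # columns: SNP, A1, weight
    p_threshold: float
    clump_r2: float
    clump_window_bp: int
    source_trait: str = ""


@dataclass
class PRSEvaluation:
    metric: str                      # nagelkerke | ordinary
    r2: float
    p_score: float = np.nan          # Wald p of the score term
    n: int = 0
    target_label: str = ""
    ci: tuple = (np.nan, np.nan)
    converged: bool = True


@dataclass
class PleiotropySpectrum:
    table: pd.DataFrame              # phenotype, r2_secondary, ratio, excess, significant
    target: str
    r2_target: float


@dataclass
class PRSConfig:
    """Knobs of the cross-validated scoring pipeline."""

    p_grid: tuple = DEFAULT_P_GRID
    clump_r2: float = 0.1
    clump_window_bp: int = 250_000
    folds: int = 10
    lambda_grid_points: int = 8
    max_rank: int = 50
    softimpute_tol: float = 1e-4
    mtag_inputs: tuple = ()          # secondary phenotype names for MTAG presets
    covariates: np.ndarray | None = None
    seed: int = 0


# ----------------------------------------------------------------------
# C+T


def clump(stats, panel: GenotypePanel, r2_threshold: float = 0.1,
          window_bp: int = 250_000) -> list:
    """Greedy LD clumping by ascending p-value.

    A SNP is removed if it lies within ``window_bp`` of an already retained
    SNP and their squared dosage correlation is >= ``r2_threshold``.
    Deterministic: ties in p break by smaller bp.  Returns retained SNP ids.
    """
    t = stats.ok
    pmap = panel.snp_map.set_index("snp")
    t = t[t["SNP"].isin(pmap.index)]
    order = t.sort_values(["P", "BP"], kind="stable")
    col_of = {s: i for i, s in enumerate(panel.snp_map["snp"])}
    Gs = panel.standardized()
    n = panel.n_samples

    kept: dict = {}                  # chr -> list of (bp, col)
    retained = []
    for _, row in order.iterrows():
        snp, chrom, bp = row["SNP"], row["CHR"], row["BP"]
        col = col_of[snp]
        pruned = False
        for kbp, kcol in kept.get(chrom, []):
            if abs(kbp - bp) <= window_bp:
                r = float(Gs[:, col] @ Gs[:, kcol]) / n
                if r * r >= r2_threshold:
                    pruned = True
                    break
        if not pruned:
            kept.setdefault(chrom, []).append((bp, col))
            retained.append(snp)
    return retained


def build_and_score(stats, retained: list, p_threshold: float,
                    panel: GenotypePanel) -> tuple:
    """Score = sum of aligned weights x dosages over retained SNPs with p <= threshold.

    Weights are aligned to the panel's effect allele (sign flipped on an
    a1/a2 swap; unalignable SNPs dropped).  Returns (scores, PRSModel).
    """
    t = stats.ok.set_index("SNP")
    pmap = panel.snp_map.set_index("snp")
    col_of = {s: i for i, s in enumerate(panel.snp_map["snp"])}
    rows = []
    for snp in retained:
        if snp not in t.index or t.loc[snp, "P"] > p_threshold:
            continue
        rec = t.loc[snp]
        pan = pmap.loc[snp]
        if (rec["A1"], rec["A2"]) == (pan["a1"], pan["a2"]):
            w = float(rec["BETA"])
        elif (rec["A1"], rec["A2"]) == (pan["a2"], pan["a1"]):
            w = -float(rec["BETA"])
        else:
            continue
        rows.append((snp, pan["a1"], w, col_of[snp]))
    model = PRSModel(
        pd.DataFrame([(s, a, w) for s, a, w, _ in rows], columns=["SNP", "A1", "weight"]),
        p_threshold,
        np.nan,
        0,
        stats.trait_label,
    )
    if not rows:
        return np.zeros(panel.n_samples), model
    cols = [c for *_, c in rows]
    w = np.array([w for _, _, w, _ in rows])
    scores = panel.dosages[:, cols].astype(float) @ w
    return scores, model


# ----------------------------------------------------------------------
# evaluation metrics


def _loglik(y, eta):
    eta = np.clip(eta, -35, 35)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def nagelkerke_r2(y: np.ndarray, score: np.ndarray, covariates=None) -> PRSEvaluation:
    """Incremental Nagelkerke pseudo-R^2 of the score over covariates.

    ``[1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)]`` comparing the covariates+score
    logistic model (L1) to covariates-only (L0); with covariates, L0 is the
    covariates-only model, so the statistic isolates the score term.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, float)]
    )
    b0, _, conv0, _ = _irls(C, y)
    X1 = np.column_stack([C, score])
    b1, cov1, conv1, div1 = _irls(X1, y, beta0=np.append(b0, 0.0))
    if not (conv0 and conv1) or div1:
        return PRSEvaluation("nagelkerke", np.nan, np.nan, n, converged=False)
    ll0 = _loglik(y, C @ b0)
    ll1 = _loglik(y, X1 @ b1)
    num = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    den = 1.0 - np.exp(2.0 * ll0 / n)
    r2 = float(num / den) if den > 0 else np.nan
    se = np.sqrt(cov1[-1, -1])
    p = float(sps.chi2.sf((b1[-1] / se) ** 2, 1)) if se > 0 else np.nan
    return PRSEvaluation("nagelkerke", max(r2, 0.0), p, n)


def incremental_r2(y: np.ndarray, score: np.ndarray, covariates=None) -> PRSEvaluation:
    """Partial (incremental) R^2 of the score over covariates for quantitative y."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, float)]
    )
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    s_r = score - Q @ (Q.T @ score)
    ss = float(s_r @ s_r)
    rss0 = float(y_r @ y_r)
    if ss == 0 or rss0 == 0:
        return PRSEvaluation("ordinary", 0.0, 1.0, n)
    beta = float(s_r @ y_r) / ss
    rss1 = rss0 - beta**2 * ss
    dof = n - C.shape[1] - 1
    sigma2 = rss1 / max(dof, 1)
    se = np.sqrt(sigma2 / ss)
    p = float(sps.chi2.sf((beta / se) ** 2, 1)) if se > 0 else np.nan
    return PRSEvaluation("ordinary", max(1.0 - rss1 / rss0, 0.0), p, n)


def _evaluate(y, score, covariates, kind):
    if kind == BINARY:
        return nagelkerke_r2(y, score, covariates)
    return incremental_r2(y, score, covariates)


# ----------------------------------------------------------------------
# joint cross-validation


def _train_stats(phenome, panel_tr, train_idx, target, method, config, seed):
    """GWAS summary statistics for the target computed on training samples only."""
    j = phenome.col_index(target)
    kind = phenome.col_types[j]
    sub = Phenome(
        phenome.values[train_idx],
        phenome.mask[train_idx],
        list(phenome.col_types),
        list(phenome.col_names),
        [phenome.sample_ids[i] for i in train_idx],
    )
    cov = config.covariates[train_idx] if config.covariates is not None else None

    if method == "observed":
        rows = np.where(sub.mask[:, j])[0]
        y = sub.values[rows, j]
        pan = panel_tr.subset_samples(rows)
        cov_o = cov[rows] if cov is not None else None
        if kind == BINARY:
            return logistic_scan(pan, y, cov_o, trait_label=target)
        return linear_scan(pan, y, cov_o, trait_label=target)

    if method in ("imp_only", "imp_all"):
        grid = _impute.default_lambda_grid(sub, n_points=config.lambda_grid_points)
        _, _, fit = _impute.select_lambda(
            sub, grid=grid, max_rank=config.max_rank,
            tol=config.softimpute_tol, seed=seed,
        )
        if method == "imp_all":
            vals, _ = _impute.impute_values(fit, sub, "imp_all")
            y = vals[:, j]
            return linear_scan(panel_tr, y, cov, trait_label=f"{target}:imp_all")
        pred, rows = _impute.impute_values(fit, sub, "imp_only", target=target)
        pan = panel_tr.subset_samples(rows)
        cov_o = cov[rows] if cov is not None else None
        return linear_scan(pan, pred, cov_o, trait_label=f"{target}:imp_only")

    if method == "mtag":
        # linear scans on observed values of target + configured inputs
        inputs = [target] + list(config.mtag_inputs)
        stats_list = []
        for nm in inputs:
            jj = sub.col_index(nm)
            rows = np.where(sub.mask[:, jj])[0]
            pan = panel_tr.subset_samples(rows)
            cov_o = cov[rows] if cov is not None else None
            stats_list.append(linear_scan(pan, sub.values[rows, jj], cov_o, trait_label=nm))
        scores = compute_ld_scores(panel_tr)
        omega, sigma = _mtag.estimate_omega_sigma(stats_list, scores)
        res = _mtag.mtag_combine(stats_list, omega, sigma)
        return res.adjusted[target]

    raise ValueError(f"unknown method {method!r}")


def crossval_pipeline(phenome: Phenome, panel: GenotypePanel, target: str,
                      method: str = "observed", config: PRSConfig | None = None):
    """Joint k-fold cross-validation of imputation -> GWAS -> PRS.

    Folds partition the samples; for each fold, every data-dependent step
    (imputation and its penalty selection, secondary GWAS, multi-trait
    combination, clumping, threshold selection) sees only the 90% training
    samples, and the held-out 10% are scored with the frozen model.  Returns
    (per-fold evaluations, summary dict with mean r2 and a cross-fold 95%
    CI ``mean +- 1.96 * sd / sqrt(folds)``).
    """
    if config is None:
        config = PRSConfig()
    folds = config.folds
    if folds < 2:
        raise ValueError("need at least 2 folds")
    n = phenome.n_samples
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f in range(folds):
        fold_of[perm[f::folds]] = f
    j = phenome.col_index(target)
    kind = phenome.col_types[j]

    evals = []
    for f in range(folds):
        test_idx = np.where(fold_of == f)[0]
        train_idx = np.where(fold_of != f)[0]
        assert len(np.intersect1d(test_idx, train_idx)) == 0, "fold leakage"
        panel_tr = panel.subset_samples(train_idx)
        stats = _train_stats(phenome, panel_tr, train_idx, target, method,
                             config, seed=config.seed * 1000 + f)
        retained = clump(stats, panel_tr, config.clump_r2, config.clump_window_bp)

        # threshold selection on training observed target only
        tr_obs = train_idx[phenome.mask[train_idx, j]]
        cov_tr = config.covariates[tr_obs] if config.covariates is not None else None
        best = None
        for thr in config.p_grid:
            sc_all, model = build_and_score(stats, retained, thr, panel)
            if len(model.weights) == 0:
                continue
            ev = _evaluate(phenome.values[tr_obs, j], sc_all[tr_obs], cov_tr, kind)
            if np.isnan(ev.r2):
                continue
            if best is None or ev.r2 > best[0]:
                best = (ev.r2, thr, sc_all, model)
        if best is None:
            evals.append(PRSEvaluation("nagelkerke" if kind == BINARY else "ordinary",
                                       np.nan, n=0, target_label=target,
                                       converged=False))
            continue
        _, thr, sc_all, model = best
        te_obs = test_idx[phenome.mask[test_idx, j]]
        cov_te = config.covariates[te_obs] if config.covariates is not None else None
        ev = _evaluate(phenome.values[te_obs, j], sc_all[te_obs], cov_te, kind)
        ev.target_label = target
        evals.append(ev)

    r2s = np.array([e.r2 for e in evals if np.isfinite(e.r2)])
    if len(r2s):
        mean = float(r2s.mean())
        half = 1.96 * r2s.std(ddof=1) / np.sqrt(len(r2s)) if len(r2s) > 1 else np.nan
        summary = {"mean_r2": mean, "ci": (mean - half, mean + half),
                   "folds": folds, "method": method}
    else:
        summary = {"mean_r2": np.nan, "ci": (np.nan, np.nan),
                   "folds": folds, "method": method}
    return evals, summary


# ----------------------------------------------------------------------
# pleiotropy


def pleiotropy_spectrum(scores: np.ndarray, phenome: Phenome, target: str,
                        covariates=None, alpha_family: int | None = None,
                        secondary: list | None = None) -> PleiotropySpectrum:
    """Per-secondary-phenotype prediction R^2 relative to the target.

    ``ratio = r2_secondary / r2_target`` (PRS pleiotropy); significance of
    the score term at the family-corrected level 0.05/m.  Secondary
    phenotypes are evaluated on their observed samples with the
    type-appropriate incremental metric.
    """
    jt = phenome.col_index(target)
    rows_t = np.where(phenome.mask[:, jt])[0]
    cov_t = covariates[rows_t] if covariates is not None else None
    ev_t = _evaluate(phenome.values[rows_t, jt], scores[rows_t], cov_t,
                     phenome.col_types[jt])
    if not np.isfinite(ev_t.r2) or ev_t.r2 <= 0:
        raise ValueError("target r2 is zero or undefined; spectrum not defined")

    if secondary is None:
        secondary = [nm for nm in phenome.col_names if nm != target]
    m = alpha_family if alpha_family is not None else len(secondary)
    rows = []
    for nm in secondary:
        jj = phenome.col_index(nm)
        obs = np.where(phenome.mask[:, jj])[0]
        if len(obs) < 10 or np.std(phenome.values[obs, jj]) == 0:
            continue
        cov_o = covariates[obs] if covariates is not None else None
        ev = _evaluate(phenome.values[obs, jj], scores[obs], cov_o,
                       phenome.col_types[jj])
        ratio = 1.0 if nm == target else ev.r2 / ev_t.r2
        rows.append({
            "phenotype": nm,
            "r2_secondary": ev.r2,
            "ratio": ratio,
            "p_score": ev.p_score,
            "significant": bool(np.isfinite(ev.p_score) and ev.p_score < 0.05 / m),
        })
    table = pd.DataFrame(rows)
    table["excess"] = np.nan
    return PleiotropySpectrum(table, target, ev_t.r2)


def excess_pleiotropy(spectrum: PleiotropySpectrum,
                      baseline: PleiotropySpectrum) -> PleiotropySpectrum:
    """Excess PRS pleiotropy: spectrum ratio minus baseline ratio per phenotype."""
    a = spectrum.table.set_index("phenotype")
    b = baseline.table.set_index("phenotype")
    diff = set(a.index).symmetric_difference(b.index)
    if diff:
        raise ValueError(f"phenotype labels differ between spectra: {sorted(diff)}")
    out = a.copy()
    out["excess"] = a["ratio"] - b.loc[a.index, "ratio"]
    return PleiotropySpectrum(out.reset_index(), spectrum.target, spectrum.r2_target)
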
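"""Synthetic biobank generator with known ground truth.

Every downstream stage (imputation, GWAS, LD score regression, MTAG-style
combination, PRS) is exercised against data from this module, where the
generating model — causal SNP effects, latent factors, liability thresholds
and block missingness — is fully known.

The generating model
--------------------
Genotypes are drawn per LD block from a haplotype-copying Markov chain: the
allele at SNP j of a haplotype copies SNP j-1 with probability ``ld_decay``
and is otherwise redrawn from Bernoulli(p_block).  With a shared per-block
allele frequency this yields dosage autocorrelation exactly
``ld_decay ** lag`` within a block and independence across blocks, i.e. an
AR(1) LD profile with a closed-form LD score.

Each phenotype's liability is a sum of variance-1 components::

    L_p = g_p + sum_k lambda_pk * F_k + w_p * L_target + e_p

where g_p is a direct genetic score over ``n_causal`` causal SNPs rescaled
in-sample to the target heritability, F_k are latent factors (optionally
heritable through their own causal SNPs), w_p is an optional "shallow proxy"
mixture weight on the deep target's liability, and e_p absorbs the remaining
variance.  Binary phenotypes threshold the liability at its empirical
1 - K quantile, so the case fraction matches the prevalence K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .phenome import BINARY, QUANTITATIVE, GenotypePanel, Phenome

__all__ = [
    "MissingBlock",
    "SimConfig",
    "TruthSet",
    "simulate_genotypes",
    "simulate_phenome",
    "apply_missingness",
    "biobank_config",
    "simulate_biobank",
]

_BLOCK_GAP_BP = 2_000_000
_SNP_SPACING_BP = 1_000


@dataclass(frozen=True)
class MissingBlock:
    """A questionnaire-style block of phenotypes that goes missing jointly.

    ``fraction`` of samples lose *all* phenotypes in the block (all-or-none
    per sample).  If ``depends_on`` names a phenotype, the per-sample
    missingness probability is logistic in that (standardized) covariate
    with the given slope, with the intercept solved so the expected missing
    fraction is preserved.
    """

    phenotypes: tuple
    fraction: float
    depends_on: str | None = None
    slope: float = 1.0


@dataclass
class SimConfig:
    """Declarative description of one synthetic biobank."""

    n_samples: int
    n_snps: int
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 20
    ld_decay: float = 0.9
    # phenome structure -------------------------------------------------
    col_names: list = field(default_factory=list)
    col_types: list = field(default_factory=list)          # binary|quantitative
    h2_targets: np.ndarray = None                          # per-phenotype direct h2
    prevalences: dict = field(default_factory=dict)        # binary name -> K
    n_causal: np.ndarray = None                            # per-phenotype lead-SNP count
    h2_poly: np.ndarray = None                             # per-phenotype polygenic-tail h2
    n_factors: int = 0
    factor_loadings: np.ndarray = None                     # (p, k), sd units
    factor_h2: np.ndarray = None                           # per-factor lead h2 of F_k
    factor_n_causal: np.ndarray = None
    factor_h2_poly: np.ndarray = None                      # per-factor polygenic-tail h2
    n_poly: int = 300                                      # tail size (SNPs)
    proxy_mix: dict = field(default_factory=dict)          # name -> (source, w)
    missing_blocks: list = field(default_factory=list)
    seed: int = 0

    @property
    def n_phenotypes(self) -> int:
        return len(self.col_names)

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo < hi <= 0.5, got {self.maf_range}")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.n_samples < 2 or self.n_snps < 1:
            raise ValueError("need n_samples >= 2 and n_snps >= 1")
        p = self.n_phenotypes
        if p:
            if self.h2_targets is None or len(self.h2_targets) != p:
                raise ValueError("h2_targets must be given per phenotype")
            if np.any((np.asarray(self.h2_targets) < 0) | (np.asarray(self.h2_targets) > 1)):
                raise ValueError("h2 targets must lie in [0, 1]")
            for name, K in self.prevalences.items():
                if not (0 < K < 1):
                    raise ValueError(f"prevalence of {name!r} must lie in (0, 1)")
            if self.factor_loadings is not None:
                lam = np.asarray(self.factor_loadings, float)
                if lam.shape != (p, self.n_factors):
                    raise ValueError("factor_loadings must be (n_phenotypes, n_factors)")
                if not np.all(np.isfinite(lam)):
                    raise ValueError("factor_loadings must be finite")
        for mb in self.missing_blocks:
            if not (0 <= mb.fraction <= 1):
                raise ValueError("missing fraction must lie in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth of one simulated phenome.

    ``beta_true`` holds the *total* marginal effect of each standardized SNP
    on each liability (direct effects plus effects inherited through
    heritable factors and proxy mixtures); ``causal_sets`` records which SNPs
    were drawn as direct/factor causal sets; ``achievable_r2`` is the
    in-sample OLS R^2 of each phenotype on all other phenotypes, an upper
    bound oracle for imputation accuracy.
    """

    beta_true: np.ndarray            # (n_snps, n_phenotypes), standardized scale
    liabilities: np.ndarray          # (n_samples, n_phenotypes)
    factor_scores_true: np.ndarray   # (n_samples, n_factors)
    achievable_r2: np.ndarray        # (n_phenotypes,)
    genetic_component: np.ndarray    # (n_samples, n_phenotypes) direct g_p
    causal_sets: dict                # name -> index array (direct sets; "factor:k" for factors)


# ----------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Draw an LD-blocked dosage panel.

    Haplotype-copying chain per block: allele j copies allele j-1 with
    probability ``ld_decay``, else is a fresh Bernoulli(p_block) draw; the
    dosage is the sum of two independent haplotypes, giving Hardy–Weinberg
    genotypes with dosage correlation ``ld_decay ** lag`` within a block.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m, L = config.n_samples, config.n_snps, config.ld_block_size
    if L < 1:
        raise ValueError("ld_block_size must be >= 1")
    n_blocks = int(np.ceil(m / L))
    lo, hi = config.maf_range
    block_freqs = rng.uniform(lo, hi, size=n_blocks)

    dosages = np.empty((n, m), dtype=np.float32)
    block_id = np.empty(m, dtype=int)
    bp = np.empty(m, dtype=int)
    rho = config.ld_decay
    col = 0
    for b in range(n_blocks):
        size = min(L, m - col)
        p = block_freqs[b]
        hap = rng.random((n, 2)) < p
        for j in range(size):
            if j > 0:
                copy = rng.random((n, 2)) < rho
                fresh = rng.random((n, 2)) < p
                hap = np.where(copy, hap, fresh)
            dosages[:, col + j] = hap.sum(axis=1)
            bp[col + j] = b * _BLOCK_GAP_BP + 1 + j * _SNP_SPACING_BP
        block_id[col : col + size] = b
        col += size

    emp_freq = dosages.mean(axis=0) / 2.0
    # keep frequencies strictly inside (0,1); monomorphic draws are jittered
    emp_freq = np.clip(emp_freq, 0.5 / (2 * n), 1 - 0.5 / (2 * n))
    alleles = np.array(list("ACGT"))
    a1 = alleles[rng.integers(0, 4, size=m)]
    shift = rng.integers(1, 4, size=m)
    a2 = alleles[(np.searchsorted(alleles, a1) + shift) % 4]
    snp_map = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(m)],
            "chr": "1",
            "bp": bp,
            "a1": a1,
            "a2": a2,
            "freq": emp_freq,
        }
    )
    return GenotypePanel(dosages, snp_map, block_id, [f"S{i}" for i in range(n)])


# ----------------------------------------------------------------------
# phenome


def _scale_to_var(x: np.ndarray, var: float) -> np.ndarray:
    """Rescale a centered vector to exact in-sample variance ``var``."""
    x = x - x.mean()
    s = x.std()
    if s == 0:
        if var > 0:
            raise ValueError("cannot scale a constant vector to positive variance")
        return x
    return x * (np.sqrt(var) / s)


def simulate_phenome(panel: GenotypePanel, config: SimConfig) -> tuple[Phenome, TruthSet]:
    """Generate liabilities, threshold binaries, and record the ground truth.

    Components are rescaled in-sample so each phenotype's liability has
    variance exactly 1 and the direct genetic share exactly ``h2_targets``.
    Proxy phenotypes listed in ``config.proxy_mix`` additionally receive a
    ``w * L_source`` liability component (shallow-measure construction).
    """
    config.validate()
    p = config.n_phenotypes
    if p == 0:
        raise ValueError("config describes no phenotypes")
    n, m = panel.n_samples, panel.n_snps
    k = config.n_factors
    rng = np.random.default_rng(config.seed + 1)
    Gs = panel.standardized()

    lam = (
        np.asarray(config.factor_loadings, float)
        if config.factor_loadings is not None
        else np.zeros((p, max(k, 1)))[:, :k]
    )
    fh2 = np.asarray(config.factor_h2, float) if config.factor_h2 is not None else np.zeros(k)
    fnc = (
        np.asarray(config.factor_n_causal, int)
        if config.factor_n_causal is not None
        else np.full(k, 0)
    )
    fh2_poly = (
        np.asarray(config.factor_h2_poly, float)
        if config.factor_h2_poly is not None
        else np.zeros(k)
    )
    h2 = np.asarray(config.h2_targets, float)
    h2_poly = (
        np.asarray(config.h2_poly, float) if config.h2_poly is not None else np.zeros(p)
    )
    ncausal = np.asarray(config.n_causal, int) if config.n_causal is not None else np.zeros(p, int)

    need = int(fnc[fh2 > 0].sum() + ncausal[h2 > 0].sum()) if k or p else 0
    if need > m:
        raise ValueError(f"not enough SNPs for disjoint causal sets ({need} needed, {m} available)")
    pool = rng.permutation(m)
    pool_pos = 0

    def draw_causal(count):
        nonlocal pool_pos
        idx = np.sort(pool[pool_pos : pool_pos + count])
        pool_pos += count
        return idx

    causal_sets: dict = {}
    beta_std = np.zeros((m, p))          # total marginal standardized effects
    factor_beta = np.zeros((m, k))

    def draw_tail():
        """Polygenic-tail SNPs: anywhere outside the disjoint lead pool."""
        remaining = pool[need:]
        n_tail = min(config.n_poly, len(remaining))
        if n_tail == 0:
            raise ValueError("no SNPs left for a polygenic tail")
        return np.sort(rng.choice(remaining, size=n_tail, replace=False))

    def genetic_tiers(h2_lead, n_lead, h2_tail, record):
        """Lead + polygenic-tail genetic score, each tier rescaled exactly."""
        g = np.zeros(n)
        lead_idx = np.array([], dtype=int)
        if h2_lead > 0 and n_lead > 0:
            lead_idx = draw_causal(int(n_lead))
            b = rng.standard_normal(len(lead_idx))
            raw = Gs[:, lead_idx] @ b
            g = g + _scale_to_var(raw, h2_lead)
            record(lead_idx, b * (np.sqrt(h2_lead) / raw.std()))
        if h2_tail > 0:
            tail_idx = draw_tail()
            b = rng.standard_normal(len(tail_idx))
            raw = Gs[:, tail_idx] @ b
            g = g + _scale_to_var(raw, h2_tail)
            record(tail_idx, b * (np.sqrt(h2_tail) / raw.std()))
        return g, lead_idx

    # latent factors, optionally heritable
    Z = np.empty((n, k))
    for j in range(k):
        h2_f = fh2[j] + fh2_poly[j]
        if h2_f > 0:
            def rec(idx, b, j=j):
                factor_beta[idx, j] += b
            g, lead_idx = genetic_tiers(fh2[j], fnc[j], fh2_poly[j], rec)
            causal_sets[f"factor:{j}"] = lead_idx
            noise = _scale_to_var(rng.standard_normal(n), 1 - h2_f)
            Z[:, j] = g + noise
        else:
            Z[:, j] = _scale_to_var(rng.standard_normal(n), 1.0)

    liab = np.zeros((n, p))
    genetic = np.zeros((n, p))
    values = np.zeros((n, p))

    # order so that proxy sources are generated before their dependents
    order = list(range(p))
    name_to_idx = {nm: i for i, nm in enumerate(config.col_names)}
    dependents = {name_to_idx[nm]: config.proxy_mix[nm] for nm in config.proxy_mix}
    for i in dependents:
        src = name_to_idx[dependents[i][0]]
        if order.index(src) > order.index(i):
            order.remove(i)
            order.append(i)

    for i in order:
        name = config.col_names[i]
        lam_i = lam[i] if k else np.zeros(0)
        w = 0.0
        src = None
        if i in dependents:
            src_name, w = dependents[i]
            src = name_to_idx[src_name]
        var_fac = float(np.sum(lam_i**2))
        h2_direct = h2[i] + h2_poly[i]
        var_noise = 1.0 - h2_direct - var_fac - w**2
        if var_noise < -1e-12:
            raise ValueError(
                f"phenotype {name!r}: h2 + factor + proxy variance shares exceed 1"
            )
        var_noise = max(var_noise, 0.0)

        if h2_direct > 0:
            def rec(idx, b, i=i):
                beta_std[idx, i] += b
            g, lead_idx = genetic_tiers(h2[i], ncausal[i], h2_poly[i], rec)
            causal_sets[name] = lead_idx
        else:
            g = np.zeros(n)
            causal_sets[name] = np.array([], dtype=int)

        fac = Z @ lam_i if k else 0.0
        beta_std[:, i] += factor_beta @ lam_i if k else 0.0
        noise = _scale_to_var(rng.standard_normal(n), var_noise) if var_noise > 0 else 0.0
        L = g + fac + noise
        if w:
            L = L + w * liab[:, src]
            beta_std[:, i] += w * beta_std[:, src]
        liab[:, i] = L
        genetic[:, i] = g

        if config.col_types[i] == BINARY:
            K = config.prevalences.get(name)
            if K is None:
                raise ValueError(f"binary phenotype {name!r} has no prevalence")
            thr = np.quantile(L, 1 - K)
            values[:, i] = (L > thr).astype(float)
        else:
            values[:, i] = L

    # Achievable imputation R^2: in-sample OLS of each phenotype on the
    # phenotypes that can co-occur with it when it is missing.  Columns in a
    # shared missing block are excluded — they are never observed for the
    # samples whose entry needs imputing.
    comiss = {i: {i} for i in range(p)}
    for mb in config.missing_blocks:
        idxs = [name_to_idx[nm] for nm in mb.phenotypes if nm in name_to_idx]
        for i in idxs:
            comiss.setdefault(i, {i}).update(idxs)
    achievable = np.empty(p)
    X = values - values.mean(axis=0)
    for i in range(p):
        keep = [j for j in range(p) if j not in comiss[i]]
        others = X[:, keep]
        coef, *_ = np.linalg.lstsq(others, X[:, i], rcond=None)
        pred = others @ coef
        denom = np.var(X[:, i])
        achievable[i] = 0.0 if denom == 0 else float(np.var(pred) / denom)

    phen = Phenome(
        values,
        np.ones_like(values, dtype=bool),
        list(config.col_types),
        list(config.col_names),
        list(panel.sample_ids),
    )
    truth = TruthSet(beta_std, liab, Z, achievable, genetic, causal_sets)
    return phen, truth


def apply_missingness(phenome: Phenome, config: SimConfig) -> Phenome:
    """Apply questionnaire-block missingness.

    For each :class:`MissingBlock`, the listed phenotypes are set missing
    *jointly* for the sampled individuals (all-or-none per sample).  With a
    ``depends_on`` covariate the per-sample probability is logistic in that
    covariate, calibrated to preserve the expected missing fraction.
    Observed values are never altered.
    """
    out = phenome.copy()
    rng = np.random.default_rng(config.seed + 2)
    for mb in config.missing_blocks:
        cols = [out.col_index(nm) for nm in mb.phenotypes]
        n = out.n_samples
        if mb.fraction == 0:
            continue
        if mb.depends_on is not None:
            cov, cov_mask = out.column(mb.depends_on)
            if not cov_mask.all():
                raise ValueError("missingness covariate must be fully observed")
            z = (cov - cov.mean()) / (cov.std() or 1.0)
            if mb.fraction >= 1:
                prob = np.ones(n)
            else:
                def mean_prob(a):
                    return expit(a + mb.slope * z).mean() - mb.fraction

                a0 = brentq(mean_prob, -50, 50)
                prob = expit(a0 + mb.slope * z)
            rows = rng.random(n) < prob
        else:
            rows = rng.random(n) < mb.fraction
        for j in cols:
            out.mask[rows, j] = False
    return out


# ----------------------------------------------------------------------
# the standard synthetic depression biobank


def biobank_config(
    n_samples: int = 10_000,
    n_snps: int = 2_000,
    seed: int = 0,
    target_missing: float = 0.8,
    ld_decay: float = 0.9,
    shallow_w: float = 0.5,
) -> SimConfig:
    """The study-condition biobank used throughout the analyses and tests.

    One deep binary target (prevalence 0.25, direct h2 0.25 over 8 causal
    SNPs, loading on a heritable "help-seeking" factor F1 and a mildly
    heritable "SES" factor F2) sits in an 80%-missing questionnaire block
    together with four symptom items.  Five fully observed shallow proxies
    mix the target liability (w ~ 0.5) with F1; 21 background phenome
    columns load on F1-F3.  F3 is a purely environmental factor.
    """
    names: list = []
    types: list = []
    h2: list = []
    h2p: list = []
    nc: list = []
    prev: dict = {}
    load: list = []
    proxy_mix: dict = {}

    def add(name, kind, h2_i, nc_i, lam, K=None, mix=None, h2_poly=0.0):
        names.append(name)
        types.append(kind)
        h2.append(h2_i)
        h2p.append(h2_poly)
        nc.append(nc_i)
        load.append(lam)
        if K is not None:
            prev[name] = K
        if mix is not None:
            proxy_mix[name] = mix

    # deep target: 3 lead loci (h2 0.15) + polygenic tail (h2 0.10)
    add("target", BINARY, 0.15, 3, (0.35, 0.20, 0.0), K=0.25, h2_poly=0.10)
    for s in range(4):
        add(f"symptom{s + 1}", BINARY, 0.0, 0, (0.15, 0.0, 0.0), K=0.30,
            mix=("target", 0.70))
    proxy_specs = [
        ("proxy_shallow", BINARY, 0.35, (0.60, 0.0, 0.0), 0.50),
        ("proxy_selfrep", BINARY, 0.30, (0.45, 0.0, 0.0), 0.55),
        ("proxy_gp", BINARY, 0.40, (0.50, 0.10, 0.0), 0.45),
        ("proxy_score", QUANTITATIVE, None, (0.40, 0.0, 0.0), 0.50),
        ("proxy_mood", QUANTITATIVE, None, (0.35, 0.15, 0.0), 0.50),
    ]
    for nm, kind, K, lam, w in proxy_specs:
        add(nm, kind, 0.0, 0, lam, K=K, mix=("target", shallow_w if nm == "proxy_shallow" else w))
    rng = np.random.default_rng(seed + 99)
    for f in range(3):
        for j in range(7):
            lam = [0.0, 0.0, 0.0]
            lam[f] = float(rng.uniform(0.5, 0.75))
            kind = BINARY if (f == 0 and j < 2) else QUANTITATIVE
            K = 0.2 if kind == BINARY else None
            add(f"pheno_f{f + 1}_{j + 1}", kind, 0.0, 0, tuple(lam), K=K)

    missing = [
        MissingBlock(("target", "symptom1", "symptom2", "symptom3", "symptom4"),
                     target_missing),
        MissingBlock(tuple(f"pheno_f3_{j + 1}" for j in range(7)), 0.3),
    ]
    return SimConfig(
        n_samples=n_samples,
        n_snps=n_snps,
        maf_range=(0.05, 0.5),
        ld_block_size=20,
        ld_decay=ld_decay,
        col_names=names,
        col_types=types,
        h2_targets=np.array(h2),
        prevalences=prev,
        n_causal=np.array(nc),
        h2_poly=np.array(h2p),
        n_factors=3,
        factor_loadings=np.array(load, float),
        factor_h2=np.array([0.20, 0.15, 0.0]),
        factor_n_causal=np.array([5, 4, 0]),
        factor_h2_poly=np.array([0.20, 0.15, 0.0]),
        n_poly=300,
        proxy_mix=proxy_mix,
        missing_blocks=missing,
        seed=seed,
    )


def simulate_biobank(config: SimConfig):
    """Convenience: genotypes + full phenome + masked phenome + truth."""
    panel = simulate_genotypes(config)
    full, truth = simulate_phenome(panel, config)
    observed = apply_missingness(full, config)
    return panel, full, observed, truth
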
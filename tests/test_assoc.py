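"""Association scans against textbook oracles, loci, heterogeneity, PCs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenolink import assoc
from phenolink.assoc import (
    FLAG_DEGENERATE,
    FLAG_MONOMORPHIC,
    SummaryStats,
    define_loci,
    genomic_inflation,
    heterogeneity_meta,
    linear_scan,
    logistic_scan,
    replication_check,
    compute_pcs,
)
from phenolink.phenome import GenotypePanel
from phenolink.simulate import SimConfig, simulate_genotypes


def _panel_from_dosages(D, bp=None, chrom=None):
    D = np.asarray(D, float)
    n, m = D.shape
    snp_map = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(m)],
        "chr": chrom if chrom is not None else ["1"] * m,
        "bp": bp if bp is not None else (np.arange(m) + 1) * 1000,
        "a1": ["A"] * m,
        "a2": ["G"] * m,
        "freq": np.clip(D.mean(axis=0) / 2, 0.01, 0.99),
    })
    return GenotypePanel(D, snp_map, np.zeros(m, int))


def _stats_from(beta, se, bp=None, chrom=None, n=1000, snp=None):
    m = len(beta)
    t = pd.DataFrame({
        "SNP": snp if snp is not None else [f"rs{i}" for i in range(m)],
        "CHR": chrom if chrom is not None else ["1"] * m,
        "BP": bp if bp is not None else (np.arange(m) + 1) * 1000,
        "A1": ["A"] * m, "A2": ["G"] * m, "FRQ": [0.3] * m,
        "BETA": beta, "SE": se,
        "P": sps.chi2.sf((np.asarray(beta) / np.asarray(se)) ** 2, 1),
        "N": [n] * m, "TEST": ["linear"] * m,
    })
    return SummaryStats(t)


class TestLinearScan:
    def test_y_in_covariate_span_gives_null_betas(self, tiny_panel, rng):
        cov = rng.standard_normal(tiny_panel.n_samples)
        st = linear_scan(tiny_panel, cov, covariates=cov)
        ok = st.ok
        assert np.all(np.abs(ok["BETA"]) < 1e-8)

    def test_perfect_fit_flagged_degenerate(self):
        D = np.array([[0.0], [1.0], [2.0], [1.0], [0.0]])
        panel = _panel_from_dosages(D)
        y = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        st = linear_scan(panel, y)
        row = st.table.iloc[0]
        assert row["FLAG"] == FLAG_DEGENERATE
        # the point estimate before flagging was the exact slope 1.0
        assert not np.isfinite(row["BETA"])  # flagged -> no estimate reported

    def test_monomorphic_flagged(self, rng):
        D = np.column_stack([np.ones(50) * 2, rng.integers(0, 3, 50)])
        panel = _panel_from_dosages(D)
        st = linear_scan(panel, rng.standard_normal(50))
        assert st.table["FLAG"].iloc[0] == FLAG_MONOMORPHIC

    def test_matches_statsmodels_ols(self, tiny_panel, rng):
        import statsmodels.api as sm

        n = tiny_panel.n_samples
        cov = rng.standard_normal((n, 2))
        y = rng.standard_normal(n)
        st = linear_scan(tiny_panel, y, covariates=cov)
        for j in [0, 7, 23, 39]:
            X = sm.add_constant(np.column_stack([cov, tiny_panel.dosages[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert st.table["BETA"].iloc[j] == pytest.approx(fit.params[-1], abs=1e-6)
            assert st.table["SE"].iloc[j] == pytest.approx(fit.bse[-1], abs=1e-6)

    def test_rank_deficient_covariates_named(self, tiny_panel, rng):
        c = rng.standard_normal(tiny_panel.n_samples)
        with pytest.raises(ValueError, match="collinear"):
            linear_scan(tiny_panel, c, covariates=np.column_stack([c, c]))


class TestLogisticScan:
    def test_matches_statsmodels_logit(self, rng):
        import statsmodels.api as sm

        cfg = SimConfig(n_samples=400, n_snps=50, seed=21)
        panel = simulate_genotypes(cfg)
        cov = rng.standard_normal((400, 2))
        lin = 0.3 * cov[:, 0] + 0.2 * panel.standardized()[:, 0]
        y = (rng.random(400) < 1 / (1 + np.exp(-lin))).astype(float)
        st = logistic_scan(panel, y, covariates=cov)
        for j in range(0, 50, 7):
            if st.table["FLAG"].iloc[j] != "OK":
                continue
            X = sm.add_constant(np.column_stack([cov, panel.dosages[:, j]]))
            fit = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10)
            assert st.table["BETA"].iloc[j] == pytest.approx(fit.params[-1], abs=1e-6)
            assert st.table["SE"].iloc[j] == pytest.approx(fit.bse[-1], abs=1e-6)

    def test_separation_flagged(self):
        D = np.array([[0.0], [0.0], [0.0], [2.0], [2.0], [2.0]] * 5)
        panel = _panel_from_dosages(D)
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0] * 5)
        st = logistic_scan(panel, y)
        assert st.table["FLAG"].iloc[0] in ("SEPARATION", "NOCONV")
        assert not np.isfinite(st.table["BETA"].iloc[0])

    def test_single_class_rejected(self, tiny_panel):
        with pytest.raises(ValueError, match="both classes"):
            logistic_scan(tiny_panel, np.zeros(tiny_panel.n_samples))


class TestGenomicInflation:
    def test_reference_median_gives_unity(self):
        chi = np.full(101, assoc.CHI2_MEDIAN_1DF)
        st = _stats_from(np.sqrt(chi), np.ones(101))
        assert genomic_inflation(st) == pytest.approx(1.0)

    def test_scale_equivariance(self, rng):
        z = rng.standard_normal(501)
        st1 = _stats_from(z, np.ones(501))
        st2 = _stats_from(np.sqrt(2) * z, np.ones(501))
        assert genomic_inflation(st2) == pytest.approx(2 * genomic_inflation(st1))


class TestLoci:
    def _sig_stats(self, bps, ps, chrom=None):
        m = len(bps)
        z = np.sqrt(sps.chi2.isf(ps, 1))
        return _stats_from(z, np.ones(m), bp=bps, chrom=chrom)

    def test_merge_within_window(self):
        st = self._sig_stats([1_000_000, 1_200_000], [1e-9, 1e-10])
        loci = define_loci(st, merge_window=500_000)
        assert len(loci) == 1
        assert loci.loci.iloc[0]["lead_snp"] == "rs1"  # smaller p wins

    def test_separate_beyond_window(self):
        st = self._sig_stats([1_000_000, 3_000_000], [1e-9, 1e-9])
        assert len(define_loci(st, merge_window=500_000)) == 2

    def test_no_significant_snps(self):
        st = self._sig_stats([1_000_000], [1e-3])
        assert len(define_loci(st)) == 0

    def test_tie_breaks_to_smaller_bp(self):
        st = self._sig_stats([100, 200], [1e-9, 1e-9])
        loci = define_loci(st, merge_window=1000)
        assert loci.loci.iloc[0]["lead_snp"] == "rs0"


class TestHeterogeneity:
    def test_identical_effects_q_zero(self):
        a = _stats_from([0.2, 0.1], [0.05, 0.05])
        b = _stats_from([0.2, 0.1], [0.05, 0.05])
        out = heterogeneity_meta([a, b]).set_index("SNP")
        assert out.loc["rs0", "Q"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["rs0", "p_het"] == pytest.approx(1.0)

    def test_closed_form_two_studies(self):
        a = _stats_from([0.1], [0.1])
        b = _stats_from([0.3], [0.1])
        out = heterogeneity_meta([a, b]).iloc[0]
        assert out["beta_fe"] == pytest.approx(0.2)
        assert out["Q"] == pytest.approx(2.0)
        assert out["p_het"] == pytest.approx(0.1573, abs=1e-4)
        # DerSimonian-Laird: tau2 = (2-1)/(200-100) = 0.01
        w = 1 / (0.01 + 0.01)
        assert out["beta_re"] == pytest.approx(0.2)
        assert out["se_re"] == pytest.approx(np.sqrt(1 / (2 * w)))

    def test_single_study_snp_passed_through(self):
        a = _stats_from([0.1, 0.2], [0.1, 0.1])
        b = _stats_from([0.1], [0.1], snp=["rs0"])
        out = heterogeneity_meta([a, b]).set_index("SNP")
        assert out.loc["rs1", "FLAG"] == "SINGLE_STUDY"


class TestReplication:
    def _discovery(self):
        st = _stats_from([0.3], [0.03], bp=[1_000_000])
        return define_loci(st), st

    def test_sign_consistency_and_allele_flip(self):
        loci, disc = self._discovery()
        rep = _stats_from([0.2], [0.05], bp=[1_000_000])
        flipped = rep.table.copy()
        flipped["A1"], flipped["A2"] = "G", "A"
        flipped["BETA"] = -0.2
        rep_fl = SummaryStats(flipped, "flipped")
        out = replication_check(loci, disc, [rep, rep_fl], alpha_family=23)
        assert out["sign_consistent"].all()
        assert out["replicated"].all()  # p(0.2/0.05) << 0.05/23

    def test_bonferroni_threshold_arithmetic(self):
        loci, disc = self._discovery()
        z = np.sqrt(sps.chi2.isf(0.01, 1))
        rep = _stats_from([z * 0.1], [0.1], bp=[1_000_000])  # p = 0.01
        out = replication_check(loci, disc, [rep], alpha_family=23)
        assert not out["replicated"].iloc[0]  # 0.01 > 0.05/23

    def test_unalignable_alleles_excluded(self):
        loci, disc = self._discovery()
        bad = _stats_from([0.2], [0.05], bp=[1_000_000]).table.copy()
        bad["A1"], bad["A2"] = "C", "T"
        out = replication_check(loci, disc, [SummaryStats(bad)], alpha_family=23)
        assert out["note"].iloc[0] == "unalignable"


class TestPCs:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(3)
        n, m = 1000, 300
        f1 = rng.uniform(0.1, 0.9, m)
        shift = rng.uniform(-0.3, 0.3, m)
        f2 = np.clip(f1 + shift, 0.05, 0.95)
        D = np.vstack([
            rng.binomial(2, f1, size=(n // 2, m)),
            rng.binomial(2, f2, size=(n // 2, m)),
        ]).astype(float)
        panel = _panel_from_dosages(D)
        pcs = compute_pcs(panel, 2, seed=0)
        labels = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        r = np.corrcoef(pcs[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_gram_matrix_diagonal(self, tiny_panel):
        pcs = compute_pcs(tiny_panel, 4, seed=1)
        G = pcs.T @ pcs
        off = G - np.diag(np.diag(G))
        assert np.all(np.abs(off) < 1e-8 * np.abs(np.diag(G)).max())

    def test_k_zero_and_k_too_large(self, tiny_panel):
        assert compute_pcs(tiny_panel, 0).shape == (tiny_panel.n_samples, 0)
        with pytest.raises(ValueError):
            compute_pcs(tiny_panel, 10_000)
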
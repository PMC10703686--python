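"""Config-driven orchestration of the full phenotype-integration workflow.

Ties the stages together in dependency order — simulate, impute, GWAS,
LD score regression, multi-trait combination, PRS/pleiotropy — writing
every table as TSV plus a JSON manifest (seeds, stage list, digests) so a
run is reproducible from its config alone.  ``validate_io`` is the strict
schema checker for the file formats the stages exchange.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import impute as _impute
from . import prs as _prs
from .assoc import define_loci, genomic_inflation, linear_scan, logistic_scan
from .factors import factor_scores, prediction_strength, variance_explained
from .ldsc import compute_ld_scores, estimate_h2, estimate_rg, liability_transform
from .phenome import BINARY
from .simulate import biobank_config, simulate_biobank

__all__ = ["RunConfig", "run_pipeline", "validate_io"]

ALL_STAGES = ("simulate", "impute", "factors", "gwas", "ldsc", "prs")


@dataclass
class RunConfig:
    """Everything one run needs; round-trips losslessly through YAML."""

    out_dir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    n_samples: int = 4000
    n_snps: int = 800
    target: str = "target"
    folds: int = 5
    n_factors_report: int = 6
    prs_methods: tuple = ("observed", "imp_all")
    mtag_inputs: tuple = ("proxy_shallow", "proxy_selfrep", "proxy_gp")

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("stages", "prs_methods", "mtag_inputs"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the report bundle.

    Tables land under ``config.out_dir`` and a manifest records seeds,
    stage timings and output digests.  Identical configs produce
    byte-identical numeric tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    report: dict = {}
    timings: dict = {}
    artifacts: dict = {}

    def done(stage, *paths):
        for p in paths:
            artifacts[str(p.name)] = _digest(p)

    if "simulate" not in stages:
        raise ValueError("run the 'simulate' stage first: later stages need its outputs")

    t0 = time.time()
    sim_cfg = biobank_config(config.n_samples, config.n_snps, seed=config.seed)
    panel, full, observed, truth = simulate_biobank(sim_cfg)
    _io.write_phenome(observed, out / "phenome.tsv", out / "phenome_types.tsv")
    _io.write_dosage_matrix(panel, out / "dosages.tsv", out / "snp_map.tsv")
    done("simulate", out / "phenome.tsv", out / "snp_map.tsv")
    timings["simulate"] = time.time() - t0
    report["simulate"] = {"n_samples": panel.n_samples, "n_snps": panel.n_snps,
                          "n_phenotypes": observed.n_phenotypes}

    fit = None
    accuracy = None
    if "impute" in stages:
        t0 = time.time()
        grid = _impute.default_lambda_grid(observed, n_points=8)
        lam, accuracy, fit = _impute.select_lambda(observed, grid=grid,
                                                   seed=config.seed)
        acc = pd.DataFrame({
            "phenotype": accuracy.col_names,
            "n_obs": accuracy.n_obs.astype(int),
            "n_miss": accuracy.n_miss.astype(int),
            "r2": accuracy.r2,
            "n_eff": accuracy.n_eff,
        })
        acc.to_csv(out / "imputation_accuracy.tsv", sep="\t", index=False)
        timings["impute"] = time.time() - t0
        report["impute"] = {"lambda": lam,
                            "target_r2": accuracy.for_phenotype(config.target)["r2"],
                            "target_n_eff": accuracy.for_phenotype(config.target)["n_eff"]}

    if "factors" in stages:
        if fit is None:
            raise ValueError("stage 'factors' needs stage 'impute' first")
        t0 = time.time()
        k = min(config.n_factors_report, fit.rank)
        ve = variance_explained(fit)[:k]
        ps = prediction_strength(observed, k, seed=config.seed, lam=fit.lam)
        pd.DataFrame({"factor": np.arange(1, k + 1), "var_explained": ve,
                      "prediction_strength": ps[:k]}).to_csv(
            out / "factor_diagnostics.tsv", sep="\t", index=False)
        scores = factor_scores(fit, k)
        pd.DataFrame(scores, index=observed.sample_ids,
                     columns=[f"factor{i + 1}" for i in range(k)]).to_csv(
            out / "factor_scores.tsv", sep="\t")
        timings["factors"] = time.time() - t0
        report["factors"] = {"k": k, "var_explained": ve.tolist()}

    scans: dict = {}
    if "gwas" in stages:
        t0 = time.time()
        j = observed.col_index(config.target)
        rows = np.where(observed.mask[:, j])[0]
        y = observed.values[rows, j]
        if observed.col_types[j] == BINARY:
            scans["observed"] = logistic_scan(panel.subset_samples(rows), y,
                                              trait_label=config.target)
        else:
            scans["observed"] = linear_scan(panel.subset_samples(rows), y,
                                            trait_label=config.target)
        if fit is not None:
            vals, _ = _impute.impute_values(fit, observed, "imp_all")
            scans["imp_all"] = linear_scan(panel, vals[:, j],
                                           trait_label=f"{config.target}:imp_all")
            pred, miss_rows = _impute.impute_values(fit, observed, "imp_only",
                                                    target=config.target)
            scans["imp_only"] = linear_scan(panel.subset_samples(miss_rows), pred,
                                            trait_label=f"{config.target}:imp_only")
        gwas_summary = []
        for name, st in scans.items():
            _io.write_sumstats(st, out / f"gwas_{name}.tsv")
            loci = define_loci(st)
            gwas_summary.append({"scan": name, "lambda_gc": genomic_inflation(st),
                                 "n_loci": len(loci), "n": int(st.ok["N"].median())})
        pd.DataFrame(gwas_summary).to_csv(out / "gwas_summary.tsv", sep="\t", index=False)
        timings["gwas"] = time.time() - t0
        report["gwas"] = gwas_summary

    if "ldsc" in stages:
        if not scans:
            raise ValueError("stage 'ldsc' needs stage 'gwas' first")
        t0 = time.time()
        scores_ld = compute_ld_scores(panel)
        rows_out = []
        for name, st in scans.items():
            est = estimate_h2(st, scores_ld)
            h2_liab = None
            jt = observed.col_index(config.target)
            if name == "observed" and observed.col_types[jt] == BINARY:
                K = float(full.values[:, jt].mean())
                P = float(observed.values[observed.mask[:, jt], jt].mean())
                h2_liab = liability_transform(est.h2_obs, K, P)
            rows_out.append({"scan": name, "h2_obs": est.h2_obs, "h2_se": est.h2_se,
                             "intercept": est.intercept, "h2_liab": h2_liab})
        if "observed" in scans and "imp_only" in scans:
            rg = estimate_rg(scans["imp_only"], scans["observed"], scores_ld)
            report["rg_imp_obs"] = {"rg": rg.rg, "se": rg.se}
        pd.DataFrame(rows_out).to_csv(out / "heritability.tsv", sep="\t", index=False)
        timings["ldsc"] = time.time() - t0
        report["ldsc"] = rows_out

    if "prs" in stages:
        t0 = time.time()
        prs_rows = []
        for method in config.prs_methods:
            cfg = _prs.PRSConfig(folds=config.folds, seed=config.seed,
                                 mtag_inputs=config.mtag_inputs)
            _, summary = _prs.crossval_pipeline(observed, panel, config.target,
                                                method=method, config=cfg)
            prs_rows.append({"method": method, **{k: v for k, v in summary.items()
                                                  if k != "method"}})
        pd.DataFrame(prs_rows).to_csv(out / "prs_accuracy.tsv", sep="\t", index=False)
        timings["prs"] = time.time() - t0
        report["prs"] = prs_rows

    manifest = {
        "seed": config.seed,
        "stages": stages,
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    config.to_yaml(out / "run_config.yaml")
    return report


# ----------------------------------------------------------------------
# validation


def validate_io(path, fmt: str):
    """Strict schema check; raises ValueError listing every problem found.

    Formats: phenome | vcf | sumstats | scores.  For VCF, a file without a
    DS field falls back to GT-derived dosages with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    errors: list = []
    if fmt == "phenome":
        obj = _io.read_phenome(path)
        if obj.n_phenotypes == 0:
            errors.append("phenome has no phenotype columns")
        for j in range(obj.n_phenotypes):
            if obj.mask[:, j].sum() == 0:
                errors.append(f"column {obj.col_names[j]!r}: no observed entries")
    elif fmt == "vcf":
        obj, used_ds = _io.read_vcf(path)
        if not used_ds:
            warnings.warn("VCF has no DS field; dosages derived from GT")
    elif fmt == "sumstats":
        df = pd.read_csv(path, sep="\t")
        from .assoc import SUMSTATS_COLUMNS

        for c in SUMSTATS_COLUMNS:
            if c not in df.columns:
                errors.append(f"missing column {c!r}")
        if not errors:
            for col in ("A1", "A2"):
                bad = ~df[col].astype(str).str.fullmatch("[ACGT]+")
                for i in df.index[bad]:
                    errors.append(f"line {i + 2}, column {col}: non-ACGT allele {df.loc[i, col]!r}")
            bad_se = df["SE"].notna() & (df["SE"] <= 0)
            for i in df.index[bad_se]:
                errors.append(f"line {i + 2}, column SE: must be > 0")
            obj = _io.read_sumstats(path)
        else:
            obj = None
    elif fmt == "scores":
        obj = _io.read_scores(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if errors:
        raise ValueError("; ".join(errors))
    return obj
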
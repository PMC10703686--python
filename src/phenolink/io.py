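"""Readers and writers for the pipeline's file formats.

Phenome: TSV with a header row of phenotype names, first column the sample
ID, literal ``NA`` for missing entries.  Genotypes: VCF 4.2 with a DS
(dosage) FORMAT field, or a dosage-matrix TSV plus a map TSV.  Summary
statistics: columnar TSV with exactly SNP CHR BP A1 A2 FRQ BETA SE P N
TEST.  Scoring files: SNP, effect allele, weight.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import SUMSTATS_COLUMNS, SummaryStats
from .impute import ImputationFit
from .phenome import BINARY, MAP_COLUMNS, QUANTITATIVE, GenotypePanel, Phenome

__all__ = [
    "write_phenome",
    "read_phenome",
    "write_vcf",
    "read_vcf",
    "write_dosage_matrix",
    "read_dosage_matrix",
    "write_sumstats",
    "read_sumstats",
    "write_scores",
    "read_scores",
    "save_fit",
    "load_fit",
]

NA = "NA"


def write_phenome(phenome: Phenome, path, types_path=None) -> None:
    df = phenome.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep=NA)
    if types_path is not None:
        pd.DataFrame({"phenotype": phenome.col_names, "type": phenome.col_types}).to_csv(
            types_path, sep="\t", index=False
        )


def read_phenome(path, types_path=None, col_types=None) -> Phenome:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA], keep_default_na=False)
    values = df.to_numpy(dtype=float)
    mask = np.isfinite(values)
    values = np.where(mask, values, 0.0)
    if types_path is not None:
        tdf = pd.read_csv(types_path, sep="\t").set_index("phenotype")
        col_types = [tdf.loc[c, "type"] for c in df.columns]
    elif col_types is None:
        # infer: observed values all in {0,1} -> binary
        col_types = []
        for j in range(values.shape[1]):
            obs = values[mask[:, j], j]
            col_types.append(BINARY if np.isin(obs, [0.0, 1.0]).all() and len(obs) else QUANTITATIVE)
    return Phenome(values, mask, col_types, list(df.columns), [str(s) for s in df.index])


# ----------------------------------------------------------------------
# genotypes


def write_vcf(panel: GenotypePanel, path) -> None:
    """Plain-text VCF 4.2 with GT (rounded) and DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for c in pd.unique(panel.snp_map["chr"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.sample_ids) + "\n")
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        D = panel.dosages
        for j, row in panel.snp_map.iterrows():
            # a1 (effect/dosage-counted allele) is written as ALT
            fields = [str(row["chr"]), str(row["bp"]), row["snp"], row["a2"],
                      row["a1"], ".", "PASS", ".", "GT:DS"]
            ds = D[:, j]
            cells = [f"{gts[int(round(d))]}:{d:.3f}" for d in ds]
            fh.write("\t".join(fields + cells) + "\n")


def read_vcf(path, block_size: int = 20):
    """Read a dosage VCF via cyvcf2; falls back to GT-derived dosages.

    Returns (GenotypePanel, used_ds: bool).  Block ids are assigned by
    contiguous runs of ``block_size`` SNPs per chromosome (annotation only).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    used_ds = True
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).ravel()
        else:
            used_ds = False
            gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,3 hom-alt
            d = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, np.where(gt == 0, 0.0, np.nan)))
        dosages.append(d)
        alt = var.ALT[0] if var.ALT else "N"
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, alt, var.REF))
    D = np.array(dosages).T
    freq = D.mean(axis=0) / 2.0
    n = D.shape[0]
    freq = np.clip(freq, 0.5 / (2 * n), 1 - 0.5 / (2 * n))
    snp_map = pd.DataFrame(rows, columns=["snp", "chr", "bp", "a1", "a2"])
    snp_map["freq"] = freq
    block = np.arange(D.shape[1]) // block_size
    return GenotypePanel(D, snp_map[MAP_COLUMNS], block, samples), used_ds


def write_dosage_matrix(panel: GenotypePanel, dosage_path, map_path) -> None:
    df = pd.DataFrame(panel.dosages, index=panel.sample_ids,
                      columns=panel.snp_map["snp"])
    df.index.name = "sample_id"
    df.to_csv(dosage_path, sep="\t", float_format="%.3f")
    m = panel.snp_map.copy()
    m["block_id"] = panel.block_id
    m.to_csv(map_path, sep="\t", index=False)


def read_dosage_matrix(dosage_path, map_path) -> GenotypePanel:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0)
    m = pd.read_csv(map_path, sep="\t")
    block = m.pop("block_id").to_numpy() if "block_id" in m else np.zeros(len(m), int)
    return GenotypePanel(df.to_numpy(dtype=float), m[MAP_COLUMNS], block,
                         [str(s) for s in df.index])


# ----------------------------------------------------------------------
# summary statistics & scores


def write_sumstats(stats: SummaryStats, path) -> None:
    stats.table[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path, trait_label: str = "") -> SummaryStats:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats file {path} missing columns: {missing}")
    return SummaryStats(df, trait_label)


def write_scores(weights: pd.DataFrame, path) -> None:
    weights[["SNP", "A1", "weight"]].to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"SNP", "A1", "weight"}
    if not need.issubset(df.columns):
        raise ValueError(f"scoring file {path} must have columns {sorted(need)}")
    return df


# ----------------------------------------------------------------------
# imputation fit


def save_fit(fit: ImputationFit, prefix) -> None:
    """Portable array container (.npz) plus a JSON manifest."""
    prefix = Path(prefix)
    np.savez(prefix.with_suffix(".npz"), U=fit.U, d=fit.d, V=fit.V,
             col_center=fit.col_center, col_scale=fit.col_scale)
    manifest = {
        "lambda": fit.lam,
        "col_names": fit.col_names,
        "converged": bool(fit.converged),
        "objective_trace": [float(x) for x in fit.objective_trace],
        "total_obs_variance": fit.total_obs_variance,
    }
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_fit(prefix) -> ImputationFit:
    prefix = Path(prefix)
    arrs = np.load(prefix.with_suffix(".npz"))
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    return ImputationFit(
        arrs["U"], arrs["d"], arrs["V"], manifest["lambda"],
        arrs["col_center"], arrs["col_scale"], manifest["objective_trace"],
        manifest["converged"], manifest["col_names"],
        manifest.get("total_obs_variance", 0.0),
    )
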
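"""Core in-memory containers shared by every stage of the pipeline.

A :class:`Phenome` is the samples x phenotypes matrix that gets imputed;
a :class:`GenotypePanel` is the samples x SNPs dosage matrix that the
association scans, LD scores and polygenic scores run over.  Both are thin
wrappers around numpy arrays plus pandas metadata so that every stage can
pass them around without re-parsing files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BINARY = "binary"
QUANTITATIVE = "quantitative"

MAP_COLUMNS = ["snp", "chr", "bp", "a1", "a2", "freq"]


@dataclass
class Phenome:
    """Partially observed phenotype matrix.

    Parameters
    ----------
    values : (n_samples, n_phenotypes) float array
        Phenotype values.  Entries where ``mask`` is False carry no
        information: any stored value there is ignored by every consumer.
    mask : bool array, same shape
        True where the entry is observed.
    col_types : list of {"binary", "quantitative"}
    col_names : list of str
    sample_ids : list of str
    """

    values: np.ndarray
    mask: np.ndarray
    col_types: list
    col_names: list
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have the same shape")
        n, p = self.values.shape
        if not (len(self.col_types) == len(self.col_names) == p):
            raise ValueError("column metadata does not match value matrix")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids does not match value matrix")
        bad = set(self.col_types) - {BINARY, QUANTITATIVE}
        if bad:
            raise ValueError(f"unknown column types: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    def col_index(self, name: str) -> int:
        try:
            return self.col_names.index(name)
        except ValueError:
            raise KeyError(f"phenotype {name!r} not in phenome") from None

    def column(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, mask) for one phenotype."""
        j = self.col_index(name)
        return self.values[:, j], self.mask[:, j]

    def copy(self) -> "Phenome":
        return Phenome(
            self.values.copy(),
            self.mask.copy(),
            list(self.col_types),
            list(self.col_names),
            list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        """Observed values as a DataFrame with NaN at missing entries."""
        vals = np.where(self.mask, self.values, np.nan)
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.col_names)


@dataclass
class GenotypePanel:
    """Dosage matrix plus SNP map and LD-block annotation.

    ``dosages`` holds effect-allele (a1) dosages in [0, 2]; ``snp_map`` is a
    DataFrame with columns snp, chr, bp, a1, a2, freq (a1 frequency); and
    ``block_id`` labels the LD block each SNP belongs to.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    block_id: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        n, m = self.dosages.shape
        if list(self.snp_map.columns[: len(MAP_COLUMNS)]) != MAP_COLUMNS:
            raise ValueError(f"snp map must start with columns {MAP_COLUMNS}")
        if len(self.snp_map) != m:
            raise ValueError("snp map length does not match dosage matrix")
        self.block_id = np.asarray(self.block_id)
        if self.block_id.shape != (m,):
            raise ValueError("block_id length does not match dosage matrix")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids does not match dosage matrix")
        freq = self.snp_map["freq"].to_numpy()
        if np.any((freq <= 0) | (freq >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        for _, sub in self.snp_map.groupby("chr", sort=False):
            bp = sub["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError("bp must be strictly increasing within a chromosome")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (float64). Zero-variance SNPs -> 0."""
        d = self.dosages.astype(float)
        mu = d.mean(axis=0)
        sd = d.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        out = (d - mu) / sd_safe
        out[:, sd == 0] = 0.0
        return out

    def subset_samples(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            self.dosages[idx],
            self.snp_map.copy(),
            self.block_id.copy(),
            [self.sample_ids[i] for i in idx],
        )
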
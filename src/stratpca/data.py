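"""Core in-memory containers for genotype matrices and their maps.

A :class:`GenotypeMatrix` holds an N samples x P SNPs matrix of allele-dosage
values coded ``{0, 1, 2}`` with ``-1`` for missing, together with a SNP map
(id, chromosome, 1-based position, alleles) and a sample table (id, site,
case/control status).  Dosage counts copies of the *second* allele column
(``allele2``), matching PLINK's additive coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SNP_COLUMNS = ["id", "chromosome", "position", "allele1", "allele2"]
SAMPLE_COLUMNS = ["id", "site", "status"]


class FormatError(ValueError):
    """Raised when an on-disk genotype file violates its format."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus SNP map and sample metadata.

    Parameters
    ----------
    dosages
        ``int8`` array of shape (n_samples, n_snps); values in {0,1,2,-1}.
    snps
        DataFrame with columns ``id, chromosome, position, allele1, allele2``.
    samples
        DataFrame with at least column ``id``; typically also ``site`` and
        ``status`` ("case"/"control").
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x snps)")
        n, p = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"sample table has {len(self.samples)} rows for {n} samples")
        if len(self.snps) != p:
            raise ValueError(f"SNP map has {len(self.snps)} rows for {p} SNPs")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2,-1}")
        if self.snps["id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if self.samples["id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["id"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["id"].to_numpy()

    # -- derived quantities ------------------------------------------------
    def allele_freqs(self) -> np.ndarray:
        """Observed frequency of allele2 per SNP, ignoring missing calls."""
        d = self.dosages
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(obs, d, 0).sum(axis=0) / (2.0 * n_obs)
        return freq

    def missing_rate(self) -> float:
        return float((self.dosages == MISSING).mean())

    # -- subsetting --------------------------------------------------------
    def subset_samples(self, mask_or_ids) -> "GenotypeMatrix":
        idx = self._sample_indexer(mask_or_ids)
        return GenotypeMatrix(
            self.dosages[idx, :].copy(),
            self.snps.copy(),
            self.samples.iloc[idx].reset_index(drop=True),
        )

    def subset_snps(self, mask_or_ids) -> "GenotypeMatrix":
        idx = self._snp_indexer(mask_or_ids)
        return GenotypeMatrix(
            self.dosages[:, idx].copy(),
            self.snps.iloc[idx].reset_index(drop=True),
            self.samples.copy(),
        )

    def _sample_indexer(self, mask_or_ids) -> np.ndarray:
        return _indexer(mask_or_ids, self.sample_ids, "sample")

    def _snp_indexer(self, mask_or_ids) -> np.ndarray:
        return _indexer(mask_or_ids, self.snp_ids, "SNP")

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.snps.copy(), self.samples.copy())

    def status_vector(self) -> np.ndarray:
        """0/1 vector (control=0, case=1) from the sample table."""
        status = self.samples["status"].to_numpy()
        bad = set(np.unique(status)) - {"case", "control"}
        if bad:
            raise ValueError(f"status values outside {{case, control}}: {sorted(bad)}")
        return (status == "case").astype(np.int64)


def _indexer(mask_or_ids, universe: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.shape != universe.shape:
            raise ValueError(f"boolean {what} mask has wrong length")
        return np.flatnonzero(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr
    pos = pd.Index(universe).get_indexer(arr)
    if (pos < 0).any():
        missing = arr[pos < 0][:5]
        raise KeyError(f"unknown {what} ids: {list(missing)}")
    return pos
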
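"""Genotype and metadata I/O: PLINK .bed/.bim/.fam, VCF 4.2 and sample TSVs.

The PLINK binary codec is implemented bit-exactly from the 2-bit SNP-major
specification.  Dosage counts copies of the BIM file's *second* allele column
(A2), i.e. code ``00`` (homozygous allele1) decodes to dosage 0, ``10``
(heterozygous) to 1, ``11`` (homozygous allele2) to 2 and ``01`` to missing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, FormatError, GenotypeMatrix

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit code -> dosage (count of allele2)
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}

# byte-value lookup: 256 x 4 table of decoded dosages, lowest bit pair first
_BYTE_LUT = np.zeros((256, 4), dtype=np.int8)
for _b in range(256):
    for _i in range(4):
        _BYTE_LUT[_b, _i] = _CODE_TO_DOSAGE[(_b >> (2 * _i)) & 0b11]


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam fileset into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    fam = _read_fam(prefix.with_suffix(".fam"))
    bim = _read_bim(prefix.with_suffix(".bim"))
    n, p = len(fam), len(bim)
    payload = prefix.with_suffix(".bed").read_bytes()
    if len(payload) < 3 or payload[:2] != _BED_MAGIC:
        raise FormatError("not a PLINK BED file (bad magic bytes)")
    if payload[2] != _BED_SNP_MAJOR:
        raise FormatError(f"unsupported BED mode byte 0x{payload[2]:02x}; need SNP-major 0x01")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * p
    if len(payload) != expected:
        raise FormatError(
            f"BED payload is {len(payload)} bytes; expected {expected} for {n} samples x {p} SNPs"
        )
    raw = np.frombuffer(payload, dtype=np.uint8, offset=3).reshape(p, bytes_per_snp)
    decoded = _BYTE_LUT[raw].reshape(p, bytes_per_snp * 4)[:, :n]  # (P, N)
    return GenotypeMatrix(np.ascontiguousarray(decoded.T), bim, fam)


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK .bed/.bim/.fam fileset (SNP-major, zero padding bits)."""
    if genotypes.n_samples == 0 or genotypes.n_snps == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    if genotypes.snps[["allele1", "allele2"]].isna().any().any():
        raise ValueError("SNP records must carry both alleles")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = genotypes.n_samples, genotypes.n_snps
    bytes_per_snp = (n + 3) // 4
    codes = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    dos = genotypes.dosages.T  # (P, N)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[:, :n][dos == dosage] = code
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (codes.reshape(p, bytes_per_snp, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())
    _write_bim(genotypes.snps, prefix.with_suffix(".bim"))
    _write_fam(genotypes.samples, prefix.with_suffix(".fam"))


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chromosome", "id", "cm", "position", "allele1", "allele2"],
        dtype={"chromosome": str, "id": str, "allele1": str, "allele2": str},
    )
    return bim[["id", "chromosome", "position", "allele1", "allele2"]]


def _write_bim(snps: pd.DataFrame, path: Path) -> None:
    out = snps[["chromosome", "id"]].copy()
    out["cm"] = 0
    out["position"] = snps["position"]
    out["allele1"] = snps["allele1"]
    out["allele2"] = snps["allele2"]
    out.to_csv(path, sep="\t", header=False, index=False)


_STATUS_TO_PHENO = {"control": 1, "case": 2}
_PHENO_TO_STATUS = {1: "control", 2: "case"}


def _read_fam(path: Path) -> pd.DataFrame:
    fam = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["fid", "id", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "id": str},
    )
    out = pd.DataFrame({"id": fam["id"], "site": fam["fid"]})
    out["status"] = fam["pheno"].map(_PHENO_TO_STATUS)
    return out


def _write_fam(samples: pd.DataFrame, path: Path) -> None:
    fid = samples["site"] if "site" in samples else samples["id"]
    pheno = (
        samples["status"].map(_STATUS_TO_PHENO).fillna(-9).astype(int)
        if "status" in samples
        else pd.Series(-9, index=samples.index)
    )
    out = pd.DataFrame(
        {"fid": fid, "id": samples["id"], "pat": 0, "mat": 0, "sex": 0, "pheno": pheno}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic GT records from a VCF; dosage = ALT allele count.

    Multiallelic records are skipped (counted in a log message); ``./.`` maps
    to missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise FormatError("VCF has no sample columns (GT field required)")
    rows, records = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dos = np.select([gts == 0, gts == 1, gts == 3], [0, 1, 2], default=MISSING)
        rows.append(dos.astype(np.int8))
        records.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), var.POS,
                        var.REF, var.ALT[0]))
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic VCF records", n_multi)
    if not rows:
        raise FormatError("no biallelic GT records found in VCF")
    snps = pd.DataFrame(records, columns=["id", "chromosome", "position", "allele1", "allele2"])
    samples = pd.DataFrame({"id": sample_ids})
    return GenotypeMatrix(np.asarray(rows, dtype=np.int8).T, snps, samples)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF 4.2 with GT-only genotype columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in genotypes.snps["chromosome"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.sample_ids) + "\n")
        for j, snp in enumerate(genotypes.snps.itertuples(index=False)):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in genotypes.dosages[:, j])
            fh.write(
                f"{snp.chromosome}\t{snp.position}\t{snp.id}\t{snp.allele1}\t"
                f"{snp.allele2}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path, genotypes: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Read a sample metadata TSV (``sample_id``, ``site``, ``status``).

    If ``genotypes`` is given, rows are aligned to its sample order; metadata
    rows for unknown samples are dropped with a warning and genotyped samples
    without metadata raise.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "site", "status"}
    if not required.issubset(meta.columns):
        raise FormatError(f"metadata must have columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    bad = set(meta["status"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"status values outside {{case, control}}: {sorted(bad)}")
    meta = meta.rename(columns={"sample_id": "id"})
    if genotypes is not None:
        ids = pd.Index(genotypes.sample_ids)
        extra = meta.loc[~meta["id"].isin(ids), "id"]
        if len(extra):
            logger.warning("excluding %d metadata rows with no genotypes", len(extra))
        meta = meta.set_index("id")
        unmatched = ids.difference(meta.index)
        if len(unmatched):
            raise ValueError(f"genotyped samples missing from metadata: {list(unmatched[:5])}")
        meta = meta.loc[ids].rename_axis("id").reset_index()
    return meta


def write_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.rename(columns={"id": "sample_id"})
    cols = [c for c in ["sample_id", "site", "status"] if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)
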
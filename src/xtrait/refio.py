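"""Reading reference genotypes for LD estimation.

Three input forms are supported: VCF (through cyvcf2), PLINK1
.bed/.bim/.fam triples, and plain tab-delimited dosage matrices
(samples x SNPs with a header row of SNP ids).  All return an
:class:`~xtrait.sumstats.LDReference` via :func:`~xtrait.sumstats.ld_matrix`.

The .bed decoder is a direct implementation of the 2-bit SNP-major PLINK
code (00=hom A1 -> dosage 2 of allele 1, 01=missing, 10=het, 11=hom A2).
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .sumstats import LDReference, ld_matrix

_PLINK_MAGIC = b"\x6c\x1b\x01"
# 2-bit code -> dosage of the BIM A1 allele; 1 is the missing code
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a PLINK1 .bed/.bim/.fam triple.

    Returns (dosages, bim) where dosages is (n_samples, m) counting the BIM
    A1 allele, with missing as NaN, and bim has columns chrom, snp_id, pos,
    a1, a2.
    """
    prefix = pathlib.Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _BED_DECODE[codes].T  # (n, m)
    return dosages, bim


def read_vcf_dosages(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read hard-call ALT dosages from a VCF (biallelic sites only)."""
    from cyvcf2 import VCF

    rows, dos = [], []
    for var in VCF(str(path), gts012=True):
        if len(var.ALT) != 1:
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = unknown
        gts[gts == 3] = np.nan
        dos.append(gts)
        rows.append({"chrom": str(var.CHROM), "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                     "pos": var.POS, "a1": var.ALT[0], "a2": var.REF})
    if not rows:
        raise ValueError("no biallelic variants in VCF")
    return np.asarray(dos).T, pd.DataFrame(rows)


def read_dosage_tsv(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a samples-by-SNPs tab-delimited dosage matrix (header = SNP ids)."""
    df = pd.read_csv(path, sep="\t")
    meta = pd.DataFrame({"chrom": "0", "snp_id": df.columns,
                         "pos": np.arange(1, df.shape[1] + 1),
                         "a1": "A", "a2": "G"})
    return df.to_numpy(dtype=float), meta


def load_ld_reference(path) -> LDReference:
    """Dispatch on extension: .vcf/.vcf.gz, .bed (PLINK prefix), or .tsv."""
    p = pathlib.Path(path)
    name = p.name.lower()
    if name.endswith((".vcf", ".vcf.gz")):
        X, meta = read_vcf_dosages(p)
    elif name.endswith(".bed"):
        X, meta = read_plink(p.with_suffix(""))
    else:
        X, meta = read_dosage_tsv(p)
    chroms = meta["chrom"].unique()
    chrom = str(chroms[0]) if len(chroms) == 1 else "multi"
    return ld_matrix(X, snp_ids=meta["snp_id"].to_numpy(),
                     positions=meta["pos"].to_numpy(), chrom=chrom)
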
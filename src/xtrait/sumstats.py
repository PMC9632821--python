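"""Reading, validation and harmonization of GWAS summary statistics.

Summary-statistics tables are plain :class:`pandas.DataFrame` objects with a
fixed canonical column set (``COLUMNS``): one row per SNP carrying the
effect allele (a1), the other allele (a2), the effect-allele frequency, the
log-odds effect with its standard error, the association p-value, the
case/control counts and an imputation INFO score.  Positions are 1-based
(GRCh37 in the motivating datasets); genomic intervals throughout the
package are half-open ``[start, end)``.

Harmonization aligns two tables to a common effect allele and strand so the
downstream cross-trait arithmetic (meta-analysis, LD score regression,
colocalization, conditional analysis) can treat per-SNP effects as
comparable quantities.  Palindromic (A/T, C/G) SNPs cannot be oriented by
allele labels alone; they are oriented by allele frequency when the minor
allele frequency is below an ambiguity bound, and dropped otherwise.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import CHI2_MEDIAN_1DF, beta_se_from_or_ci, log10_p_from_z

#: Canonical column order for summary-statistics tables on disk.
COLUMNS = [
    "snp_id", "chrom", "pos", "a1", "a2", "freq_a1",
    "beta", "se", "p", "n_cases", "n_controls", "info",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


@dataclasses.dataclass
class HarmonizeReport:
    """Bookkeeping for one harmonization pass."""

    n_shared: int = 0
    n_flipped: int = 0          # t2 alleles swapped: beta negated, freq complemented
    n_strand_flipped: int = 0   # t2 alleles reverse-complemented
    n_ambiguous_dropped: int = 0
    n_mismatch_dropped: int = 0


@dataclasses.dataclass
class HarmonizedPair:
    """Two summary-statistics tables restricted to shared SNPs with
    identical (a1, a2) per SNP, plus the harmonization report."""

    records_1: pd.DataFrame
    records_2: pd.DataFrame
    report: HarmonizeReport

    def __post_init__(self):
        assert len(self.records_1) == len(self.records_2)


@dataclasses.dataclass
class LDReference:
    """Per-region SNP correlation matrix from a reference cohort.

    ``R`` is symmetric with unit diagonal, rows ordered as ``snp_ids``;
    ``freqs`` are reference effect-allele frequencies.  ``n_ref`` is None
    for population (noise-free) matrices such as simulated truth.
    """

    chrom: str
    start: int
    end: int
    snp_ids: np.ndarray
    positions: np.ndarray
    R: np.ndarray
    freqs: np.ndarray
    n_ref: int | None = None
    zero_variance: np.ndarray | None = None

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.R = np.asarray(self.R, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        m = len(self.snp_ids)
        if self.R.shape != (m, m):
            raise ValueError("R shape does not match snp_ids")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be symmetric")

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask_or_idx) -> "LDReference":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return LDReference(
            chrom=self.chrom, start=self.start, end=self.end,
            snp_ids=self.snp_ids[idx], positions=self.positions[idx],
            R=self.R[np.ix_(idx, idx)], freqs=self.freqs[idx],
            n_ref=self.n_ref,
        )


class LDPanel:
    """An ordered collection of independent LD blocks spanning the genome.

    Blocks are mutually uncorrelated by construction; a genome of B blocks
    of size m is represented in O(B m^2) memory instead of a dense
    (Bm)^2 matrix.
    """

    def __init__(self, blocks: Sequence[LDReference], n_ref: int | None = None):
        self.blocks = list(blocks)
        self.n_ref = n_ref

    @property
    def m(self) -> int:
        return sum(b.m for b in self.blocks)

    @property
    def snp_ids(self) -> np.ndarray:
        return np.concatenate([b.snp_ids for b in self.blocks])

    @property
    def positions(self) -> np.ndarray:
        return np.concatenate([b.positions for b in self.blocks])

    @property
    def freqs(self) -> np.ndarray:
        return np.concatenate([b.freqs for b in self.blocks])

    def block_slices(self) -> list[slice]:
        out, lo = [], 0
        for b in self.blocks:
            out.append(slice(lo, lo + b.m))
            lo += b.m
        return out

    def locus(self, chrom: str, start: int, end: int) -> LDReference:
        """Dense LD matrix for SNPs with position in [start, end).

        Spanned blocks are assembled block-diagonally (cross-block LD is
        zero by construction).
        """
        parts = []
        for b in self.blocks:
            if str(b.chrom) != str(chrom):
                continue
            mask = (b.positions >= start) & (b.positions < end)
            if mask.any():
                parts.append(b.subset(mask))
        if not parts:
            raise ValueError(f"no panel SNPs in {chrom}:{start}-{end}")
        m = sum(p.m for p in parts)
        R = np.zeros((m, m))
        lo = 0
        for p in parts:
            R[lo:lo + p.m, lo:lo + p.m] = p.R
            lo += p.m
        return LDReference(
            chrom=str(chrom), start=start, end=end,
            snp_ids=np.concatenate([p.snp_ids for p in parts]),
            positions=np.concatenate([p.positions for p in parts]),
            R=R,
            freqs=np.concatenate([p.freqs for p in parts]),
            n_ref=self.n_ref,
        )


# ---------------------------------------------------------------------------
# Reading / writing


def _finish_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "info" not in df:
        df["info"] = 1.0
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for c in ("a1", "a2"):
        df[c] = df[c].astype(str).str.upper()
    for c in ("freq_a1", "beta", "se", "p", "info"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("n_cases", "n_controls"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df[COLUMNS]


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the per-record invariants; return (table, n_dropped).

    Invariants: valid distinct alleles, se > 0, freq in (0,1), p in (0,1],
    INFO in [0,1] (missing treated as 1).
    """
    df = _finish_table(df)
    ok = (
        df["a1"].isin(_VALID_ALLELES)
        & df["a2"].isin(_VALID_ALLELES)
        & (df["a1"] != df["a2"])
        & (df["se"] > 0)
        & (df["freq_a1"] > 0) & (df["freq_a1"] < 1)
        & (df["p"] > 0) & (df["p"] <= 1)
        & df["info"].fillna(1.0).between(0, 1)
        & df["beta"].notna()
    )
    out = df.loc[ok].reset_index(drop=True)
    return out, int((~ok).sum())


def read_sumstats(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file.

    ``dialect`` maps canonical column names to the file's column names and
    may additionally declare odds-ratio input::

        {"snp_id": "SNP", "p": "P", "or": "OR", "ci_low": "L95",
         "ci_high": "U95", ...}

    When ``"or"`` is declared, beta = ln(OR) and (unless an ``se`` column is
    mapped) se is recovered from the 95% CI.  Rows failing the record
    invariants are dropped; the count is stored in ``df.attrs["n_dropped"]``.

    Raises
    ------
    ValueError
        if a mandatory mapped column is missing from the file.
    """
    dialect = dict(dialect or {})
    raw = pd.read_csv(path, sep="\t", dtype={dialect.get("chrom", "chrom"): str})

    use_or = "or" in dialect
    mandatory = ["snp_id", "chrom", "pos", "a1", "a2", "freq_a1", "p"]
    mandatory += ["or", "ci_low", "ci_high"] if use_or else ["beta", "se"]
    rename = {}
    for canon in mandatory + ["n_cases", "n_controls", "info", "se"]:
        src = dialect.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in mandatory:
            raise ValueError(f"missing mandatory column '{src}' (for '{canon}')")
    df = raw.rename(columns=rename)

    if use_or:
        beta, se = beta_se_from_or_ci(df["or"], df["ci_low"], df["ci_high"])
        df["beta"] = beta
        if "se" not in df.columns:
            df["se"] = se
    for c in ("n_cases", "n_controls"):
        if c not in df.columns:
            df[c] = np.nan
    out, n_dropped = validate_sumstats(df)
    out.attrs["n_dropped"] = n_dropped
    return out


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a table in the canonical tab-delimited column order."""
    _finish_table(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization


def _revcomp_pair(a1: pd.Series, a2: pd.Series) -> tuple[pd.Series, pd.Series]:
    return a1.map(_COMPLEMENT), a2.map(_COMPLEMENT)


def harmonize_pair(
    t1: pd.DataFrame,
    t2: pd.DataFrame,
    ambiguity_maf_bound: float = 0.40,
) -> HarmonizedPair:
    """Align two validated tables to shared SNPs with a common effect allele.

    Matching is on (chrom, pos) with an snp_id fallback for SNPs whose
    positions do not co-locate.  Where t2 lists the alleles swapped, its
    beta is negated and its frequency complemented; where they match only
    under reverse complement, t2's allele labels are complemented first.
    Palindromic SNPs (A/T or C/G) are oriented by frequency when
    min(freq, 1-freq) <= ``ambiguity_maf_bound`` in both tables and dropped
    otherwise; any other allele mismatch is dropped.

    Raises
    ------
    ValueError
        if no SNP survives (empty intersection).
    """
    rep = HarmonizeReport()
    t1 = _finish_table(t1)
    t2 = _finish_table(t2)

    m = t1.merge(t2, on=["chrom", "pos"], suffixes=("_1", "_2"), how="inner")
    # snp_id fallback for rows not matched by position
    un1 = t1.loc[~t1.set_index(["chrom", "pos"]).index.isin(
        m.set_index(["chrom", "pos"]).index)]
    un2 = t2.loc[~t2.set_index(["chrom", "pos"]).index.isin(
        m.set_index(["chrom", "pos"]).index)]
    if len(un1) and len(un2):
        extra = un1.merge(un2, on="snp_id", suffixes=("_1", "_2"), how="inner")
        if len(extra):
            extra = extra.rename(columns={"chrom_1": "chrom", "pos_1": "pos"})
            extra["snp_id_1"] = extra["snp_id"]
            extra["snp_id_2"] = extra["snp_id"]
            m = pd.concat([m, extra[m.columns]], ignore_index=True)
    if m.empty:
        raise ValueError("empty SNP intersection between the two tables")

    a1_1, a2_1 = m["a1_1"], m["a2_1"]
    a1_2, a2_2 = m["a1_2"], m["a2_2"]
    rc1_2, rc2_2 = _revcomp_pair(a1_2, a2_2)

    palin = a2_1 == a1_1.map(_COMPLEMENT)  # t1 allele pair is A/T or C/G
    same = (a1_2 == a1_1) & (a2_2 == a2_1)
    swap = (a1_2 == a2_1) & (a2_2 == a1_1)
    rc_same = (rc1_2 == a1_1) & (rc2_2 == a2_1)
    rc_swap = (rc1_2 == a2_1) & (rc2_2 == a1_1)

    flip = np.zeros(len(m), dtype=bool)       # negate beta_2, complement freq_2
    strand = np.zeros(len(m), dtype=bool)     # relabel t2 alleles (bookkeeping only)
    drop_amb = np.zeros(len(m), dtype=bool)
    drop_mis = np.zeros(len(m), dtype=bool)

    np_ = ~palin
    drop_mis |= np_ & ~(same | swap | rc_same | rc_swap)
    flip |= np_ & (swap | rc_swap)
    strand |= np_ & (rc_same | rc_swap)

    # palindromic: labels are uninformative; orient by frequency
    maf1 = np.minimum(m["freq_a1_1"], 1 - m["freq_a1_1"])
    maf2 = np.minimum(m["freq_a1_2"], 1 - m["freq_a1_2"])
    pal_match = palin & (same | swap | rc_same | rc_swap)
    drop_mis |= palin & ~pal_match
    ambiguous = pal_match & ((maf1 > ambiguity_maf_bound) | (maf2 > ambiguity_maf_bound))
    drop_amb |= ambiguous
    orientable = pal_match & ~ambiguous
    freq_flip = (np.abs(m["freq_a1_1"] - m["freq_a1_2"])
                 > np.abs(m["freq_a1_1"] - (1 - m["freq_a1_2"])))
    flip |= orientable & freq_flip

    keep = ~(drop_amb | drop_mis)
    rep.n_ambiguous_dropped = int(drop_amb.sum())
    rep.n_mismatch_dropped = int(drop_mis.sum())
    rep.n_flipped = int((flip & keep).sum())
    rep.n_strand_flipped = int((strand & keep).sum())
    rep.n_shared = int(keep.sum())
    if rep.n_shared == 0:
        raise ValueError("empty SNP intersection after allele reconciliation")

    m = m.loc[keep].reset_index(drop=True)
    flip = np.asarray(flip)[np.asarray(keep)]

    def side(suffix: str) -> pd.DataFrame:
        d = pd.DataFrame({
            "snp_id": m[f"snp_id{suffix}"],
            "chrom": m["chrom"], "pos": m["pos"],
            "a1": m["a1_1"], "a2": m["a2_1"],
            "freq_a1": m[f"freq_a1{suffix}"],
            "beta": m[f"beta{suffix}"], "se": m[f"se{suffix}"],
            "p": m[f"p{suffix}"],
            "n_cases": m[f"n_cases{suffix}"], "n_controls": m[f"n_controls{suffix}"],
            "info": m[f"info{suffix}"],
        })
        return d

    r1 = side("_1")
    r2 = side("_2")
    r2.loc[flip, "beta"] = -r2.loc[flip, "beta"]
    r2.loc[flip, "freq_a1"] = 1 - r2.loc[flip, "freq_a1"]
    r2["snp_id"] = r1["snp_id"]

    order = np.lexsort((r1["pos"].to_numpy(), r1["chrom"].to_numpy()))
    r1 = r1.iloc[order].reset_index(drop=True)
    r2 = r2.iloc[order].reset_index(drop=True)
    return HarmonizedPair(records_1=r1, records_2=r2, report=rep)


# ---------------------------------------------------------------------------
# Genomic inflation


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median chi-square of the observed p-values
    over the null median (0.4549364)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def lambda_1000(lam: float, n_cases: int, n_controls: int) -> float:
    """Rescale an inflation factor to an equivalent 1,000-case /
    1,000-control study: 1 + (lambda-1) * (1/cases + 1/controls) / (2/1000)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample counts must be positive")
    return 1.0 + (lam - 1.0) * (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)


# ---------------------------------------------------------------------------
# LD from genotype dosages


def ld_matrix(
    genotypes: np.ndarray,
    snp_ids: Iterable | None = None,
    positions: Iterable | None = None,
    chrom: str = "1",
) -> LDReference:
    """Pearson LD matrix from an (n_samples, m) dosage matrix in [0, 2].

    Missing dosages (NaN) are mean-imputed per SNP.  Zero-variance SNPs get
    zero off-diagonal correlation and are flagged in ``zero_variance``.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (n_samples >= 2, m) dosage matrix")
    n, m_snp = X.shape
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X = np.where(nan_mask, np.broadcast_to(col_mean, X.shape), X)
    sd = X.std(axis=0)
    zero_var = sd == 0
    Xc = X - X.mean(axis=0)
    sd_safe = np.where(zero_var, 1.0, sd)
    Z = Xc / sd_safe
    R = (Z.T @ Z) / n
    R[zero_var, :] = 0.0
    R[:, zero_var] = 0.0
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0

    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(m_snp)]
    if positions is None:
        positions = np.arange(1, m_snp + 1)
    positions = np.asarray(positions, dtype=np.int64)
    return LDReference(
        chrom=str(chrom), start=int(positions.min()), end=int(positions.max()) + 1,
        snp_ids=np.asarray(snp_ids), positions=positions,
        R=R, freqs=col_mean / 2.0, n_ref=n,
        zero_variance=zero_var,
    )


def log10_p_column(df: pd.DataFrame) -> np.ndarray:
    """log10 p recomputed from beta/se (robust to p-column underflow)."""
    return log10_p_from_z(df["beta"].to_numpy() / df["se"].to_numpy())
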
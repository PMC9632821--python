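"""Fixed-effect inverse-variance meta-analysis across studies and traits.

Two cross-trait modes are supported: *aligned*, pooling harmonized effects
directly, and *opposing*, pooling after reversing the second trait's
direction of effect — the latter is powered to find loci where the two
traits' risk alleles are reciprocal.  Retention applies the concordance
filter (per-trait p < 0.01 and direction agreement appropriate to the
mode) before genome-wide candidate discovery, and the extended MHC region
is excluded from candidates because its long-range LD defeats locus
clustering.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import log10_p_from_z
from .sumstats import HarmonizedPair

MHC_REGION = ("6", 24_000_000, 36_000_000)  # inclusive endpoints
GW_THRESHOLD = 5e-8
LOCUS_HALF_WINDOW = 1_000_000


@dataclasses.dataclass
class CandidateLocus:
    """A clustered shared-association candidate: lead SNP and its +/-1Mb
    window (half-open)."""

    lead_snp: str
    chrom: str
    pos: int
    mode: str
    window_start: int
    window_end: int
    lead_log10_p_meta: float
    lead_log10_p_1: float
    lead_log10_p_2: float


def ivw(betas: np.ndarray, ses: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fixed-effect IVW pooling.

    ``betas``/``ses`` have shape (k_inputs, n_snps); returns
    (beta_meta, se_meta, log10_p_meta) of length n_snps.  Weights are
    1/se^2; se_meta = (sum w)^-1/2; p two-sided normal in log space.
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    ses = np.atleast_2d(np.asarray(ses, dtype=float))
    if betas.shape != ses.shape:
        raise ValueError("betas and ses must have matching shapes")
    if betas.shape[0] < 2:
        raise ValueError("need at least two inputs to pool")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses ** 2
    sw = w.sum(axis=0)
    beta_meta = (w * betas).sum(axis=0) / sw
    se_meta = 1.0 / np.sqrt(sw)
    return beta_meta, se_meta, log10_p_from_z(beta_meta / se_meta)


def ivw_meta(inputs: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Pool a list of (beta, se) pairs for a single SNP.

    Returns (beta_meta, se_meta, log10_p_meta).
    """
    betas = np.array([[b] for b, _ in inputs])
    ses = np.array([[s] for _, s in inputs])
    bm, sm, lp = ivw(betas, ses)
    return float(bm[0]), float(sm[0]), float(lp[0])


def cross_trait_meta(pair: HarmonizedPair, mode: str = "aligned") -> pd.DataFrame:
    """Per-SNP cross-trait meta-analysis of a harmonized pair.

    ``mode='opposing'`` negates trait-2 betas before pooling; the pooled
    effect is then on the trait-1-aligned scale.  Per-trait effects in the
    output keep their original harmonized signs (the concordance filter
    needs them).
    """
    if mode not in ("aligned", "opposing"):
        raise ValueError("mode must be 'aligned' or 'opposing'")
    r1, r2 = pair.records_1, pair.records_2
    b1 = r1["beta"].to_numpy()
    s1 = r1["se"].to_numpy()
    b2 = r2["beta"].to_numpy()
    s2 = r2["se"].to_numpy()
    b2_for_pool = -b2 if mode == "opposing" else b2
    beta_meta, se_meta, lp = ivw(np.vstack([b1, b2_for_pool]), np.vstack([s1, s2]))
    out = pd.DataFrame({
        "snp_id": r1["snp_id"], "chrom": r1["chrom"], "pos": r1["pos"],
        "a1": r1["a1"], "a2": r1["a2"],
        "beta_1": b1, "se_1": s1, "log10_p_1": log10_p_from_z(b1 / s1),
        "beta_2": b2, "se_2": s2, "log10_p_2": log10_p_from_z(b2 / s2),
        "beta_meta": beta_meta, "se_meta": se_meta, "log10_p_meta": lp,
        "p_meta": np.power(10.0, np.maximum(lp, -308.0)),
        "mode": mode,
    })
    return out


def opposing_meta(pair: HarmonizedPair) -> pd.DataFrame:
    """Sign-reversed cross-trait meta-analysis (trait-1-aligned scale)."""
    return cross_trait_meta(pair, mode="opposing")


def cross_trait_filter(records: pd.DataFrame, p_bound: float = 0.01,
                       mode: str | None = None) -> pd.DataFrame:
    """Apply the retention rule: per-trait p < p_bound in both traits and
    direction concordance for the mode (aligned: same signs; opposing:
    reciprocal signs).  Returns the table with a ``retained`` column."""
    mode = mode or records["mode"].iloc[0]
    lp_bound = np.log10(p_bound)
    same_dir = np.sign(records["beta_1"]) == np.sign(records["beta_2"])
    concord = same_dir if mode == "aligned" else ~same_dir
    out = records.copy()
    out["retained"] = (
        (records["log10_p_1"] < lp_bound)
        & (records["log10_p_2"] < lp_bound)
        & concord
        & (records["beta_1"] != 0) & (records["beta_2"] != 0)
    )
    return out


def find_candidates(
    retained: pd.DataFrame,
    threshold: float = GW_THRESHOLD,
    mhc: tuple[str, int, int] | None = MHC_REGION,
    half_window: int = LOCUS_HALF_WINDOW,
) -> list[CandidateLocus]:
    """Greedy +/-1Mb clustering of retained genome-wide-significant SNPs.

    SNPs inside the MHC interval (inclusive endpoints) are removed first.
    Successive minimum-p SNPs become locus leads; SNPs within the lead's
    half-open window [pos - 1Mb, pos + 1Mb) are absorbed.  Ties break on
    smaller position.
    """
    df = retained.loc[retained["retained"]].copy()
    if mhc is not None:
        chrom, lo, hi = mhc
        in_mhc = (df["chrom"].astype(str) == str(chrom)) & df["pos"].between(lo, hi)
        df = df.loc[~in_mhc]
    df = df.loc[df["log10_p_meta"] < np.log10(threshold)]
    loci: list[CandidateLocus] = []
    df = df.sort_values(["log10_p_meta", "pos"]).reset_index(drop=True)
    while len(df):
        lead = df.iloc[0]
        start = int(lead["pos"]) - half_window
        end = int(lead["pos"]) + half_window
        loci.append(CandidateLocus(
            lead_snp=str(lead["snp_id"]), chrom=str(lead["chrom"]),
            pos=int(lead["pos"]), mode=str(lead["mode"]),
            window_start=start, window_end=end,
            lead_log10_p_meta=float(lead["log10_p_meta"]),
            lead_log10_p_1=float(lead["log10_p_1"]),
            lead_log10_p_2=float(lead["log10_p_2"]),
        ))
        covered = (df["chrom"].astype(str) == str(lead["chrom"])) \
            & (df["pos"] >= start) & (df["pos"] < end)
        df = df.loc[~covered].reset_index(drop=True)
    return loci


def check_published_loci(
    published: Sequence,
    other_trait: pd.DataFrame,
    p_bound: float = 1e-5,
    half_window: int = LOCUS_HALF_WINDOW,
) -> list[dict]:
    """Check published lead SNPs for locus-wide association in the other
    trait (any SNP with p < p_bound inside the lead's half-open +/-1Mb
    window).

    ``published`` entries are snp_ids (resolved against ``other_trait``) or
    (snp_id, chrom, pos) tuples.  Unresolvable leads are skipped and
    reported with ``resolved=False``.
    """
    lp_bound = np.log10(p_bound)
    lp_other = log10_p_from_z(other_trait["beta"].to_numpy()
                              / other_trait["se"].to_numpy())
    out = []
    for entry in published:
        if isinstance(entry, str):
            hit = other_trait.loc[other_trait["snp_id"] == entry]
            if hit.empty:
                out.append({"lead_snp": entry, "resolved": False,
                            "candidate": False})
                continue
            chrom, pos = str(hit["chrom"].iloc[0]), int(hit["pos"].iloc[0])
            snp = entry
        else:
            snp, chrom, pos = str(entry[0]), str(entry[1]), int(entry[2])
        window = (other_trait["chrom"].astype(str) == chrom) \
            & (other_trait["pos"] >= pos - half_window) \
            & (other_trait["pos"] < pos + half_window)
        if not window.any():
            out.append({"lead_snp": snp, "resolved": False, "candidate": False})
            continue
        min_lp = float(lp_other[window.to_numpy()].min())
        out.append({
            "lead_snp": snp, "chrom": chrom, "pos": pos, "resolved": True,
            "min_log10_p_other": min_lp,
            "candidate": min_lp < lp_bound,
        })
    return out
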
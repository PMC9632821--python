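"""Synthetic two-trait GWAS data with LD-blocked correlation structure.

The generator emulates the data layout of a cross-trait analysis of two
case-control traits (the motivating setting is an SLE vs. severe COVID-19
comparison): an LD reference panel organised in independent AR(1) blocks,
and per-trait summary statistics whose marginal z-scores follow the
standard generative model

    z_t ~ MVN( sqrt(n_t) * R @ beta_t ,  R )

per block, with an optional cross-trait noise covariance
``n_overlap * pheno_corr / sqrt(n1 n2) * R`` for overlapping samples.
Effects are on the standardized-genotype, unit-variance-phenotype scale;
betas and SEs are back-computed via ``beta = z / sqrt(2 f (1-f) n)``.

Causal architecture is planted per SNP with one of five labels —
``none``, ``shared_aligned``, ``shared_opposing``, ``trait1_only``,
``trait2_only`` — so that alignment/opposition structure, genetic
correlation and locus topologies are known exactly.  Causal effects have
fixed magnitude (the per-trait ``effect_scale``) and random sign, with the
sign shared (aligned) or reversed (opposing) at shared SNPs; with ``c``
causal SNPs per trait of which ``s`` are shared-aligned and ``o``
shared-opposing, the true genetic correlation is exactly ``(s - o) / c``.

An individual-level route (Gaussian-copula dosages + phenotype regression)
provides an independent oracle for the summary-level mathematics.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import p_from_z
from .sumstats import COLUMNS, LDPanel, LDReference

CAUSAL_LABELS = ("none", "shared_aligned", "shared_opposing",
                 "trait1_only", "trait2_only")

# fixed substream offsets so each operation draws from its own stream
_SUB_FREQ, _SUB_EFFECT, _SUB_Z, _SUB_GENO = 0, 1, 2, 3


@dataclasses.dataclass
class ArchitectureSpec:
    """Generative settings for a two-trait synthetic cohort.

    blocks
        list of (block size, AR(1) correlation) pairs; cross-block LD is 0.
    causal_assignments
        per-SNP label among ``CAUSAL_LABELS``; length must equal the total
        SNP count.
    effect_scale
        per-trait standardized effect magnitude at causal SNPs.
    n1, n2
        per-trait effective sample sizes.
    n_overlap, pheno_corr
        shared samples and their phenotypic correlation (cross-trait noise).
    maf_range
        effect-allele frequencies drawn Uniform(low, high).
    spacing_bp
        base-pair spacing between adjacent SNPs (one synthetic chromosome).
    """

    blocks: Sequence[tuple[int, float]]
    causal_assignments: Sequence[str]
    effect_scale: tuple[float, float]
    n1: int
    n2: int
    n_overlap: int = 0
    pheno_corr: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    spacing_bp: int = 5_000
    chrom: str = "1"

    def __post_init__(self):
        self.causal_assignments = np.asarray(self.causal_assignments)
        if len(self.causal_assignments) != self.m:
            raise ValueError("causal_assignments length must equal total SNPs")
        bad = set(np.unique(self.causal_assignments)) - set(CAUSAL_LABELS)
        if bad:
            raise ValueError(f"unknown causal labels: {sorted(bad)}")
        for _, rho in self.blocks:
            if not -1 < rho < 1:
                raise ValueError("AR(1) correlation must lie in (-1, 1)")
        if self.n_overlap > min(self.n1, self.n2):
            raise ValueError("n_overlap exceeds a trait's sample size")

    @property
    def m(self) -> int:
        return int(sum(s for s, _ in self.blocks))

    def rng(self, substream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), substream])


@dataclasses.dataclass
class SyntheticCohort:
    """A generated dataset: LD panel, true effects and summary statistics."""

    ld_ref: LDPanel
    truth_beta1: np.ndarray
    truth_beta2: np.ndarray
    sumstats_1: pd.DataFrame
    sumstats_2: pd.DataFrame
    genotypes: dict | None = None  # {"X1","y1","X2","y2"} when individual-level


def assign_architecture(
    m: int,
    n_shared_aligned: int = 0,
    n_shared_opposing: int = 0,
    n_trait1_only: int = 0,
    n_trait2_only: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Random placement of causal labels over m SNPs (without replacement)."""
    total = n_shared_aligned + n_shared_opposing + n_trait1_only + n_trait2_only
    if total > m:
        raise ValueError("more causal SNPs than SNPs")
    rng = np.random.default_rng([int(seed), 99])
    idx = rng.choice(m, size=total, replace=False)
    labels = np.full(m, "none", dtype=object)
    k = 0
    for count, lab in (
        (n_shared_aligned, "shared_aligned"),
        (n_shared_opposing, "shared_opposing"),
        (n_trait1_only, "trait1_only"),
        (n_trait2_only, "trait2_only"),
    ):
        labels[idx[k:k + count]] = lab
        k += count
    return labels


def ar1_matrix(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: r(i, j) = rho^|i-j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def make_ld_blocks(spec: ArchitectureSpec) -> LDPanel:
    """Block-diagonal LD panel with AR(1) blocks and Uniform MAFs.

    Deterministic given ``spec.seed``.  The panel carries population
    (noise-free) correlations, so ``n_ref`` is None.
    """
    rng = spec.rng(_SUB_FREQ)
    freqs = rng.uniform(*spec.maf_range, size=spec.m)
    blocks, lo = [], 0
    for size, rho in spec.blocks:
        pos = (np.arange(lo, lo + size) + 1) * spec.spacing_bp
        blocks.append(LDReference(
            chrom=spec.chrom, start=int(pos[0]), end=int(pos[-1]) + 1,
            snp_ids=np.array([f"snp{j:06d}" for j in range(lo, lo + size)]),
            positions=pos,
            R=ar1_matrix(size, rho),
            freqs=freqs[lo:lo + size],
            n_ref=None,
        ))
        lo += size
    return LDPanel(blocks, n_ref=None)


def true_effects(spec: ArchitectureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Planted standardized effect vectors for the two traits.

    Magnitude is fixed at ``effect_scale`` per trait; signs are random,
    shared at ``shared_aligned`` SNPs and reversed at ``shared_opposing``.
    """
    rng = spec.rng(_SUB_EFFECT)
    labels = spec.causal_assignments
    signs = rng.choice([-1.0, 1.0], size=spec.m)
    s1, s2 = spec.effect_scale
    b1 = np.zeros(spec.m)
    b2 = np.zeros(spec.m)
    in1 = np.isin(labels, ["shared_aligned", "shared_opposing", "trait1_only"])
    in2 = np.isin(labels, ["shared_aligned", "shared_opposing", "trait2_only"])
    b1[in1] = signs[in1] * s1
    b2[in2] = signs[in2] * s2
    b2[labels == "shared_opposing"] *= -1.0
    # trait-2-only SNPs get their own signs (same stream, already drawn)
    return b1, b2


def _sumstats_frame(spec, panel, z, n_eff) -> pd.DataFrame:
    f = panel.freqs
    denom = np.sqrt(2.0 * f * (1.0 - f) * n_eff)
    beta = z / denom
    se = 1.0 / denom
    df = pd.DataFrame({
        "snp_id": panel.snp_ids,
        "chrom": spec.chrom,
        "pos": panel.positions,
        "a1": "A", "a2": "G",
        "freq_a1": f,
        "beta": beta, "se": se,
        "p": np.clip(p_from_z(z), np.finfo(float).tiny, 1.0),
        "n_cases": int(round(n_eff / 2)),
        "n_controls": int(round(n_eff / 2)),
        "info": 1.0,
    })
    return df[COLUMNS]


def simulate_sumstats(spec: ArchitectureSpec, ld_ref: LDPanel | None = None) -> SyntheticCohort:
    """Draw two-trait marginal z-scores from the blockwise MVN model.

    Per block b: ``z_t = sqrt(n_t) R_b beta_t + eps_t`` with joint noise
    covariance ``[[R, c R], [c R, R]]`` where
    ``c = n_overlap * pheno_corr / sqrt(n1 n2)``.  Deterministic given
    ``spec.seed``.

    Raises
    ------
    ValueError
        if |c| >= 1 (non-positive-definite joint covariance).
    """
    if ld_ref is None:
        ld_ref = make_ld_blocks(spec)
    c = spec.n_overlap * spec.pheno_corr / np.sqrt(spec.n1 * spec.n2)
    if abs(c) >= 1.0:
        raise ValueError(
            f"overlap setting (n_overlap={spec.n_overlap}, "
            f"pheno_corr={spec.pheno_corr}) gives cross-trait noise "
            f"correlation {c:.3f}; joint covariance not positive definite")
    L2 = np.linalg.cholesky(np.array([[1.0, c], [c, 1.0]]))

    b1, b2 = true_effects(spec)
    rng = spec.rng(_SUB_Z)
    z1 = np.empty(spec.m)
    z2 = np.empty(spec.m)
    for sl, block in zip(ld_ref.block_slices(), ld_ref.blocks):
        R = block.R
        Lb = np.linalg.cholesky(R + 1e-10 * np.eye(block.m))
        E = rng.standard_normal((block.m, 2))
        eps = Lb @ E @ L2.T
        z1[sl] = np.sqrt(spec.n1) * (R @ b1[sl]) + eps[:, 0]
        z2[sl] = np.sqrt(spec.n2) * (R @ b2[sl]) + eps[:, 1]

    return SyntheticCohort(
        ld_ref=ld_ref, truth_beta1=b1, truth_beta2=b2,
        sumstats_1=_sumstats_frame(spec, ld_ref, z1, spec.n1),
        sumstats_2=_sumstats_frame(spec, ld_ref, z2, spec.n2),
    )


def _copula_dosages(rng, R: np.ndarray, freqs: np.ndarray, n: int) -> np.ndarray:
    """Discretize MVN latents into {0,1,2} at Hardy-Weinberg cut points.

    Discretization attenuates correlation (more so at extreme MAF), so the
    latent correlation for each pair is calibrated from the two-term
    Hermite expansion of the dosage covariance,

        cov(d_i, d_j) ~ a_i a_j rho + (b_i b_j / 2) rho^2,

    with a_i = phi(t0_i) + phi(t1_i) and b_i = t0_i phi(t0_i) +
    t1_i phi(t1_i), solved for rho so the resulting dosage correlation
    matches the target R.  The compensated matrix is eigenvalue-clipped
    back to PSD if needed.
    """
    from scipy.stats import norm

    m = R.shape[0]
    t0 = norm.ppf((1.0 - freqs) ** 2)      # below: genotype 0
    t1 = norm.ppf(1.0 - freqs ** 2)        # above: genotype 2
    sd = np.sqrt(2.0 * freqs * (1.0 - freqs))
    a = norm.pdf(t0) + norm.pdf(t1)
    b = t0 * norm.pdf(t0) + t1 * norm.pdf(t1)
    target_cov = R * np.outer(sd, sd)
    A2 = np.outer(b, b) / 2.0
    A1 = np.outer(a, a)
    # smaller-magnitude root of A2 rho^2 + A1 rho - cov = 0
    disc = np.sqrt(np.maximum(A1 ** 2 + 4.0 * A2 * target_cov, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = (-A1 + disc) / (2.0 * A2)
        lin = target_cov / A1
    R_lat = np.where(np.abs(A2) > 1e-12, quad, lin)
    R_lat = np.clip(R_lat, -0.999, 0.999)
    np.fill_diagonal(R_lat, 1.0)
    eigvals, eigvecs = np.linalg.eigh((R_lat + R_lat.T) / 2.0)
    if eigvals.min() < 1e-8:
        R_lat = (eigvecs * np.clip(eigvals, 1e-8, None)) @ eigvecs.T
        d = np.sqrt(np.diag(R_lat))
        R_lat = R_lat / np.outer(d, d)
    L = np.linalg.cholesky(R_lat + 1e-10 * np.eye(m))
    latent = rng.standard_normal((n, m)) @ L.T
    return (latent > t0).astype(float) + (latent > t1).astype(float)


def _marginal_regression(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-SNP simple linear regression of y on raw dosage."""
    from scipy.stats import t as t_dist

    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (Xc ** 2).sum(axis=0)
    sxy = Xc.T @ yc
    syy = float(yc @ yc)
    sxx_safe = np.where(sxx == 0, np.nan, sxx)
    b = sxy / sxx_safe
    resid = np.maximum(syy - b * sxy, 0.0)
    s2 = resid / (n - 2)
    se = np.sqrt(s2 / sxx_safe)
    tstat = b / se
    p = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    return pd.DataFrame({"beta": b, "se": se, "p": np.clip(p, np.finfo(float).tiny, 1.0)})


def simulate_individual(spec: ArchitectureSpec, ld_ref: LDPanel | None = None) -> SyntheticCohort:
    """Individual-level route: copula dosages, liability phenotypes and
    per-SNP marginal regression.  An oracle for the summary-level model.

    Cohorts for the two traits are independent (``n_overlap`` must be 0)
    and capped at 5,000 samples each.
    """
    if max(spec.n1, spec.n2) > 5_000:
        raise ValueError("individual-level route capped at n <= 5,000")
    if spec.n_overlap:
        raise ValueError("individual-level route supports disjoint cohorts only")
    if ld_ref is None:
        ld_ref = make_ld_blocks(spec)
    b1, b2 = true_effects(spec)
    rng = spec.rng(_SUB_GENO)

    genotypes = {}
    frames = []
    for trait, (n, beta) in enumerate([(spec.n1, b1), (spec.n2, b2)], start=1):
        X = np.empty((n, spec.m))
        for sl, block in zip(ld_ref.block_slices(), ld_ref.blocks):
            X[:, sl] = _copula_dosages(rng, block.R, block.freqs, n)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - X.mean(axis=0)) / sd
        # genetic variance on the standardized scale; residual tops up to 1
        g = Xs @ beta
        var_g = float(g.var())
        eps_sd = np.sqrt(max(1.0 - var_g, 1e-6))
        y = g + rng.standard_normal(n) * eps_sd
        reg = _marginal_regression(X, y)
        df = pd.DataFrame({
            "snp_id": ld_ref.snp_ids,
            "chrom": spec.chrom,
            "pos": ld_ref.positions,
            "a1": "A", "a2": "G",
            "freq_a1": X.mean(axis=0) / 2.0,
            "beta": reg["beta"], "se": reg["se"], "p": reg["p"],
            "n_cases": int(round(n / 2)), "n_controls": int(round(n / 2)),
            "info": 1.0,
        })[COLUMNS]
        frames.append(df)
        genotypes[f"X{trait}"] = X
        genotypes[f"y{trait}"] = y

    return SyntheticCohort(
        ld_ref=ld_ref, truth_beta1=b1, truth_beta2=b2,
        sumstats_1=frames[0], sumstats_2=frames[1],
        genotypes=genotypes,
    )
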
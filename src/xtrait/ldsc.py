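"""Cross-trait LD score regression: SNP heritability and genetic correlation.

Under a polygenic model, the expected association chi-square of SNP j grows
linearly in its LD score ell_j = sum_k r^2_jk:

    E[chi2_j]    = N h2 ell_j / M + 1 + N a
    E[z1j z2j]   = sqrt(N1 N2) rho_g ell_j / M + rho N_s / sqrt(N1 N2)

so a weighted regression of chi-square (or the z-score product) on scaled
LD scores estimates h2 (or the genetic covariance rho_g), with the
intercept absorbing confounding and sample overlap.  The genetic
correlation is rg = rho_g / sqrt(h2_1 h2_2).  Standard errors come from a
delete-one block jackknife over contiguous genomic blocks, applied to the
full rg ratio.

Weighting follows the canonical two-step scheme: an unweighted
(1/ell-weighted) fit supplies fitted means, which then set
heteroskedasticity weights for one refit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._stats import log10_p_from_z
from .sumstats import LDPanel

DEFAULT_N_BLOCKS = 200


@dataclasses.dataclass
class Ldsch2:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    m_snps: int


@dataclasses.dataclass
class LdscFit:
    """Genome-wide cross-trait LD score regression fit."""

    h2_1: float
    h2_1_se: float
    h2_2: float
    h2_2_se: float
    gencov: float
    gencov_se: float
    rg: float
    rg_se: float
    rg_log10_p: float
    intercept_1: float
    intercept_2: float
    intercept_cross: float
    m_snps: int
    rg_defined: bool = True


def ld_scores(panel: LDPanel, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Per-SNP LD scores over a base-pair window.

    With a finite reference cohort (``n_ref``) each squared correlation is
    bias-adjusted as r2 - (1 - r2) / (n_ref - 2); population panels
    (``n_ref`` None) use raw r2.  Self-r2 (= 1) is included, so ell >= 1.
    """
    ells = []
    for block in panel.blocks:
        r2 = block.R ** 2
        if panel.n_ref is not None and panel.n_ref > 2:
            r2 = r2 - (1.0 - r2) / (panel.n_ref - 2)
        dist = np.abs(block.positions[:, None] - block.positions[None, :])
        r2 = np.where(dist <= window_bp, r2, 0.0)
        ells.append(r2.sum(axis=1))
    ell = np.concatenate(ells)
    freqs = panel.freqs
    return pd.DataFrame({
        "snp_id": panel.snp_ids,
        "ell": ell,
        "maf": np.minimum(freqs, 1.0 - freqs),
    })


def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    n_blocks = max(2, min(n_blocks, n))
    return np.linspace(0, n, n_blocks + 1).astype(int)


def _wls_jackknife(x, y, w, bounds):
    """Weighted regression of y on [x, 1] with delete-one-block estimates.

    Returns (coef, delete_coefs) where coef = (slope, intercept) and
    delete_coefs has one row per block.  Uses per-block sufficient
    statistics so the jackknife is O(n + n_blocks).
    """
    X = np.column_stack([x, np.ones_like(x)])
    WX = X * w[:, None]
    n_blocks = len(bounds) - 1
    A_blocks = np.empty((n_blocks, 2, 2))
    c_blocks = np.empty((n_blocks, 2))
    for i in range(n_blocks):
        sl = slice(bounds[i], bounds[i + 1])
        A_blocks[i] = WX[sl].T @ X[sl]
        c_blocks[i] = WX[sl].T @ y[sl]
    A = A_blocks.sum(axis=0)
    c = c_blocks.sum(axis=0)
    coef = np.linalg.lstsq(A, c, rcond=None)[0]
    delete = np.empty((n_blocks, 2))
    for i in range(n_blocks):
        delete[i] = np.linalg.lstsq(A - A_blocks[i], c - c_blocks[i],
                                    rcond=None)[0]
    return coef, delete


def _jackknife_se(delete: np.ndarray) -> np.ndarray:
    b = delete.shape[0]
    return np.sqrt((b - 1) / b * ((delete - delete.mean(axis=0)) ** 2).sum(axis=0))


def _chi2_cap(N: float) -> float:
    return max(80.0, 0.001 * N)


def _two_step_fit(x, y, ell, var_fn, bounds):
    """Two-step weighted fit: 1/ell weights, then heteroskedasticity
    reweighting from the step-1 fitted means."""
    ell_c = np.maximum(ell, 1.0)
    w1 = 1.0 / ell_c
    coef1, _ = _wls_jackknife(x, y, w1, bounds)
    fitted = coef1[0] * x + coef1[1]
    w2 = 1.0 / (ell_c * np.maximum(var_fn(fitted), 0.1))
    return _wls_jackknife(x, y, w2, bounds)


def ldsc_h2(z, ell, N, M: int | None = None,
            n_blocks: int = DEFAULT_N_BLOCKS) -> Ldsch2:
    """Single-trait SNP heritability by LD score regression.

    ``z`` and ``ell`` are aligned per-SNP vectors; ``N`` is scalar or
    per-SNP; ``M`` defaults to the SNP count.  Chi-squares above
    max(80, 0.001 N) are excluded as outliers.

    Raises
    ------
    ValueError
        if fewer SNPs than jackknife blocks remain.
    """
    z = np.asarray(z, dtype=float)
    ell = np.asarray(ell, dtype=float)
    N = np.broadcast_to(np.asarray(N, dtype=float), z.shape)
    if M is None:
        M = len(z)
    chi2 = z ** 2
    keep = chi2 < _chi2_cap(float(np.median(N)))
    chi2, ell_k, N_k = chi2[keep], ell[keep], N[keep]
    n = len(chi2)
    if n < n_blocks:
        raise ValueError("fewer SNPs than jackknife blocks")
    n_blocks = max(2, min(n_blocks, n // 100))
    bounds = _block_bounds(n, n_blocks)
    x = N_k * ell_k / M
    coef, delete = _two_step_fit(x, chi2, ell_k, lambda mu: 2.0 * mu ** 2, bounds)
    se = _jackknife_se(delete)
    return Ldsch2(h2=float(coef[0]), h2_se=float(se[0]),
                  intercept=float(coef[1]), intercept_se=float(se[1]),
                  m_snps=n)


def ldsc_rg(z1, z2, ell, N1, N2, M: int | None = None,
            n_blocks: int = DEFAULT_N_BLOCKS,
            maf=None, maf_bound: float = 0.01) -> LdscFit:
    """Cross-trait genetic correlation by LD score regression.

    Runs the two single-trait chi-square regressions and the z-score
    product regression on the shared SNP set, then jackknifes the full
    ratio rg = rho_g / sqrt(h2_1 h2_2) over contiguous blocks.  The cross
    intercept absorbs sample overlap.  SNPs with MAF <= ``maf_bound`` (when
    ``maf`` is given) or an outlying chi-square in either trait are
    excluded.

    When either heritability estimate is non-positive rg is undefined and
    reported as NaN with ``rg_defined=False``.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    ell = np.asarray(ell, dtype=float)
    N1 = np.broadcast_to(np.asarray(N1, dtype=float), z1.shape)
    N2 = np.broadcast_to(np.asarray(N2, dtype=float), z2.shape)
    if M is None:
        M = len(z1)
    keep = (z1 ** 2 < _chi2_cap(float(np.median(N1)))) \
        & (z2 ** 2 < _chi2_cap(float(np.median(N2))))
    if maf is not None:
        keep &= np.asarray(maf, dtype=float) > maf_bound
    z1, z2, ell_k = z1[keep], z2[keep], ell[keep]
    N1_k, N2_k = N1[keep], N2[keep]
    n = len(z1)
    if n < n_blocks:
        raise ValueError("fewer SNPs than jackknife blocks")
    n_blocks = max(2, min(n_blocks, n // 100))
    bounds = _block_bounds(n, n_blocks)

    x1 = N1_k * ell_k / M
    x2 = N2_k * ell_k / M
    x12 = np.sqrt(N1_k * N2_k) * ell_k / M
    c1, d1 = _two_step_fit(x1, z1 ** 2, ell_k, lambda mu: 2.0 * mu ** 2, bounds)
    c2, d2 = _two_step_fit(x2, z2 ** 2, ell_k, lambda mu: 2.0 * mu ** 2, bounds)

    mu1 = np.maximum(c1[0] * x1 + c1[1], 0.1)
    mu2 = np.maximum(c2[0] * x2 + c2[1], 0.1)
    y12 = z1 * z2
    coef0, _ = _wls_jackknife(x12, y12, 1.0 / np.maximum(ell_k, 1.0), bounds)
    mu12 = coef0[0] * x12 + coef0[1]
    w12 = 1.0 / (np.maximum(ell_k, 1.0) * (mu1 * mu2 + mu12 ** 2))
    c12, d12 = _wls_jackknife(x12, y12, w12, bounds)

    h2_1, h2_2, gencov = float(c1[0]), float(c2[0]), float(c12[0])
    se1 = _jackknife_se(d1)
    se2 = _jackknife_se(d2)
    se12 = _jackknife_se(d12)

    defined = h2_1 > 0 and h2_2 > 0
    if defined:
        rg = gencov / np.sqrt(h2_1 * h2_2)
        # ratio jackknife; denominators clipped away from zero for stability
        floor1, floor2 = 0.1 * h2_1, 0.1 * h2_2
        rg_del = d12[:, 0] / np.sqrt(np.maximum(d1[:, 0], floor1)
                                     * np.maximum(d2[:, 0], floor2))
        rg_se = float(_jackknife_se(rg_del[:, None])[0])
        rg_lp = float(log10_p_from_z(rg / rg_se)) if rg_se > 0 else 0.0
    else:
        rg, rg_se, rg_lp = np.nan, np.nan, np.nan

    return LdscFit(
        h2_1=h2_1, h2_1_se=float(se1[0]),
        h2_2=h2_2, h2_2_se=float(se2[0]),
        gencov=gencov, gencov_se=float(se12[0]),
        rg=float(rg), rg_se=rg_se, rg_log10_p=rg_lp,
        intercept_1=float(c1[1]), intercept_2=float(c2[1]),
        intercept_cross=float(c12[1]),
        m_snps=n, rg_defined=defined,
    )
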
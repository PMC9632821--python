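"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from xtrait.simulate import ArchitectureSpec
from xtrait.sumstats import COLUMNS


def enum_coloc_oracle(labf_1, labf_2, p1=1e-4, p2=1e-4, p12=1e-5):
    """Brute-force colocalization posteriors by explicit enumeration of
    every causal configuration: H0 (none), H1/H2 (each single-trait SNP),
    H3 (every ordered pair of distinct SNPs), H4 (each shared SNP).

    Plain python sums over math.exp — independent of the log-sum-exp path.
    """
    n = len(labf_1)
    h0 = 1.0
    h1 = sum(p1 * math.exp(a) for a in labf_1)
    h2 = sum(p2 * math.exp(b) for b in labf_2)
    h3 = sum(p1 * p2 * math.exp(labf_1[i] + labf_2[j])
             for i in range(n) for j in range(n) if i != j)
    h4 = sum(p12 * math.exp(labf_1[i] + labf_2[i]) for i in range(n))
    total = h0 + h1 + h2 + h3 + h4
    return np.array([h0, h1, h2, h3, h4]) / total


def ols_joint_oracle(X: np.ndarray, y: np.ndarray, idx: list[int]):
    """Multivariate least squares of y on the selected dosage columns
    (with intercept); returns (coefs, ses) for the selected SNPs."""
    Xd = np.column_stack([np.ones(len(y)), X[:, idx]])
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    s2 = float(resid @ resid) / (len(y) - Xd.shape[1])
    cov = s2 * np.linalg.inv(Xd.T @ Xd)
    return coef[1:], np.sqrt(np.diag(cov))[1:]


def make_table(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical summary-statistics table from partial row dicts."""
    defaults = {"chrom": "1", "a1": "A", "a2": "G", "freq_a1": 0.3,
                "beta": 0.1, "se": 0.02, "p": 1e-6,
                "n_cases": 1000, "n_controls": 1000, "info": 1.0}
    full = []
    for i, row in enumerate(rows):
        r = {"snp_id": f"rs{i}", "pos": 1000 * (i + 1), **defaults, **row}
        full.append(r)
    return pd.DataFrame(full)[COLUMNS]


def two_signal_locus_spec(seed: int, m: int = 50, n: int = 2000,
                          effect: float = 0.18) -> ArchitectureSpec:
    """A one-block locus with two causal SNPs two lags apart in an AR(1)
    block with rho = 0.53, so their LD is r^2 = 0.53^4 ~ 0.079."""
    labels = np.full(m, "none", dtype=object)
    labels[[20, 22]] = "trait1_only"
    return ArchitectureSpec(
        blocks=[(m, 0.53)], causal_assignments=labels,
        effect_scale=(effect, 0.0), n1=n, n2=100, seed=seed)


def cohort_ld(cohort, trait: int = 1):
    """LD reference estimated from the simulated cohort's own genotypes
    (mirroring the use of study controls as the LD panel)."""
    from xtrait.sumstats import ld_matrix

    panel = cohort.ld_ref
    return ld_matrix(cohort.genotypes[f"X{trait}"],
                     snp_ids=panel.snp_ids, positions=panel.positions)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
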
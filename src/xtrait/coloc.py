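"""Approximate-Bayes-factor colocalization under a single-causal-variant model.

Each SNP's evidence for association with a trait is summarized by
Wakefield's approximate Bayes factor: with V = se^2, r = W/(W+V) and
z = beta/se,

    log ABF = 1/2 [ log(1 - r) + r z^2 ].

Under the assumption of at most one causal variant per trait at the locus,
five hypotheses partition the configuration space — H0 (no association),
H1/H2 (one trait only), H3 (both, distinct variants), H4 (both, shared
variant) — with per-configuration priors p1, p2 and p12.  Posteriors are
accumulated in log space (log-sum-exp throughout).

Two decision rules are provided: the composite two-prior rule
(PP_H4 > 0.5 at p12 = 5e-5 AND PP_H3 < 0.5 at p12 = 1e-5) used for
declaring shared causal signals, and a strict single-posterior rule
(PP_H4 > 0.9) for published-locus follow-up.  Multi-signal loci are
handled by colocalizing each pair of conditioned marginal signals from
stepwise fine-mapping and reporting the per-pair matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import logsumexp

HYPOTHESES = ("PP_H0", "PP_H1", "PP_H2", "PP_H3", "PP_H4")


@dataclasses.dataclass
class ColocConfig:
    """Per-configuration priors and prior effect variances.

    ``p1``/``p2`` are the per-SNP single-trait priors, ``p12`` the shared
    causal prior.  ``W1``/``W2`` are prior variances of the true effect;
    0.2^2 on the log-odds scale for case-control traits (0.15^2 is the
    usual choice for quantitative traits).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W1: float = 0.04
    W2: float = 0.04

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")

    def with_p12(self, p12: float) -> "ColocConfig":
        return dataclasses.replace(self, p12=p12)


@dataclasses.dataclass
class ColocPosterior:
    """Per-SNP log ABFs and the five hypothesis posteriors."""

    labf_1: np.ndarray
    labf_2: np.ndarray
    pp: dict[str, float]
    config: ColocConfig

    @property
    def pp_h4(self) -> float:
        return self.pp["PP_H4"]

    @property
    def pp_h3(self) -> float:
        return self.pp["PP_H3"]


def labf(beta, se, W: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor (vectorized).

    Raises
    ------
    ValueError
        if any se <= 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    V = se ** 2
    r = W / (W + V)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z ** 2)


def coloc_abf(labf_1, labf_2, config: ColocConfig | None = None) -> ColocPosterior:
    """Hypothesis posteriors from two aligned per-SNP log-ABF vectors.

    Sums causal-configuration likelihoods in log space:
    H1 = p1 sum_i ABF1_i; H2 = p2 sum_j ABF2_j;
    H3 = p1 p2 (sum_i ABF1_i sum_j ABF2_j - sum_i ABF1_i ABF2_i);
    H4 = p12 sum_i ABF1_i ABF2_i; H0 = 1; then normalizes.
    """
    cfg = config or ColocConfig()
    l1 = np.asarray(labf_1, dtype=float)
    l2 = np.asarray(labf_2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("log-ABF vectors must have equal length")

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = np.log(cfg.p1) + s1
    lh2 = np.log(cfg.p2) + s2
    lh4 = np.log(cfg.p12) + s12
    # sum over i != j: total product minus the diagonal, in log space
    diff = s12 - (s1 + s2)
    if diff >= 0:  # single SNP (or numerically degenerate): no i != j terms
        lh3 = -np.inf
    else:
        lh3 = np.log(cfg.p1) + np.log(cfg.p2) + s1 + s2 + np.log1p(-np.exp(diff))
    logs = np.array([lh0, lh1, lh2, lh3, lh4])
    post = np.exp(logs - logsumexp(logs))
    return ColocPosterior(labf_1=l1, labf_2=l2,
                          pp=dict(zip(HYPOTHESES, post.tolist())), config=cfg)


def coloc_sumstats(t1: pd.DataFrame, t2: pd.DataFrame,
                   config: ColocConfig | None = None) -> ColocPosterior:
    """Colocalize two aligned summary-statistics tables (columns beta, se)."""
    cfg = config or ColocConfig()
    return coloc_abf(labf(t1["beta"], t1["se"], cfg.W1),
                     labf(t2["beta"], t2["se"], cfg.W2), cfg)


def shared_decision(pp_at_p12_5e5: ColocPosterior,
                    pp_at_p12_1e5: ColocPosterior) -> bool:
    """Composite two-prior rule: PP_H4 > 0.5 under the permissive shared
    prior (p12 = 5e-5) AND PP_H3 < 0.5 under the default prior (1e-5)."""
    return (pp_at_p12_5e5.pp_h4 > 0.5) and (pp_at_p12_1e5.pp_h3 < 0.5)


def strict_shared_decision(pp: ColocPosterior, bound: float = 0.9) -> bool:
    """Strict rule for published-locus follow-up: PP_H4 strictly above 0.9."""
    return pp.pp_h4 > bound


def run_shared_decision(t1: pd.DataFrame, t2: pd.DataFrame,
                        config: ColocConfig | None = None
                        ) -> tuple[bool, ColocPosterior, ColocPosterior]:
    """Evaluate the two-prior rule on a locus, returning the decision and
    both posteriors (permissive-prior first)."""
    cfg = config or ColocConfig()
    hi = coloc_sumstats(t1, t2, cfg.with_p12(5e-5))
    lo = coloc_sumstats(t1, t2, cfg.with_p12(1e-5))
    return shared_decision(hi, lo), hi, lo


def coloc_per_signal(
    sumstats_1: pd.DataFrame,
    sumstats_2: pd.DataFrame,
    model_1,
    model_2,
    config: ColocConfig | None = None,
) -> tuple[pd.DataFrame, dict, float]:
    """Colocalize every pair of independent signals across two traits.

    ``model_1``/``model_2`` are :class:`~xtrait.cojo.CojoModel` objects (or
    None).  For each selected signal the trait's conditioned marginal
    statistics (conditioned on the *other* index SNPs) replace the raw
    marginals; a trait with no or one selected signal falls back to its
    unconditioned statistics.  Returns (PP_H4 matrix indexed by signal
    pairs, posterior dict keyed by pair, max PP_H4).
    """
    cfg = config or ColocConfig()

    def signal_tables(ss: pd.DataFrame, model) -> dict[str, pd.DataFrame]:
        if model is None or not model.selected:
            return {"marginal": ss}
        if len(model.selected) == 1:
            return {model.selected[0]: ss}
        return {s: model.conditioned_marginals[s] for s in model.selected}

    tabs1 = signal_tables(sumstats_1, model_1)
    tabs2 = signal_tables(sumstats_2, model_2)
    posteriors = {}
    mat = pd.DataFrame(index=list(tabs1), columns=list(tabs2), dtype=float)
    for s1_name, t1 in tabs1.items():
        for s2_name, t2 in tabs2.items():
            merged = t1.merge(t2, on="snp_id", suffixes=("_1", "_2"))
            if merged.empty:
                continue
            post = coloc_abf(
                labf(merged["beta_1"], merged["se_1"], cfg.W1),
                labf(merged["beta_2"], merged["se_2"], cfg.W2), cfg)
            posteriors[(s1_name, s2_name)] = post
            mat.loc[s1_name, s2_name] = post.pp_h4
    max_pp = float(np.nanmax(mat.to_numpy(dtype=float))) if posteriors else np.nan
    return mat, posteriors, max_pp
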
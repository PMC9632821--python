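"""Approximate conditional and joint association analysis from summary data.

Multivariate regression coefficients are recovered from marginal GWAS
effects plus reference LD via the summary-statistics normal equations: with
per-SNP genotype variance weight D_j = 2 f_j (1 - f_j) N_j, the joint
system over a SNP set S is

    B b_J = rhs,   B_jk = r_jk sqrt(D_j D_k)  (j != k),  B_jj = D_j,
    rhs_j = D_j beta_j,

where r comes from the reference panel (zeroed beyond a distance window).
The phenotypic variance is inferred per SNP from the marginal identity
y'y = D se^2 (N - 1) + D beta^2 and median-aggregated, giving the residual
variance for joint standard errors.

``cojo_select`` runs forward stepwise selection with backward elimination:
repeatedly add the candidate with the smallest conditional p-value, skip
candidates collinear (r^2 above the cutoff) with the model or making the
system ill-conditioned, and drop selected SNPs whose joint p rises above
the threshold.  ``cojo_cond`` returns, for every SNP, its association
conditioned on a fixed index-SNP set — the "conditioned marginal" signals
that per-signal colocalization consumes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._stats import effective_n, log10_p_from_z
from .sumstats import LDReference

DEFAULT_P_CUT = 1e-5
DEFAULT_COLLINEARITY = 0.9
DEFAULT_WINDOW_BP = 10_000_000
FREQ_GUARD = 0.2
CONDITION_LIMIT = 1e8


@dataclasses.dataclass
class CojoModel:
    """Stepwise-selected index SNPs with joint effects and, for
    multi-signal models, per-signal conditioned marginal tables."""

    selected: list[str]
    bJ: np.ndarray
    bJ_se: np.ndarray
    log10_pJ: np.ndarray
    settings: dict
    conditioned_marginals: dict[str, pd.DataFrame]
    n_freq_dropped: int = 0
    skipped_collinear: list[str] = dataclasses.field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.selected,
            "bJ": self.bJ, "bJ_se": self.bJ_se,
            "pJ": np.power(10.0, np.maximum(self.log10_pJ, -308.0)),
            "log10_pJ": self.log10_pJ,
        })


class _Workspace:
    """Aligned summary statistics + LD, with the normal-equations pieces."""

    def __init__(self, sumstats: pd.DataFrame, ld_ref: LDReference,
                 window_bp: float, n_eff=None):
        ss = sumstats.reset_index(drop=True)
        ref_index = {s: i for i, s in enumerate(ld_ref.snp_ids)}
        keep = ss["snp_id"].map(ref_index).notna()
        ss = ss.loc[keep].reset_index(drop=True)
        if ss.empty:
            raise ValueError("no summary-statistics SNPs found in the LD reference")
        ridx = ss["snp_id"].map(ref_index).to_numpy(dtype=int)

        f_ref = ld_ref.freqs[ridx]
        f_ss = ss["freq_a1"].to_numpy()
        ok = np.abs(f_ss - f_ref) <= FREQ_GUARD
        self.n_freq_dropped = int((~ok).sum())
        ss = ss.loc[ok].reset_index(drop=True)
        ridx = ridx[ok]
        if ss.empty:
            raise ValueError("all SNPs failed the frequency-consistency guard")

        if n_eff is not None:
            N = np.broadcast_to(np.asarray(n_eff, dtype=float), (len(ss),)).copy()
        else:
            N = effective_n(ss["n_cases"].to_numpy(), ss["n_controls"].to_numpy())
        if not np.all(np.isfinite(N)):
            raise ValueError("sample sizes unavailable; pass n_eff")

        R = ld_ref.R[np.ix_(ridx, ridx)].copy()
        pos = ld_ref.positions[ridx]
        far = np.abs(pos[:, None] - pos[None, :]) > window_bp
        R[far] = 0.0
        np.fill_diagonal(R, 1.0)

        f = ss["freq_a1"].to_numpy()
        beta = ss["beta"].to_numpy()
        se = ss["se"].to_numpy()
        self.ss = ss
        self.pos = pos
        self.R = R
        self.N = N
        self.D = 2.0 * f * (1.0 - f) * N
        self.rhs = self.D * beta
        self.beta = beta
        self.se = se
        self.log10_p = log10_p_from_z(beta / se)
        # per-SNP phenotypic variance from the marginal identity, median-pooled
        yty = self.D * se ** 2 * (N - 1.0) + self.D * beta ** 2
        self.vy = float(np.median(yty / N))
        self.m = len(ss)

    # -- joint fit on an index set ------------------------------------------

    def _B(self, idx: np.ndarray) -> np.ndarray:
        sqD = np.sqrt(self.D[idx])
        B = self.R[np.ix_(idx, idx)] * np.outer(sqD, sqD)
        np.fill_diagonal(B, self.D[idx])
        return B

    def joint_fit(self, idx: np.ndarray):
        """Joint effects, SEs and log10 p for the SNPs in ``idx``.

        Raises
        ------
        np.linalg.LinAlgError
            if the system's condition number exceeds the limit.
        """
        idx = np.asarray(idx, dtype=int)
        B = self._B(idx)
        if np.linalg.cond(B) > CONDITION_LIMIT:
            raise np.linalg.LinAlgError("ill-conditioned joint system")
        Binv = np.linalg.inv(B)
        rhs = self.rhs[idx]
        bJ = Binv @ rhs
        n = float(np.median(self.N[idx]))
        df = max(n - len(idx), 1.0)
        sigma2 = max(n * self.vy - float(bJ @ rhs), 1e-12) / df
        se = np.sqrt(np.diag(Binv) * sigma2)
        return bJ, se, log10_p_from_z(bJ / se)

    def conditional_stats(self, cand: np.ndarray, sel: np.ndarray):
        """Effects of each candidate conditioned on the selected set.

        Partitioned-regression form of the joint solve on sel + {j}, run
        for every candidate at once.  Returns (beta_c, se_c, log10_p_c);
        near-perfect proxies of the selected set (denominator collapse)
        come back with beta 0 and p 1.
        """
        cand = np.asarray(cand, dtype=int)
        sel = np.asarray(sel, dtype=int)
        if len(sel) == 0:
            return self.beta[cand], self.se[cand], self.log10_p[cand]
        B_ss = self._B(sel)
        Binv = np.linalg.inv(B_ss)
        rhs_s = self.rhs[sel]
        w = Binv @ rhs_s
        fit_ss = float(rhs_s @ w)

        sqD_c = np.sqrt(self.D[cand])
        sqD_s = np.sqrt(self.D[sel])
        cross = self.R[np.ix_(cand, sel)] * np.outer(sqD_c, sqD_s)
        denom = self.D[cand] - np.einsum("ij,jk,ik->i", cross, Binv, cross)
        num = self.rhs[cand] - cross @ w
        good = denom > 1e-8 * self.D[cand]

        beta_c = np.zeros(len(cand))
        se_c = self.se[cand].copy()
        lp_c = np.zeros(len(cand))
        if good.any():
            bc = num[good] / denom[good]
            n = float(np.median(self.N))
            df = max(n - len(sel) - 1.0, 1.0)
            rss = np.maximum(n * self.vy - fit_ss - num[good] ** 2 / denom[good], 1e-12)
            sc = np.sqrt(rss / df / denom[good])
            beta_c[good] = bc
            se_c[good] = sc
            lp_c[good] = log10_p_from_z(bc / sc)
        return beta_c, se_c, lp_c

    def max_r2_with(self, cand: np.ndarray, sel: np.ndarray) -> np.ndarray:
        if len(sel) == 0:
            return np.zeros(len(cand))
        return (self.R[np.ix_(cand, sel)] ** 2).max(axis=1)


def cojo_select(
    sumstats: pd.DataFrame,
    ld_ref: LDReference,
    p_cut: float = DEFAULT_P_CUT,
    collinearity: float = DEFAULT_COLLINEARITY,
    window_bp: float = DEFAULT_WINDOW_BP,
    n_eff=None,
) -> CojoModel:
    """Forward stepwise selection of independently associated SNPs.

    Candidates enter in order of conditional p-value (ties break on smaller
    position); candidates with r^2 above ``collinearity`` to any selected
    SNP, or making the joint system ill-conditioned, are skipped.  After
    each addition the joint model is refit and any selected SNP whose joint
    p rises above ``p_cut`` is backward-eliminated.  For each final index
    SNP a conditioned marginal table (conditioned on the other index SNPs)
    is attached.
    """
    ws = _Workspace(sumstats, ld_ref, window_bp, n_eff=n_eff)
    lp_cut = np.log10(p_cut)
    selected: list[int] = []
    skipped: list[str] = []
    all_idx = np.arange(ws.m)

    while True:
        cand = np.setdiff1d(all_idx, selected)
        if len(cand) == 0:
            break
        r2 = ws.max_r2_with(cand, np.array(selected, dtype=int))
        keep = r2 <= collinearity
        skipped.extend(ws.ss["snp_id"].iloc[cand[~keep & (r2 > collinearity)]])
        cand = cand[keep]
        if len(cand) == 0:
            break
        _, _, lp_c = ws.conditional_stats(cand, np.array(selected, dtype=int))
        order = np.lexsort((ws.pos[cand], lp_c))
        best = cand[order[0]]
        if lp_c[order[0]] >= lp_cut:
            break
        trial = selected + [int(best)]
        try:
            bJ, seJ, lpJ = ws.joint_fit(np.array(trial))
        except np.linalg.LinAlgError:
            skipped.append(str(ws.ss["snp_id"].iloc[best]))
            all_idx = np.setdiff1d(all_idx, [best])
            continue
        selected = trial
        # backward elimination
        while len(selected) > 1:
            bJ, seJ, lpJ = ws.joint_fit(np.array(selected))
            worst = int(np.argmax(lpJ))
            if lpJ[worst] < lp_cut:
                break
            selected.pop(worst)
        if len(selected) == 1:
            bJ, seJ, lpJ = ws.joint_fit(np.array(selected))

    settings = {"p_cut": p_cut, "collinearity": collinearity,
                "window_bp": window_bp}
    if not selected:
        return CojoModel(selected=[], bJ=np.empty(0), bJ_se=np.empty(0),
                         log10_pJ=np.empty(0), settings=settings,
                         conditioned_marginals={},
                         n_freq_dropped=ws.n_freq_dropped,
                         skipped_collinear=skipped)

    sel = np.array(selected, dtype=int)
    bJ, seJ, lpJ = ws.joint_fit(sel)
    names = [str(s) for s in ws.ss["snp_id"].iloc[sel]]
    conditioned = {}
    for i, name in enumerate(names):
        others = [names[j] for j in range(len(names)) if j != i]
        conditioned[name] = _cond_table(ws, others)
    return CojoModel(selected=names, bJ=bJ, bJ_se=seJ, log10_pJ=lpJ,
                     settings=settings, conditioned_marginals=conditioned,
                     n_freq_dropped=ws.n_freq_dropped,
                     skipped_collinear=skipped)


def _cond_table(ws: _Workspace, condition_names: list[str]) -> pd.DataFrame:
    name_to_idx = {s: i for i, s in enumerate(ws.ss["snp_id"])}
    missing = [s for s in condition_names if s not in name_to_idx]
    if missing:
        raise ValueError(f"conditioning SNPs absent from the data: {missing}")
    sel = np.array([name_to_idx[s] for s in condition_names], dtype=int)
    cand = np.setdiff1d(np.arange(ws.m), sel)
    beta_c, se_c, lp_c = ws.conditional_stats(cand, sel)
    return pd.DataFrame({
        "snp_id": ws.ss["snp_id"].iloc[cand].to_numpy(),
        "chrom": ws.ss["chrom"].iloc[cand].to_numpy(),
        "pos": ws.ss["pos"].iloc[cand].to_numpy(),
        "beta": beta_c, "se": se_c,
        "p": np.power(10.0, np.maximum(lp_c, -308.0)),
        "log10_p": lp_c,
    })


def cojo_cond(
    sumstats: pd.DataFrame,
    ld_ref: LDReference,
    condition_on: list[str],
    window_bp: float = DEFAULT_WINDOW_BP,
    n_eff=None,
) -> pd.DataFrame:
    """Marginal statistics for every SNP conditioned on a fixed SNP set.

    Conditioning on an empty set returns the marginal statistics unchanged.
    A SNP that is a (near-)perfect proxy of the conditioning set has its
    signal fully absorbed: conditional beta 0 and p 1.
    """
    ws = _Workspace(sumstats, ld_ref, window_bp, n_eff=n_eff)
    return _cond_table(ws, list(condition_on))
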
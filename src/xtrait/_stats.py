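"""Small numerical helpers shared across modules.

P-values from extreme z-scores underflow double precision well before the
magnitudes seen in large GWAS meta-analyses, so every two-sided normal test
in the package is computed in log10 space and only exponentiated for
display.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

Z_95 = 1.959964  # two-sided 97.5% normal quantile, as printed in CI formulas
CHI2_MEDIAN_1DF = 0.4549364  # median of the chi-square distribution, 1 df

_LOG10 = np.log(10.0)


def log10_p_from_z(z):
    """Two-sided normal log10 p-value for a z-score (vectorized)."""
    z = np.asarray(z, dtype=float)
    return (np.log(2.0) + stats.norm.logsf(np.abs(z))) / _LOG10


def p_from_z(z):
    """Two-sided normal p-value; underflows to 0.0 below ~1e-308."""
    return np.power(10.0, log10_p_from_z(z))


def z_from_log10_p(log10_p):
    """|z| recovering a two-sided normal log10 p-value."""
    log10_p = np.asarray(log10_p, dtype=float)
    return stats.norm.isf(np.power(10.0, log10_p) / 2.0)


def beta_se_from_or_ci(or_point, ci_low, ci_high):
    """Log-odds effect and SE from an odds ratio with a 95% CI.

    beta = ln(OR); se = (ln hi - ln lo) / (2 * 1.959964).
    """
    beta = np.log(np.asarray(or_point, dtype=float))
    se = (np.log(np.asarray(ci_high, dtype=float))
          - np.log(np.asarray(ci_low, dtype=float))) / (2.0 * Z_95)
    return beta, se


def effective_n(n_cases, n_controls):
    """Effective sample size 4 / (1/cases + 1/controls) for binary traits."""
    n_cases = np.asarray(n_cases, dtype=float)
    n_controls = np.asarray(n_controls, dtype=float)
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)
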
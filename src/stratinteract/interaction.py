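"""Correlation-adjusted difference tests for age-, sex- and age-by-sex
specific genetic effects.

The two-way statistic compares pooled group estimates a and b:

    t = (b_a - b_b) / sqrt(SE_a^2 + SE_b^2 - 2 r SE_a SE_b)

where ``r`` is the genome-wide Spearman rank correlation between the two
groups' effect estimates.  The groups are built from disjoint individuals,
so their *sampling* errors are independent; the correlation instead
captures the shared polygenic signal that makes effect estimates at the
same marker similar across groups, and ignoring it (r = 0) makes the test
conservative.  The same statistic, with r set to the between-study effect
correlation, serves comparisons against external study groups with
overlapping samples.

The three-way statistic is the age-difference of sex-differences (equal,
up to sign, to the sex-difference of age-differences):

    t = ((b_Mle50 - b_Fle50) - (b_Mgt50 - b_Fgt50)) / sqrt(sum of 4 SE^2)

with no correlation term in the denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: default floor on the number of markers for correlation estimation
CORRELATION_FLOOR = 100


def estimate_correlation(
    betas_a, betas_b, floor: int = CORRELATION_FLOOR
) -> float:
    """Spearman rank correlation between two groups' per-marker effects."""
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("effect vectors must be paired (same marker set)")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < floor:
        raise ValueError(
            f"correlation estimation needs >= {floor} markers, have {int(ok.sum())}"
        )
    rho = stats.spearmanr(a[ok], b[ok]).statistic
    return float(rho)


def difference_test(beta_a, se_a, beta_b, se_b, r: float = 0.0):
    """Correlation-adjusted two-group difference test (vectorised).

    Returns ``(t, p)`` with a two-sided normal P.  Raises if the variance
    of the difference is non-positive (degenerate |r| -> 1 with equal SEs).
    """
    beta_a, se_a, beta_b, se_b = map(np.asarray, (beta_a, se_a, beta_b, se_b))
    var = se_a**2 + se_b**2 - 2.0 * r * se_a * se_b
    finite = np.isfinite(var)
    if np.any(var[finite] <= 0):
        bad = np.argwhere(finite & (var <= 0)).ravel()[:5]
        raise ValueError(
            f"non-positive variance of the difference at indices {bad.tolist()} "
            f"(r={r}, se_a={np.atleast_1d(se_a)[bad]}, se_b={np.atleast_1d(se_b)[bad]})"
        )
    t = (beta_a - beta_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(t))
    if t.ndim == 0:
        return float(t), float(p)
    return t, p


def three_way_test(beta_m_le50, se_m_le50, beta_f_le50, se_f_le50,
                   beta_m_gt50, se_m_gt50, beta_f_gt50, se_f_gt50):
    """Age-by-sex (three-way) difference test over the four strata.

    Strata are disjoint samples, so the denominator is the plain sum of
    the four squared standard errors, without correlation terms.
    """
    arrs = map(np.asarray, (beta_m_le50, se_m_le50, beta_f_le50, se_f_le50,
                            beta_m_gt50, se_m_gt50, beta_f_gt50, se_f_gt50))
    bml, sml, bfl, sfl, bmg, smg, bfg, sfg = arrs
    num = (bml - bfl) - (bmg - bfg)
    den = np.sqrt(sml**2 + sfl**2 + smg**2 + sfg**2)
    t = num / den
    p = 2.0 * stats.norm.sf(np.abs(t))
    if t.ndim == 0:
        return float(t), float(p)
    return t, p


def interaction_table(
    meta: pd.DataFrame,
    r_age: float | None = None,
    r_sex: float | None = None,
    correlation_floor: int = CORRELATION_FLOOR,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """All three interaction statistics for a pooled hierarchy table.

    ``meta`` is the wide output of :func:`stratinteract.meta.pool_strata`.
    The correlations are estimated genome-wide from the table itself unless
    supplied, then applied as constants to every marker.  Markers missing
    any stratum are excluded (no partial imputation).

    Returns the per-marker table (columns MARKER, T_AGE, P_AGEDIFF, T_SEX,
    P_SEXDIFF, T_AGESEX, P_AGESEXDIFF, R_AGE_USED, R_SEX_USED) and the
    correlations used.
    """
    complete = meta[[f"SE_{s}" for s in
                     ("M_le50", "M_gt50", "F_le50", "F_gt50")]].notna().all(axis=1)
    df = meta.loc[complete]

    if r_age is None:
        r_age = estimate_correlation(df["BETA_le50"], df["BETA_gt50"],
                                     floor=correlation_floor)
    if r_sex is None:
        r_sex = estimate_correlation(df["BETA_M"], df["BETA_F"],
                                     floor=correlation_floor)

    t_age, p_age = difference_test(df["BETA_le50"], df["SE_le50"],
                                   df["BETA_gt50"], df["SE_gt50"], r_age)
    t_sex, p_sex = difference_test(df["BETA_M"], df["SE_M"],
                                   df["BETA_F"], df["SE_F"], r_sex)
    t_as, p_as = three_way_test(
        df["BETA_M_le50"], df["SE_M_le50"], df["BETA_F_le50"], df["SE_F_le50"],
        df["BETA_M_gt50"], df["SE_M_gt50"], df["BETA_F_gt50"], df["SE_F_gt50"])

    out = pd.DataFrame({
        "MARKER": df["MARKER"].to_numpy(),
        "T_AGE": np.asarray(t_age), "P_AGEDIFF": np.asarray(p_age),
        "T_SEX": np.asarray(t_sex), "P_SEXDIFF": np.asarray(p_sex),
        "T_AGESEX": np.asarray(t_as), "P_AGESEXDIFF": np.asarray(p_as),
        "R_AGE_USED": r_age, "R_SEX_USED": r_sex,
    })
    return out.reset_index(drop=True), {"r_age": float(r_age), "r_sex": float(r_sex)}


def se_from_beta_p(beta, pvalue):
    """Back-derive a standard error from a printed effect and P-value.

    Uses the two-sided normal quantile ``|z| = Phi^-1(1 - P/2)``, evaluated
    in log space (``ndtri_exp``) so P-values near the floating underflow
    limit remain accurate; SE = |beta| / |z|.
    """
    from scipy.special import ndtri_exp

    beta = np.asarray(beta, dtype=float)
    p = np.asarray(pvalue, dtype=float)
    z = -ndtri_exp(np.log(p) - np.log(2.0))
    se = np.abs(beta) / z
    if se.ndim == 0:
        return float(se)
    return se
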
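"""Downstream statistics: per-SNP explained variance from summary
statistics, group explained-variance sums, and exact binomial
direction/enrichment tests for look-up data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .screening import clump_loci


def snp_r2(pvalue, n, small_sample_correction: bool = True):
    """Explained phenotypic variance of one SNP from its P-value and N.

    With ``z = Phi^-1(P/2)`` the main term is ``z^2 / (z^2 + N)``; the
    small-sample correction subtracts ``(1 - r^2)/N``, giving the linear
    self-consistency ``r^2 (1 - 1/N) = z^2/(z^2+N) - 1/N`` solved in closed
    form.  The result is floored at 0 (a null P yields 0).  Set
    ``small_sample_correction=False`` for the uncorrected main term.
    """
    p = np.asarray(pvalue, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr <= 1):
        raise ValueError("n must exceed 1")
    z = stats.norm.isf(p / 2.0)
    main = z**2 / (z**2 + n_arr)
    if small_sample_correction:
        r2 = (main - 1.0 / n_arr) / (1.0 - 1.0 / n_arr)
    else:
        r2 = main
    r2 = np.maximum(r2, 0.0)
    if r2.ndim == 0:
        return float(r2)
    return r2


@dataclasses.dataclass
class VarExpResult:
    """Summed explained variance over clumped lead SNPs for one group."""

    group: str
    threshold: float
    n_loci: int
    total_r2: float
    per_snp: pd.DataFrame
    bootstrap_se: float | None = None


GROUP_COLUMNS = {
    "women": ("P_F", "N_F"),
    "men": ("P_M", "N_M"),
    "younger": ("P_le50", "N_le50"),
    "older": ("P_gt50", "N_gt50"),
}


def group_r2_sum(
    meta: pd.DataFrame,
    group: str,
    threshold: float = 5e-8,
    clump_window: int = 500_000,
    n_bootstrap: int = 1_000,
    seed: int = 0,
) -> VarExpResult:
    """Group-specific explained variance of the top overall-association loci.

    Markers with ``P_overall`` below the threshold are clumped into
    independent regions by physical distance, and for each region's lead
    SNP (lowest overall P) the explained variance is computed from the
    *group's* P and N; the sums are reported with a nonparametric
    bootstrap SE over loci.
    """
    if group not in GROUP_COLUMNS:
        raise ValueError(f"group must be one of {sorted(GROUP_COLUMNS)}")
    p_col, n_col = GROUP_COLUMNS[group]
    passed = meta[(meta["P_overall"] < threshold)
                  & meta[p_col].notna() & meta[n_col].notna()]
    if passed.empty:
        return VarExpResult(group=group, threshold=threshold, n_loci=0,
                            total_r2=0.0, per_snp=pd.DataFrame(),
                            bootstrap_se=0.0)
    loci = clump_loci(passed, window=clump_window, p_column="P_overall")
    leads = passed.set_index("MARKER").loc[[l.lead_marker for l in loci]]
    r2 = snp_r2(leads[p_col].to_numpy(), leads[n_col].to_numpy())
    per_snp = pd.DataFrame({"MARKER": leads.index, "R2": r2,
                            "P_GROUP": leads[p_col].to_numpy(),
                            "N_GROUP": leads[n_col].to_numpy()})
    total = float(np.sum(r2))
    boot_se = None
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, len(r2), size=(n_bootstrap, len(r2)))
        boot_se = float(np.std(r2[draws].sum(axis=1), ddof=1))
    return VarExpResult(group=group, threshold=threshold, n_loci=len(loci),
                        total_r2=total, per_snp=per_snp, bootstrap_se=boot_se)


def group_r2_difference(
    meta: pd.DataFrame,
    group_a: str,
    group_b: str,
    threshold: float = 5e-8,
    clump_window: int = 500_000,
    n_bootstrap: int = 1_000,
    seed: int = 0,
) -> dict:
    """Bootstrap comparison of summed explained variance between two groups.

    Loci are resampled jointly (the same resample is scored in both
    groups), giving a difference estimate, its bootstrap SE and a normal
    two-sided P for the null of equal sums.
    """
    res_a = group_r2_sum(meta, group_a, threshold, clump_window, 0, seed)
    res_b = group_r2_sum(meta, group_b, threshold, clump_window, 0, seed)
    diff = res_a.total_r2 - res_b.total_r2
    if res_a.n_loci == 0 or res_b.n_loci == 0:
        return {"difference": diff, "se": np.nan, "pvalue": np.nan,
                "group_a": res_a, "group_b": res_b}
    joint = res_a.per_snp.merge(res_b.per_snp, on="MARKER",
                                suffixes=("_a", "_b"))
    ra = joint["R2_a"].to_numpy()
    rb = joint["R2_b"].to_numpy()
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(joint), size=(n_bootstrap, len(joint)))
    diffs = ra[draws].sum(axis=1) - rb[draws].sum(axis=1)
    se = float(np.std(diffs, ddof=1))
    p = 2.0 * stats.norm.sf(abs(diff) / se) if se > 0 else np.nan
    return {"difference": diff, "se": se, "pvalue": float(p),
            "group_a": res_a, "group_b": res_b}


@dataclasses.dataclass
class EnrichmentInput:
    n_tested: int
    n_success: int
    p0: float
    success_definition: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.n_success <= self.n_tested:
            raise ValueError("need 0 <= n_success <= n_tested")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")


def binomial_direction_test(k: int, n: int, p0: float) -> float:
    """Exact one-sided upper-tail binomial probability P(X >= k)."""
    EnrichmentInput(n_tested=n, n_success=k, p0=p0)
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def lookup_enrichment(
    lookup: pd.DataFrame,
    p0: float = 0.025,
    alpha: float = 0.05,
) -> tuple[EnrichmentInput, float]:
    """Enrichment of directionally consistent nominal associations.

    ``lookup`` needs columns MARKER, BETA, P and EXPECTED_SIGN (+1/-1).
    A success is a nominally significant association (P < ``alpha``) whose
    effect sign matches the hypothesised direction; under the null each
    SNP succeeds with probability ``p0`` (default 0.05 x 1/2 = 0.025).
    """
    missing = lookup["EXPECTED_SIGN"].isna() | (lookup["EXPECTED_SIGN"] == 0)
    if missing.any():
        raise ValueError(
            "missing expected sign for markers: "
            f"{lookup.loc[missing, 'MARKER'].tolist()}")
    success = ((lookup["P"] < alpha)
               & (np.sign(lookup["BETA"]) == np.sign(lookup["EXPECTED_SIGN"])))
    inp = EnrichmentInput(
        n_tested=len(lookup), n_success=int(success.sum()), p0=p0,
        success_definition=f"P < {alpha} with hypothesised direction")
    return inp, binomial_direction_test(inp.n_success, inp.n_tested, p0)
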
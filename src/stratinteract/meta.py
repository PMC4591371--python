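"""Fixed-effect inverse-variance-weighted (IVW) pooling across studies and
across the four-stratum hierarchy, plus the overall and joint tests.

The stratum hierarchy is: four disjoint strata (men <=50y, men >50y,
women <=50y, women >50y), the two sexes (M, F), the two age groups
(le50, gt50), and the overall level pooling everything.  Because IVW
pooling is associative, pooling strata directly or through intermediate
levels gives identical results; both are exposed.

The joint main+interaction test sums the squared pooled stratum z-scores
into a chi-square statistic with one df per contributing stratum; the
strata are disjoint samples and hence independent.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import STRATA

#: hierarchy levels -> constituent strata
LEVELS = {
    "M": ("M_le50", "M_gt50"),
    "F": ("F_le50", "F_gt50"),
    "le50": ("M_le50", "F_le50"),
    "gt50": ("M_gt50", "F_gt50"),
    "overall": STRATA,
}


def ivw_pool(
    betas: Sequence[float], ses: Sequence[float]
) -> tuple[float, float, float]:
    """Inverse-variance-weighted fixed-effect pool of effect estimates.

    Weights are ``w_i = 1/se_i^2``; the pooled estimate is the weighted
    mean, its SE is ``1/sqrt(sum w)`` and the P-value the two-sided normal
    tail of the pooled z-score.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0 or b.size != s.size:
        raise ValueError("need equal-length, non-empty betas and ses")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def pool_study_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """IVW-pool several per-study tables for one stratum, marker-wise.

    Each table needs columns MARKER, CHR, POS, BETA, SE, N (EAF optional).
    Markers absent from a study simply contribute nothing.  Returns one row
    per marker with pooled BETA/SE/P, summed N, and N_STUDIES.
    """
    frames = []
    for i, t in enumerate(tables):
        f = t[["MARKER", "CHR", "POS", "BETA", "SE", "N"]].copy()
        if "EAF" in t.columns:
            f["EAF"] = t["EAF"]
        f["_study"] = i
        frames.append(f)
    if not frames:
        raise ValueError("no study tables supplied")
    allrows = pd.concat(frames, ignore_index=True)
    allrows["_w"] = 1.0 / allrows["SE"] ** 2
    allrows["_wb"] = allrows["_w"] * allrows["BETA"]
    if "EAF" in allrows.columns:
        allrows["_wf"] = allrows["_w"] * allrows["EAF"]
    g = allrows.groupby("MARKER", sort=False)
    out = pd.DataFrame({
        "CHR": g["CHR"].first(),
        "POS": g["POS"].first(),
        "BETA": g["_wb"].sum() / g["_w"].sum(),
        "SE": 1.0 / np.sqrt(g["_w"].sum()),
        "N": g["N"].sum(),
        "N_STUDIES": g["_study"].nunique(),
    })
    if "EAF" in allrows.columns:
        out["EAF"] = g["_wf"].sum() / g["_w"].sum()
    out["P"] = 2.0 * stats.norm.sf(np.abs(out["BETA"] / out["SE"]))
    return out.reset_index().sort_values(["CHR", "POS"], kind="stable") \
              .reset_index(drop=True)


def joint_test(
    stratum_betas: Sequence[float], stratum_ses: Sequence[float]
) -> tuple[float, int, float]:
    """Joint main+interaction chi-square test over pooled stratum estimates.

    ``chi2 = sum_s (beta_s / se_s)^2`` on as many df as strata contribute;
    it is powerful both for a shared main effect and for effects that
    differ (even in sign) across strata.  Requires >= 2 strata.
    """
    b = np.asarray(stratum_betas, dtype=float)
    s = np.asarray(stratum_ses, dtype=float)
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
    if ok.sum() < 2:
        raise ValueError("joint test needs >= 2 strata with positive SEs")
    z2 = (b[ok] / s[ok]) ** 2
    chi2 = float(np.sum(z2))
    df = int(ok.sum())
    return chi2, df, float(stats.chi2.sf(chi2, df))


def pool_strata(stratum_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Build the full marker-level hierarchy table from per-stratum pools.

    ``stratum_tables`` maps each stratum name to its across-study pooled
    table (columns MARKER, CHR, POS, BETA, SE, P, N and optionally
    N_STUDIES).  For every marker present in at least one stratum the
    sex-level, age-level and overall estimates are IVW pools of whichever
    constituent strata carry the marker; the joint chi-square uses the
    strata present (df = count).  Output is one wide row per marker with
    BETA_<level>, SE_<level>, P_<level>, N_<level> columns plus
    JOINT_CHI2, JOINT_DF, JOINT_P and N_STRATA.
    """
    unknown = set(stratum_tables) - set(STRATA)
    if unknown:
        raise ValueError(f"unknown strata: {sorted(unknown)}")

    pieces = []
    for s, t in stratum_tables.items():
        f = t.set_index("MARKER")
        cols = {f"BETA_{s}": f["BETA"], f"SE_{s}": f["SE"], f"N_{s}": f["N"]}
        pieces.append(pd.DataFrame(cols))
        pieces.append(f[["CHR", "POS"]].rename(
            columns={"CHR": f"_CHR_{s}", "POS": f"_POS_{s}"}))
    wide = pd.concat(pieces, axis=1)

    chr_cols = [c for c in wide.columns if c.startswith("_CHR_")]
    pos_cols = [c for c in wide.columns if c.startswith("_POS_")]
    wide["CHR"] = wide[chr_cols].bfill(axis=1).iloc[:, 0].astype(np.int64)
    wide["POS"] = wide[pos_cols].bfill(axis=1).iloc[:, 0].astype(np.int64)
    wide = wide.drop(columns=chr_cols + pos_cols)

    present = [s for s in STRATA if f"BETA_{s}" in wide.columns]
    for s in STRATA:
        if s not in present:
            wide[f"BETA_{s}"] = np.nan
            wide[f"SE_{s}"] = np.nan
            wide[f"N_{s}"] = np.nan

    beta = wide[[f"BETA_{s}" for s in STRATA]].to_numpy(float)
    se = wide[[f"SE_{s}" for s in STRATA]].to_numpy(float)
    n = wide[[f"N_{s}" for s in STRATA]].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(np.isfinite(se) & (se > 0), 1.0 / se**2, 0.0)
        wb = np.where(w > 0, w * beta, 0.0)

    for s in STRATA:
        z = wide[f"BETA_{s}"] / wide[f"SE_{s}"]
        wide[f"P_{s}"] = 2.0 * stats.norm.sf(np.abs(z))

    for level, members in LEVELS.items():
        idx = [STRATA.index(m) for m in members]
        wsum = w[:, idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            b_lvl = wb[:, idx].sum(axis=1) / wsum
            se_lvl = 1.0 / np.sqrt(wsum)
        b_lvl[wsum == 0] = np.nan
        se_lvl[wsum == 0] = np.nan
        wide[f"BETA_{level}"] = b_lvl
        wide[f"SE_{level}"] = se_lvl
        wide[f"P_{level}"] = 2.0 * stats.norm.sf(np.abs(b_lvl / se_lvl))
        wide[f"N_{level}"] = np.nansum(np.where(w[:, idx] > 0, n[:, idx], 0.0),
                                       axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(w > 0, (beta / se) ** 2, 0.0)
    n_strata = (w > 0).sum(axis=1)
    chi2 = z2.sum(axis=1)
    wide["N_STRATA"] = n_strata
    wide["JOINT_CHI2"] = np.where(n_strata >= 2, chi2, np.nan)
    wide["JOINT_DF"] = np.where(n_strata >= 2, n_strata, np.nan)
    wide["JOINT_P"] = stats.chi2.sf(wide["JOINT_CHI2"], wide["JOINT_DF"])

    wide = wide.reset_index().rename(columns={"index": "MARKER"})
    return wide.sort_values(["CHR", "POS"], kind="stable").reset_index(drop=True)


def post_meta_filter(
    results: pd.DataFrame,
    max_n: dict[str, float] | None = None,
    fraction: float = 0.5,
) -> pd.DataFrame:
    """Post-meta-analysis marker filter.

    Keeps markers available in at least ``fraction`` (default half) of the
    maximum attainable sample size in *every* stratum, and carrying a
    mapped chromosome/position.  ``max_n`` gives the per-stratum maxima;
    when omitted they are taken as the column maxima of the table itself.
    """
    keep = results["CHR"].notna() & results["POS"].notna()
    for s in STRATA:
        col = results[f"N_{s}"].fillna(0.0)
        cap = (max_n or {}).get(s, float(np.nanmax(col)) if col.notna().any() else 0.0)
        if cap > 0:
            keep &= col >= fraction * cap
    return results.loc[keep].reset_index(drop=True)
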
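"""Reading, harmonising, QC-filtering and genomic-control correction of
per-study, per-stratum GWAS summary statistics.

Input files are tab- or whitespace-delimited text with one header row
(gzip-transparent), in the dialect consortia typically upload for
METAL-style meta-analysis.  Canonical column names are ``MARKER, CHR, POS,
EA, OA, EAF, BETA, SE, P, N, INFO, IMPUTED, CALLRATE, HWE_P``; arbitrary
headers can be mapped onto these via ``column_map``.

All P-values are recomputed from ``beta/se`` downstream rather than trusted
from the upload, so rounding in contributed files cannot propagate.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: median of the chi-square distribution with 1 df, the genomic-control
#: normalising constant.
CHI2_1_MEDIAN = 0.4549364231195724

#: analysis strata: men/women crossed with age at or below / above 50 years
STRATA = ("M_le50", "M_gt50", "F_le50", "F_gt50")

CANONICAL_COLUMNS = (
    "MARKER", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N",
    "INFO", "IMPUTED", "CALLRATE", "HWE_P",
)

MANDATORY = ("CHR", "POS", "EA", "OA", "BETA", "SE", "N")

#: imputation-quality floors by imputation software (metric differs by tool)
QUALITY_FLOORS = {"MACH": 0.3, "BIMBAM": 0.3, "IMPUTE": 0.4, "PLINK": 0.8}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Panel(str, enum.Enum):
    """Genotyping panel of a contributing study."""

    GENOME_WIDE = "genome-wide-imputed"
    TARGETED_CHIP = "targeted-chip"


@dataclasses.dataclass
class StudyMeta:
    """Descriptive metadata for one study-stratum summary file."""

    study_id: str
    stratum: str
    panel: Panel = Panel.GENOME_WIDE
    imputation_software: str | None = None
    lambda_gc: float | None = None
    ascertainment: str = "population-based"
    self_report: bool = False

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(
                f"stratum must be one of {STRATA}, got {self.stratum!r}"
            )
        self.panel = Panel(self.panel)


@dataclasses.dataclass
class QCReport:
    """Per-rule removal counts for one QC pass."""

    input_count: int = 0
    monomorphic: int = 0
    low_mac: int = 0
    low_quality: int = 0
    low_callrate: int = 0
    hwe_failure: int = 0
    unmappable: int = 0
    incompatible_alleles: int = 0
    duplicate: int = 0
    retained: int = 0

    @property
    def removed(self) -> int:
        return (self.monomorphic + self.low_mac + self.low_quality
                + self.low_callrate + self.hwe_failure + self.unmappable
                + self.incompatible_alleles + self.duplicate)

    def to_text(self) -> str:
        lines = [f"input\t{self.input_count}"]
        for field in ("monomorphic", "low_mac", "low_quality", "low_callrate",
                      "hwe_failure", "unmappable", "incompatible_alleles",
                      "duplicate"):
            lines.append(f"removed_{field}\t{getattr(self, field)}")
        lines.append(f"retained\t{self.retained}")
        return "\n".join(lines)


class SumstatsError(Exception):
    """Raised on malformed or unusable summary-statistics input."""


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"1": True, "0": False, "true": True, "false": False,
               "yes": True, "no": False, "t": True, "f": False}
    return series.astype(str).str.strip().str.lower().map(mapping)


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    meta: StudyMeta | None = None,
) -> tuple[pd.DataFrame, int]:
    """Read one study-stratum summary-statistics file.

    Parameters
    ----------
    path
        Delimited text file (gzip transparent), one header row.
    column_map
        Optional mapping from file headers to canonical field names
        (e.g. ``{"Effect": "BETA", "StdErr": "SE"}``).  Canonical names are
        case-insensitive on both sides.
    meta
        Unused here beyond validation; accepted for symmetry with the CLI.

    Returns
    -------
    (records, n_dropped)
        ``records`` is a DataFrame with canonical upper-case columns in
        input row order; rows whose mandatory fields failed to parse are
        dropped and counted in ``n_dropped``.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty and df.columns.size == 0:
        raise SumstatsError(f"empty summary-statistics file: {path}")
    if column_map:
        rename = {k: v.upper() for k, v in column_map.items()}
        df = df.rename(columns=rename)
    df.columns = [c.upper() for c in df.columns]

    has_marker = "MARKER" in df.columns
    for col in MANDATORY:
        if col not in df.columns:
            if col in ("CHR", "POS") and has_marker:
                continue
            raise SumstatsError(f"mandatory column {col!r} not resolvable "
                                f"(have {list(df.columns)})")
    if "CHR" not in df.columns:
        split = df["MARKER"].str.split(":", expand=True)
        df["CHR"], df["POS"] = split[0], split[1]
    if df.empty:
        raise SumstatsError(f"no data rows in {path}")

    numeric = ["CHR", "POS", "EAF", "BETA", "SE", "P", "N", "INFO",
               "CALLRATE", "HWE_P"]
    for col in numeric:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("EA", "OA"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    if "IMPUTED" in df.columns:
        df["IMPUTED"] = _coerce_bool(df["IMPUTED"])
    else:
        df["IMPUTED"] = "INFO" in df.columns

    mand = [c for c in ("CHR", "POS", "BETA", "SE", "N") if c in df.columns]
    ok = df[mand].notna().all(axis=1)
    ok &= df["SE"] > 0
    n_dropped = int((~ok).sum())
    df = df.loc[ok].reset_index(drop=True)
    for col in ("CHR", "POS", "N"):
        df[col] = df[col].astype(np.int64)
    if "MARKER" not in df.columns:
        df["MARKER"] = df["CHR"].astype(str) + ":" + df["POS"].astype(str)
    return df, n_dropped


def write_sumstats(records: pd.DataFrame, path) -> None:
    """Write records in the same tab-delimited dialect ``read_sumstats`` accepts."""
    cols = [c for c in CANONICAL_COLUMNS if c in records.columns]
    records.to_csv(path, sep="\t", index=False, columns=cols)


def _is_strand_ambiguous(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return ea.map(COMPLEMENT.get) == oa


def harmonize_markers(
    records: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    report: QCReport | None = None,
    max_ambiguous_eaf_diff: float = 0.2,
) -> pd.DataFrame:
    """Rename markers to ``chr:pos``, de-duplicate and align alleles.

    Marker identifiers are rewritten to the unique ``chromosome:position``
    form so that genome-wide imputed and targeted-chip panels overlap.
    Among duplicate positions within one study-stratum the record with the
    higher imputation quality wins (ties: lower input row index).

    If ``reference`` (columns MARKER, EA, OA and optionally EAF) is given,
    alleles are aligned to that consortium-wide orientation: a swapped
    record has its beta sign flipped and its EAF mirrored; records whose
    allele pair cannot be reconciled (directly, by swap, by strand flip, or
    by flipped swap) are excluded and counted.  Strand-ambiguous (A/T, C/G)
    markers are kept and flagged; when reference EAFs are available they are
    orientation-checked by frequency (|dEAF| < ``max_ambiguous_eaf_diff``).
    """
    if report is None:
        report = QCReport()
    df = records.copy()
    df["MARKER"] = df["CHR"].astype(str) + ":" + df["POS"].astype(str)

    if df["MARKER"].duplicated().any():
        quality = df["INFO"] if "INFO" in df.columns else pd.Series(1.0, index=df.index)
        order = pd.DataFrame({"q": quality.fillna(-1.0), "i": np.arange(len(df))})
        keep = (order.sort_values(["q", "i"], ascending=[False, True])
                .groupby(df["MARKER"].values, sort=False).head(1).index)
        report.duplicate += len(df) - len(keep)
        df = df.loc[sorted(keep)].reset_index(drop=True)

    df["AMBIGUOUS"] = _is_strand_ambiguous(df["EA"], df["OA"])

    if reference is not None:
        ref = reference.set_index("MARKER")
        idx = df["MARKER"]
        have = idx.isin(ref.index)
        ref_ea = idx.map(ref["EA"]).str.upper()
        ref_oa = idx.map(ref["OA"]).str.upper()
        same = (df["EA"] == ref_ea) & (df["OA"] == ref_oa)
        swap = (df["EA"] == ref_oa) & (df["OA"] == ref_ea)
        cea = df["EA"].map(COMPLEMENT.get)
        coa = df["OA"].map(COMPLEMENT.get)
        flip = (cea == ref_ea) & (coa == ref_oa) & ~df["AMBIGUOUS"]
        flipswap = (cea == ref_oa) & (coa == ref_ea) & ~df["AMBIGUOUS"]

        do_swap = have & (swap | flipswap)
        df.loc[do_swap, "BETA"] = -df.loc[do_swap, "BETA"]
        if "EAF" in df.columns:
            df.loc[do_swap, "EAF"] = 1.0 - df.loc[do_swap, "EAF"]
        df.loc[do_swap, ["EA", "OA"]] = df.loc[do_swap, ["OA", "EA"]].values
        renorm = have & (flip | flipswap)
        df.loc[renorm, "EA"] = df.loc[renorm, "MARKER"].map(ref["EA"])
        df.loc[renorm, "OA"] = df.loc[renorm, "MARKER"].map(ref["OA"])

        bad = have & ~(same | do_swap | flip)
        # ambiguous markers matching by identity or swap: EAF concordance check
        if "EAF" in ref.columns and "EAF" in df.columns:
            ref_eaf = idx.map(ref["EAF"])
            amb = df["AMBIGUOUS"] & have & ref_eaf.notna()
            bad |= amb & ((df["EAF"] - ref_eaf).abs() >= max_ambiguous_eaf_diff)
        report.incompatible_alleles += int(bad.sum())
        df = df.loc[~bad].reset_index(drop=True)

    return df


def apply_qc(
    records: pd.DataFrame,
    meta: StudyMeta,
    callrate_floor: float = 0.95,
    hwe_floor: float = 1e-5,
    mac_floor: float = 3.0,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the standard per-study marker filters.

    Removes, in order: monomorphic markers (EAF exactly 0 or 1); markers
    with ``min(EAF, 1-EAF) * N <= mac_floor`` (default 3, a minor-allele
    count floor); imputed markers below the software-specific quality floor
    (MACH r2 < 0.3, BIMBAM dosage-variance ratio < 0.3, IMPUTE info < 0.4,
    PLINK info < 0.8); and genotyped markers with call rate < 0.95 or a
    Hardy-Weinberg exact-test P < 1e-5.  The operation is idempotent.
    """
    report = QCReport(input_count=len(records))
    df = records.copy()
    eaf = df["EAF"] if "EAF" in df.columns else pd.Series(0.5, index=df.index)

    mono = (eaf <= 0.0) | (eaf >= 1.0)
    report.monomorphic = int(mono.sum())
    df, eaf = df.loc[~mono], eaf.loc[~mono]

    maf = np.minimum(eaf, 1.0 - eaf)
    low = maf * df["N"] <= mac_floor
    report.low_mac = int(low.sum())
    df, eaf = df.loc[~low], eaf.loc[~low]

    imputed = df["IMPUTED"].fillna(False).astype(bool) if "IMPUTED" in df.columns \
        else pd.Series(False, index=df.index)
    if imputed.any():
        software = (meta.imputation_software or "").upper()
        if software not in QUALITY_FLOORS:
            raise SumstatsError(
                f"imputed records present but imputation software "
                f"{meta.imputation_software!r} is not one of {sorted(QUALITY_FLOORS)}"
            )
        floor = QUALITY_FLOORS[software]
        qual = df["INFO"] if "INFO" in df.columns else pd.Series(np.nan, index=df.index)
        low_q = imputed & (qual.fillna(-np.inf) < floor)
        report.low_quality = int(low_q.sum())
        df, imputed = df.loc[~low_q], imputed.loc[~low_q]

    genotyped = ~imputed
    if genotyped.any():
        if "CALLRATE" in df.columns:
            low_cr = genotyped & (df["CALLRATE"] < callrate_floor)
            report.low_callrate = int(low_cr.sum())
            df, genotyped = df.loc[~low_cr], genotyped.loc[~low_cr]
        if "HWE_P" in df.columns:
            hwe = genotyped & (df["HWE_P"] < hwe_floor)
            report.hwe_failure = int(hwe.sum())
            df = df.loc[~hwe]

    unmappable = (df["CHR"] < 1) | (df["CHR"] > 22) | (df["POS"] < 1)
    report.unmappable = int(unmappable.sum())
    df = df.loc[~unmappable]

    report.retained = len(df)
    return df.reset_index(drop=True), report


def estimate_lambda(
    records: pd.DataFrame,
    subset: Sequence[str] | None = None,
    min_records: int = 100,
) -> float:
    """Genomic-control inflation factor.

    ``lambda = median((beta/se)^2) / median(chi2_1)``, estimated from all
    available markers (genome-wide panels) or from a supplied marker subset
    (targeted-chip panels, which lack a genome-wide null backbone).
    Returned unclamped; clamping at 1 is deferred to :func:`gc_correct`.
    """
    df = records
    if subset is not None:
        df = df[df["MARKER"].isin(set(subset))]
    if len(df) < min_records:
        raise SumstatsError(
            f"lambda estimation needs >= {min_records} markers, have {len(df)}"
        )
    z2 = (df["BETA"] / df["SE"]) ** 2
    return float(np.median(z2) / CHI2_1_MEDIAN)


def gc_correct(records: pd.DataFrame, lambda_gc: float) -> pd.DataFrame:
    """Genomic-control correction of SEs and P-values.

    With ``lam* = max(lambda_gc, 1)`` (no deflation correction):
    ``se -> se * sqrt(lam*)`` and the P-value is recomputed as the
    two-sided normal tail of ``beta / se``; betas are unchanged.
    """
    if not lambda_gc > 0:
        raise ValueError(f"lambda_gc must be positive, got {lambda_gc}")
    lam = max(float(lambda_gc), 1.0)
    df = records.copy()
    df["SE"] = df["SE"] * np.sqrt(lam)
    df["P"] = 2.0 * stats.norm.sf(np.abs(df["BETA"] / df["SE"]))
    return df
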
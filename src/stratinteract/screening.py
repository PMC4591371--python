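"""Genome-wide screens: FDR control, a-priori filtering, locus clumping
and effect-pattern classification.

Six interaction screens are defined (age-, sex- and age-by-sex-difference,
each with and without the a-priori filter restricting attention to markers
with overall association P below 1e-5) plus two main-effect screens (the
overall IVW test and the joint chi-square test) at genome-wide
significance.  The FDR of a filtered screen is controlled over the
filtered set: the filter is applied *before* the step-up procedure, so the
multiplicity burden reflects only the markers actually tested.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

#: screen name -> P-value column of the merged meta+interaction table
TEST_COLUMNS = {
    "agediff": "P_AGEDIFF",
    "sexdiff": "P_SEXDIFF",
    "agesexdiff": "P_AGESEXDIFF",
    "overall": "P_overall",
    "joint": "JOINT_P",
}

PATTERN_LABELS = (
    "stronger-in-women", "stronger-in-men", "opposite",
    "stronger-in-younger", "stronger-in-older", "opposite-by-age",
)


@dataclasses.dataclass
class ScreenSpec:
    """Configuration of one screen.

    ``prefilter`` is the a-priori threshold on the overall association
    P-value (None disables it); interaction screens use FDR control at
    ``fdr_q`` while main-effect screens use the fixed genome-wide
    ``threshold``.  ``clump_window`` is the physical distance (bp) for
    collapsing discoveries into loci.
    """

    test: str
    prefilter: float | None = None
    fdr_q: float | None = 0.05
    threshold: float | None = None
    clump_window: int = 500_000

    def __post_init__(self) -> None:
        if self.test not in TEST_COLUMNS:
            raise ValueError(
                f"unknown test {self.test!r}; choose from {sorted(TEST_COLUMNS)}"
            )
        if self.fdr_q is not None and not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.clump_window <= 0:
            raise ValueError("clump_window must be positive")


@dataclasses.dataclass
class Locus:
    """A clumped genomic region led by its most significant marker."""

    lead_marker: str
    chromosome: int
    start: int
    end: int
    members: list[str]
    lead_p: float
    novel: bool | None = None


@dataclasses.dataclass
class ScreenResult:
    spec: ScreenSpec
    n_tested: int
    table: pd.DataFrame            # tested markers with P, Q, SIGNIFICANT
    significant: pd.DataFrame      # significant subset
    loci: list[Locus]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the sorted P-values, so
    q-values are monotone in P and a marker is significant at level q
    exactly when its q-value is below q.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * p.size / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def clump_loci(markers: pd.DataFrame, window: int = 500_000,
               p_column: str = "P") -> list[Locus]:
    """Greedy physical-distance clumping.

    Repeatedly takes the lowest-P unassigned marker as a lead and absorbs
    all unassigned markers on the same chromosome strictly within
    ``window`` bp of it.  Ties on P are broken by lower position.
    """
    df = markers[["MARKER", "CHR", "POS", p_column]].copy()
    df = df.sort_values([p_column, "CHR", "POS"], kind="stable")
    loci: list[Locus] = []
    unassigned = df.copy()
    while not unassigned.empty:
        lead = unassigned.iloc[0]
        near = unassigned[(unassigned["CHR"] == lead["CHR"])
                          & ((unassigned["POS"] - lead["POS"]).abs() < window)]
        loci.append(Locus(
            lead_marker=str(lead["MARKER"]),
            chromosome=int(lead["CHR"]),
            start=int(near["POS"].min()),
            end=int(near["POS"].max()),
            members=list(near["MARKER"]),
            lead_p=float(lead[p_column]),
        ))
        unassigned = unassigned.drop(near.index)
    return loci


def flag_novelty(loci: list[Locus], known: pd.DataFrame,
                 window: int = 500_000) -> list[Locus]:
    """Mark each locus as novel unless its lead lies within ``window`` of a
    known-locus interval (columns CHR, START, END; 1-based inclusive)."""
    for locus in loci:
        rows = known[known["CHR"] == locus.chromosome]
        hit = ((rows["START"] - window < locus.end)
               & (rows["END"] + window > locus.start)).any() if len(rows) else False
        locus.novel = not bool(hit)
    return loci


def run_screen(merged: pd.DataFrame, spec: ScreenSpec,
               known: pd.DataFrame | None = None) -> ScreenResult:
    """Execute one screen on a merged meta+interaction marker table.

    The a-priori filter (if any) restricts the tested set to markers with
    ``P_overall`` below the filter threshold before multiplicity control,
    so the FDR denominator is the filtered count.  Discoveries are clumped
    into loci by physical distance.
    """
    col = TEST_COLUMNS[spec.test]
    if col not in merged.columns:
        raise ValueError(f"column {col!r} for test {spec.test!r} missing")
    tested = merged[merged[col].notna()]
    if spec.prefilter is not None:
        tested = tested[tested["P_overall"] < spec.prefilter]
    tested = tested.copy()

    if spec.threshold is not None:
        tested["Q"] = np.nan
        tested["SIGNIFICANT"] = tested[col] < spec.threshold
    else:
        tested["Q"] = bh_fdr(tested[col].to_numpy())
        tested["SIGNIFICANT"] = tested["Q"] < spec.fdr_q

    sig = tested[tested["SIGNIFICANT"]]
    loci = clump_loci(sig, window=spec.clump_window, p_column=col) if len(sig) else []
    if known is not None:
        loci = flag_novelty(loci, known, window=spec.clump_window)
    return ScreenResult(spec=spec, n_tested=len(tested), table=tested,
                        significant=sig.reset_index(drop=True), loci=loci)


def classify_pattern(beta_1, p_1, beta_2, p_2, axis: str = "sex",
                     alpha_within: float = 0.05) -> str:
    """Label the group pattern of one marker's effects.

    For ``axis='sex'`` group 1 is women and group 2 men; for ``axis='age'``
    group 1 is the younger and group 2 the older adults.  The marker is
    ``opposite`` when both groups are nominally significant
    (P < ``alpha_within``) with discordant signs; otherwise the group with
    the larger |beta| labels the direction (ties prefer group 1, i.e.
    women / younger).
    """
    if axis not in ("sex", "age"):
        raise ValueError("axis must be 'sex' or 'age'")
    labels = (("stronger-in-women", "stronger-in-men", "opposite") if axis == "sex"
              else ("stronger-in-younger", "stronger-in-older", "opposite-by-age"))
    both_sig = (p_1 < alpha_within) and (p_2 < alpha_within)
    if both_sig and np.sign(beta_1) * np.sign(beta_2) < 0:
        return labels[2]
    return labels[0] if abs(beta_1) >= abs(beta_2) else labels[1]


def default_screens(fdr_q: float = 0.05, prefilter: float = 1e-5,
                    gw_threshold: float = 5e-8,
                    clump_window: int = 500_000) -> list[ScreenSpec]:
    """The standard battery: six interaction screens (three tests, with and
    without the a-priori filter) plus the two main-effect screens."""
    specs = []
    for test in ("agediff", "sexdiff", "agesexdiff"):
        specs.append(ScreenSpec(test=test, prefilter=prefilter, fdr_q=fdr_q,
                                clump_window=clump_window))
        specs.append(ScreenSpec(test=test, prefilter=None, fdr_q=fdr_q,
                                clump_window=clump_window))
    for test in ("overall", "joint"):
        specs.append(ScreenSpec(test=test, prefilter=None, fdr_q=None,
                                threshold=gw_threshold, clump_window=clump_window))
    return specs
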
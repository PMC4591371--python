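"""Synthetic multi-study, four-stratum GWAS summary statistics with the
statistical structure the analysis pipeline assumes.

The default sampling model works at the summary level, mirroring the
consortium workflow: each study-stratum reports, for every marker on its
panel, an effect estimate drawn from ``Normal(true effect,
expected_se(maf, n))`` with optional genomic inflation applied by scaling
the sampling noise by ``sqrt(lambda)``.  True per-stratum effects are the
sum of planted single-marker scenarios and an optional polygenic
background whose between-group correlation (same sex across age groups,
same age group across sexes) induces the genome-wide effect correlations
the difference tests adjust for.

A miniature individual-level path exists to validate the phenotype
transformation and per-stratum regression contract; it is an accessory,
not the scale path.

All randomness flows from a single master seed; every operation is
bit-reproducible per (seed, study, stratum).
"""

from __future__ import annotations

import dataclasses
import pathlib
import zlib
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .power import Scenario, beta_from_r2, expected_se
from .screening import classify_pattern
from .sumstats import STRATA, Panel, StudyMeta

_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclasses.dataclass
class StudySpec:
    """One study's roster entry: sample sizes and panel characteristics."""

    study_id: str
    n_per_stratum: dict[str, int]
    panel: Panel = Panel.GENOME_WIDE
    imputation_software: str = "MACH"
    ascertainment: str = "population-based"
    self_report: bool = False
    target_lambda: float = 1.0

    def meta(self, stratum: str) -> StudyMeta:
        return StudyMeta(
            study_id=self.study_id, stratum=stratum, panel=self.panel,
            imputation_software=(self.imputation_software
                                 if self.panel is Panel.GENOME_WIDE else None),
            ascertainment=self.ascertainment, self_report=self.self_report)


@dataclasses.dataclass
class SimConfig:
    """Configuration of a simulated consortium.

    ``planted`` maps marker indices (or uses rng placement when given as a
    bare list) to four-stratum true effect tuples in the stratum order
    ``(M_le50, M_gt50, F_le50, F_gt50)``.  ``rho_age``/``rho_sex`` shape
    the correlation of the polygenic background between age groups of the
    same sex and between sexes of the same age group respectively.
    """

    studies: list[StudySpec]
    n_markers: int = 5_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    planted: Sequence[tuple[float, float, float, float]] = ()
    polygenic_sd: float = 0.0
    rho_age: float = 0.0
    rho_sex: float = 0.0
    chip_marker_fraction: float = 0.4
    marker_spacing: int = 1_000_000
    quality_range: tuple[float, float] = (0.85, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("study roster must be nonempty")
        for rho in (self.rho_age, self.rho_sex):
            if not -1.0 <= rho <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")

    def total_n(self, stratum: str) -> int:
        return sum(s.n_per_stratum.get(stratum, 0) for s in self.studies)


def _rng_for(seed: int, *tokens) -> np.random.Generator:
    """Deterministic child generator keyed by seed and string/int tokens."""
    parts = [int(seed) % (2**31)]
    for t in tokens:
        if isinstance(t, str):
            parts.append(zlib.crc32(t.encode()) % (2**31))
        else:
            parts.append(int(t) % (2**31))
    return np.random.default_rng(parts)


def _pattern_label(betas: tuple[float, float, float, float]) -> str:
    """Noise-free pattern of a planted effect: the sex axis labels any
    sex-asymmetric configuration, else the age axis, else 'null'."""
    b_m = (betas[0] + betas[1]) / 2.0
    b_f = (betas[2] + betas[3]) / 2.0
    b_y = (betas[0] + betas[2]) / 2.0
    b_o = (betas[1] + betas[3]) / 2.0
    if not np.allclose(betas, 0.0):
        def p(b):  # noise-free limit: any nonzero effect is significant
            return 0.0 if abs(b) > 1e-12 else 1.0
        if abs(b_m - b_f) > 1e-12:
            return classify_pattern(b_f, p(b_f), b_m, p(b_m), axis="sex")
        if abs(b_y - b_o) > 1e-12:
            return classify_pattern(b_y, p(b_y), b_o, p(b_o), axis="age")
        return "uniform"
    return "null"


def make_truth(config: SimConfig) -> pd.DataFrame:
    """Per-marker ground truth: map positions, MAFs, alleles and the true
    four-stratum effects (recorded before any sampling noise)."""
    rng = _rng_for(config.seed, "truth")
    m = config.n_markers
    chrom = 1 + (np.arange(m) * 22) // m
    # restart positions on each chromosome, one marker per spacing unit
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, 23):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 1_000_000 + np.arange(idx.size) * config.marker_spacing
    maf = rng.uniform(*config.maf_range, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)

    betas = np.zeros((m, 4))
    if config.polygenic_sd > 0:
        r_age = np.array([[1.0, config.rho_age], [config.rho_age, 1.0]])
        r_sex = np.array([[1.0, config.rho_sex], [config.rho_sex, 1.0]])
        # stratum order (M_le50, M_gt50, F_le50, F_gt50) = sex (x) age
        cov = np.kron(r_sex, r_age) * config.polygenic_sd**2
        chol = np.linalg.cholesky(cov)
        betas += rng.standard_normal((m, 4)) @ chol.T

    causal = np.zeros(m, dtype=bool)
    if len(config.planted):
        slots = rng.choice(m, size=len(config.planted), replace=False)
        for slot, b in zip(np.sort(slots), config.planted):
            betas[slot] += np.asarray(b, dtype=float)
            causal[slot] = True

    truth = pd.DataFrame({
        "MARKER": [f"{c}:{p}" for c, p in zip(chrom, pos)],
        "CHR": chrom, "POS": pos,
        "EA": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "OA": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "MAF": maf,
        "B_M_le50": betas[:, 0], "B_M_gt50": betas[:, 1],
        "B_F_le50": betas[:, 2], "B_F_gt50": betas[:, 3],
        "CAUSAL": causal,
    })
    truth["PATTERN"] = [
        _pattern_label(tuple(b)) for b in betas
    ]
    return truth


def _chip_marker_mask(config: SimConfig) -> np.ndarray:
    """Targeted-chip panels carry a fixed random subset of the marker map,
    shared by all chip studies (panel overlap is by construction)."""
    rng = _rng_for(config.seed, "chip-panel")
    m = config.n_markers
    k = int(round(config.chip_marker_fraction * m))
    mask = np.zeros(m, dtype=bool)
    mask[rng.choice(m, size=k, replace=False)] = True
    return mask


def simulate_summary_study(
    config: SimConfig,
    truth: pd.DataFrame,
    study: StudySpec,
    stratum: str,
) -> pd.DataFrame:
    """Summary statistics of one study-stratum, in the upload dialect.

    Effect estimates are drawn around the stratum's true effects with the
    closed-form SE for the study's sample size; genomic inflation scales
    the sampling noise (not the reported SE) by ``sqrt(target_lambda)``,
    so the z-scores carry the inflation.  Reported EAFs add binomial
    sampling noise at 2n allele draws.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    n = study.n_per_stratum.get(stratum, 0)
    if n <= 0:
        raise ValueError(f"{study.study_id} has no samples in {stratum}")
    rng = _rng_for(config.seed, study.study_id, stratum)

    rows = truth
    if study.panel is Panel.TARGETED_CHIP:
        rows = truth.loc[_chip_marker_mask(config)]
    maf = rows["MAF"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    true_b = rows[f"B_{stratum}"].to_numpy()
    beta_hat = true_b + rng.normal(0.0, se) * np.sqrt(study.target_lambda)
    eaf_hat = rng.binomial(2 * n, maf) / (2.0 * n)

    df = pd.DataFrame({
        "MARKER": rows["MARKER"].to_numpy(),
        "CHR": rows["CHR"].to_numpy(), "POS": rows["POS"].to_numpy(),
        "EA": rows["EA"].to_numpy(), "OA": rows["OA"].to_numpy(),
        "EAF": eaf_hat, "BETA": beta_hat, "SE": se,
        "P": 2.0 * stats.norm.sf(np.abs(beta_hat / se)),
        "N": np.int64(n),
        "INFO": rng.uniform(*config.quality_range, size=len(rows)),
        "IMPUTED": study.panel is Panel.GENOME_WIDE,
        "CALLRATE": rng.uniform(0.97, 1.0, size=len(rows)),
        "HWE_P": rng.uniform(1e-4, 1.0, size=len(rows)),
    })
    return df


def simulate_consortium(
    config: SimConfig,
    out_dir: str | pathlib.Path | None = None,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """All study-stratum tables plus the ground-truth table.

    With ``out_dir`` set, one tab-delimited file per study-stratum
    (``<study>.<stratum>.tsv``) and a ``TRUTH.tsv`` table are written in
    the summary-statistics dialect.
    """
    truth = make_truth(config)
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for study in config.studies:
        for stratum in STRATA:
            if study.n_per_stratum.get(stratum, 0) > 0:
                tables[(study.study_id, stratum)] = simulate_summary_study(
                    config, truth, study, stratum)
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (sid, stratum), df in tables.items():
            df.to_csv(out / f"{sid}.{stratum}.tsv", sep="\t", index=False)
        truth.to_csv(out / "TRUTH.tsv", sep="\t", index=False)
    return tables, truth


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offsets)."""
    v = np.asarray(values, dtype=float)
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.375) / (v.size + 0.25))


def simulate_individual_study(
    n_per_stratum: int,
    mafs: Sequence[float],
    betas: Sequence[tuple[float, float, float, float]],
    seed: int = 0,
    study_id: str = "IND",
) -> dict[str, pd.DataFrame]:
    """Miniature individual-level study with the full analysis contract.

    For each stratum: genotypes are binomial(2, maf) draws, the raw trait
    adds linear and quadratic age terms plus unit noise, residuals on
    (1, age, age^2) are inverse-normal transformed within stratum, and
    each marker is tested by additive linear regression.  Returns one
    summary table per stratum whose (beta, se) obey the closed-form
    ``expected_se`` model within sampling error.
    """
    if n_per_stratum > 5_000:
        raise ValueError("individual-level path is a validation accessory; "
                         "use the summary-level simulator at scale")
    mafs = np.asarray(mafs, dtype=float)
    b = np.asarray(betas, dtype=float)            # (n_markers, 4)
    rng = np.random.default_rng([int(seed) % (2**31), zlib.crc32(study_id.encode())])
    out = {}
    for si, stratum in enumerate(STRATA):
        n = n_per_stratum
        age = (rng.uniform(18, 50, n) if "le50" in stratum
               else rng.uniform(50.0001, 90, n))
        geno = rng.binomial(2, mafs, size=(n, mafs.size)).astype(float)
        pheno = (geno @ b[:, si]
                 + 0.02 * age + 1e-4 * age**2 + rng.standard_normal(n))
        design = np.column_stack([np.ones(n), age, age**2])
        resid = pheno - design @ np.linalg.lstsq(design, pheno, rcond=None)[0]
        y = rank_inverse_normal(resid)
        records = []
        for j in range(mafs.size):
            g = geno[:, j]
            gc = g - g.mean()
            sxx = float(gc @ gc)
            beta_hat = float(gc @ y / sxx)
            resid_y = y - y.mean() - beta_hat * gc
            sigma2 = float(resid_y @ resid_y) / (n - 2)
            se = float(np.sqrt(sigma2 / sxx))
            tstat = beta_hat / se
            records.append({
                "MARKER": f"1:{1_000_000 + j * 1_000_000}",
                "CHR": 1, "POS": 1_000_000 + j * 1_000_000,
                "EA": "A", "OA": "G", "EAF": g.mean() / 2.0,
                "BETA": beta_hat, "SE": se,
                "P": 2.0 * stats.t.sf(abs(tstat), df=n - 2),
                "N": n, "IMPUTED": False, "CALLRATE": 1.0, "HWE_P": 0.5,
            })
        out[stratum] = pd.DataFrame(records)
        out[stratum]["PHENO_MEAN"] = float(y.mean())
        out[stratum]["PHENO_VAR"] = float(y.var(ddof=1))
    return out


#: anchor effect: an established body-size locus of medium effect,
#: R^2 = 0.037% at maf 0.5 -> |b| = 0.0272 in SD units ... the heat-grid
#: convention instead fixes b = 0.033 directly.
ANCHOR_BETA = 0.033


def preset_scenarios(total_n: float = 300_000, maf: float = 0.5,
                     beta: float = ANCHOR_BETA) -> dict[str, Scenario]:
    """The five named interaction configurations used in the power grids.

    All use four equally sized strata.  Stratum order of the beta tuples is
    ``(M_le50, M_gt50, F_le50, F_gt50)``.
    """
    b = float(beta)
    make = Scenario.equal_strata
    return {
        "pure-age": make((b, 0.0, b, 0.0), total_n, maf, "pure-age",
                         "effect in both sexes below 50y, none above"),
        "pure-sex": make((0.0, 0.0, b, b), total_n, maf, "pure-sex",
                         "effect in women of both age groups, none in men"),
        "opposite-sex": make((-b, -b, b, b), total_n, maf, "opposite-sex",
                             "opposite effect directions in women vs men"),
        "extreme-three-way": make((-b, 0.0, b, -b), total_n, maf,
                                  "extreme-three-way",
                                  "opposite directions across age and sex"),
        "1-stratum": make((0.0, 0.0, b, 0.0), total_n, maf, "1-stratum",
                          "effect only in women below 50y"),
        "3-strata": make((b, 0.0, b, b), total_n, maf, "3-strata",
                         "effect in all strata except men above 50y"),
    }


def women_specific_config(
    n_loci: int = 20,
    r2_range: tuple[float, float] = (0.0002, 0.0008),
    n_markers: int = 5_000,
    n_per_stratum_total: int = 150_000,
    n_studies: int = 6,
    n_opposite: int = 1,
    seed: int = 0,
) -> SimConfig:
    """A consortium with women-only planted loci (sex-specific effects of
    realistic explained variance) plus ``n_opposite`` loci of equal
    magnitude but opposite direction in men versus women — the latter
    cancel in the overall association and are reachable only by the
    unfiltered sex-difference screen.  Used for end-to-end recovery runs."""
    rng = np.random.default_rng([int(seed) % (2**31), 7])
    planted = []
    maf = 0.5  # effects stated via R2 at the truth MAF below
    for _ in range(n_loci):
        r2 = rng.uniform(*r2_range)
        b = beta_from_r2(r2, maf)
        planted.append((0.0, 0.0, b, b))
    for _ in range(n_opposite):
        b = beta_from_r2(r2_range[1], maf)
        planted.append((-b, -b, b, b))
    per_study = n_per_stratum_total // n_studies
    studies = [
        StudySpec(study_id=f"STUDY{i+1}",
                  n_per_stratum={s: per_study for s in STRATA})
        for i in range(n_studies)
    ]
    return SimConfig(studies=studies, n_markers=n_markers,
                     maf_range=(0.5, 0.5), planted=planted,
                     polygenic_sd=0.0, seed=seed)
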
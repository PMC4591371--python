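"""Model/Results front end for the stratified interaction meta-analysis.

:class:`StratifiedGWAMA` holds the per-study, per-stratum summary
statistics of a consortium; :meth:`StratifiedGWAMA.fit` runs the full
pipeline — marker harmonisation, per-study QC, genomic-control
correction, inverse-variance pooling across studies and across the
stratum hierarchy, the joint 4-df test, the post-meta sample-size
filter, and the three correlation-adjusted interaction statistics —
returning a :class:`StratifiedGWAMAResults` carrying the marker-level
tables, the correlation and inflation estimates and the QC diagnostics.
Screens, explained-variance summaries and pattern classification hang
off the results object.
"""

from __future__ import annotations

import textwrap

import numpy as np
import pandas as pd

from . import interaction as _interaction
from . import meta as _meta
from . import sumstats as _sumstats
from .downstream import VarExpResult, group_r2_difference, group_r2_sum
from .screening import (ScreenResult, ScreenSpec, classify_pattern,
                        default_screens, run_screen)
from .sumstats import STRATA, Panel, QCReport, StudyMeta


class StratifiedGWAMA:
    """Four-stratum GWAS meta-analysis of a multi-study consortium.

    Parameters
    ----------
    study_tables
        ``{(study_id, stratum): DataFrame}`` in the canonical
        summary-statistics dialect (see :mod:`stratinteract.sumstats`).
    study_metas
        ``{(study_id, stratum): StudyMeta}`` describing each table.
    reference
        Optional consortium-wide allele orientation (MARKER, EA, OA
        [, EAF]) used during harmonisation.
    lambda_subsets
        Optional ``{study_id: marker list}`` restricting inflation-factor
        estimation (targeted-chip panels lack a genome-wide null backbone
        and use a designated null marker subset).
    """

    def __init__(
        self,
        study_tables: dict[tuple[str, str], pd.DataFrame],
        study_metas: dict[tuple[str, str], StudyMeta],
        reference: pd.DataFrame | None = None,
        lambda_subsets: dict[str, list[str]] | None = None,
    ) -> None:
        if not study_tables:
            raise ValueError("no study tables supplied")
        missing = set(study_tables) - set(study_metas)
        if missing:
            raise ValueError(f"missing StudyMeta for {sorted(missing)}")
        self.study_tables = study_tables
        self.study_metas = study_metas
        self.reference = reference
        self.lambda_subsets = lambda_subsets or {}

    # ------------------------------------------------------------------
    @classmethod
    def from_files(cls, manifest: list[dict],
                   reference: pd.DataFrame | None = None) -> "StratifiedGWAMA":
        """Build from a manifest of file entries.

        Each entry needs ``study_id``, ``stratum`` and ``path`` and may
        carry ``panel``, ``imputation_software``, ``lambda_gc``,
        ``ascertainment``, ``self_report`` and ``column_map``.
        """
        tables, metas = {}, {}
        for entry in manifest:
            meta = StudyMeta(
                study_id=entry["study_id"], stratum=entry["stratum"],
                panel=Panel(entry.get("panel", Panel.GENOME_WIDE)),
                imputation_software=entry.get("imputation_software"),
                lambda_gc=entry.get("lambda_gc"),
                ascertainment=entry.get("ascertainment", "population-based"),
                self_report=bool(entry.get("self_report", False)))
            df, _ = _sumstats.read_sumstats(entry["path"],
                                            entry.get("column_map"))
            key = (meta.study_id, meta.stratum)
            tables[key], metas[key] = df, meta
        return cls(tables, metas, reference=reference)

    @classmethod
    def from_simulation(cls, config, tables=None, truth=None) -> "StratifiedGWAMA":
        """Build directly from a :class:`~stratinteract.simulate.SimConfig`."""
        from .simulate import simulate_consortium
        if tables is None:
            tables, truth = simulate_consortium(config)
        metas = {}
        by_id = {s.study_id: s for s in config.studies}
        for (sid, stratum) in tables:
            metas[(sid, stratum)] = by_id[sid].meta(stratum)
        model = cls(tables, metas)
        model.truth = truth
        return model

    # ------------------------------------------------------------------
    def select_studies(self, predicate) -> "StratifiedGWAMA":
        """Sensitivity-analysis subset: keep study-strata whose
        :class:`StudyMeta` satisfies ``predicate`` (e.g. population-based
        only, or measured-anthropometry only)."""
        keys = [k for k, m in self.study_metas.items() if predicate(m)]
        if not keys:
            raise ValueError("predicate removed every study")
        return StratifiedGWAMA(
            {k: self.study_tables[k] for k in keys},
            {k: self.study_metas[k] for k in keys},
            reference=self.reference, lambda_subsets=self.lambda_subsets)

    # ------------------------------------------------------------------
    def fit(
        self,
        qc: bool = True,
        gc: bool = True,
        r_age: float | None = None,
        r_sex: float | None = None,
        post_filter: bool = True,
        min_lambda_markers: int = 100,
        correlation_floor: int = 100,
    ) -> "StratifiedGWAMAResults":
        """Run the pipeline and return the fitted results.

        ``r_age`` / ``r_sex`` override the genome-wide Spearman effect
        correlations (estimated from the pooled tables when ``None``).
        Studies whose marker count falls below ``min_lambda_markers``
        skip inflation estimation and are left uncorrected unless their
        metadata supplies ``lambda_gc``.
        """
        qc_reports: dict[tuple[str, str], QCReport] = {}
        lambdas: dict[tuple[str, str], float] = {}
        per_stratum: dict[str, list[pd.DataFrame]] = {s: [] for s in STRATA}

        for key, raw in self.study_tables.items():
            meta = self.study_metas[key]
            report = QCReport(input_count=len(raw))
            df = _sumstats.harmonize_markers(raw, reference=self.reference,
                                             report=report)
            if qc:
                df, qrep = _sumstats.apply_qc(df, meta)
                for field in ("monomorphic", "low_mac", "low_quality",
                              "low_callrate", "hwe_failure", "unmappable"):
                    setattr(report, field, getattr(qrep, field))
            report.retained = len(df)
            qc_reports[key] = report

            lam = meta.lambda_gc
            if gc:
                if lam is None and len(df) >= min_lambda_markers:
                    subset = self.lambda_subsets.get(meta.study_id)
                    lam = _sumstats.estimate_lambda(df, subset=subset,
                                                    min_records=min_lambda_markers)
                lam = 1.0 if lam is None else lam
                df = _sumstats.gc_correct(df, lam)
            lambdas[key] = float(lam if lam is not None else 1.0)
            per_stratum[meta.stratum].append(df)

        stratum_tables = {
            s: _meta.pool_study_tables(tbls)
            for s, tbls in per_stratum.items() if tbls
        }
        if not stratum_tables:
            raise ValueError("no strata with data after QC")
        meta_table = _meta.pool_strata(stratum_tables)
        if post_filter:
            meta_table = _meta.post_meta_filter(meta_table)

        inter, corr = _interaction.interaction_table(
            meta_table, r_age=r_age, r_sex=r_sex,
            correlation_floor=correlation_floor)

        return StratifiedGWAMAResults(
            model=self, meta=meta_table, interactions=inter,
            correlations=corr, lambdas=lambdas, qc_reports=qc_reports)


class StratifiedGWAMAResults:
    """Fitted marker-level results of a :class:`StratifiedGWAMA`.

    Attributes
    ----------
    meta
        Wide per-marker table with BETA/SE/P/N at all nine hierarchy
        levels plus the joint chi-square test.
    interactions
        Per-marker age-, sex- and age-by-sex difference statistics.
    correlations
        The genome-wide Spearman effect correlations used.
    lambdas
        Genomic-control inflation factor per study-stratum.
    """

    def __init__(self, model, meta, interactions, correlations, lambdas,
                 qc_reports) -> None:
        self.model = model
        self.meta = meta
        self.interactions = interactions
        self.correlations = correlations
        self.lambdas = lambdas
        self.qc_reports = qc_reports
        self._merged = None

    @property
    def merged(self) -> pd.DataFrame:
        """Meta and interaction tables joined on MARKER."""
        if self._merged is None:
            self._merged = self.meta.merge(self.interactions, on="MARKER",
                                           how="left")
        return self._merged

    # ------------------------------------------------------------------
    def screen(self, test: str, prefilter: float | None = None,
               fdr_q: float | None = 0.05, threshold: float | None = None,
               clump_window: int = 500_000,
               known: pd.DataFrame | None = None) -> ScreenResult:
        """Run one screen (see :class:`~stratinteract.screening.ScreenSpec`)."""
        spec = ScreenSpec(test=test, prefilter=prefilter, fdr_q=fdr_q,
                          threshold=threshold, clump_window=clump_window)
        return run_screen(self.merged, spec, known=known)

    def run_default_screens(self, known: pd.DataFrame | None = None,
                            **kwargs) -> dict[str, ScreenResult]:
        """The standard battery of six interaction screens and two
        main-effect screens, keyed ``<test>[+filter]``."""
        out = {}
        for spec in default_screens(**kwargs):
            name = spec.test + ("+filter" if spec.prefilter is not None else "")
            out[name] = run_screen(self.merged, spec, known=known)
        return out

    def classify(self, markers, axis: str = "sex",
                 alpha_within: float = 0.05) -> pd.Series:
        """Effect-pattern labels for the given markers along one axis."""
        rows = self.meta.set_index("MARKER").loc[list(markers)]
        cols = (("BETA_F", "P_F", "BETA_M", "P_M") if axis == "sex"
                else ("BETA_le50", "P_le50", "BETA_gt50", "P_gt50"))
        return pd.Series(
            [classify_pattern(r[cols[0]], r[cols[1]], r[cols[2]], r[cols[3]],
                              axis=axis, alpha_within=alpha_within)
             for _, r in rows.iterrows()],
            index=rows.index, name="PATTERN")

    def explained_variance(self, group: str, threshold: float = 5e-8,
                           clump_window: int = 500_000,
                           n_bootstrap: int = 1_000,
                           seed: int = 0) -> VarExpResult:
        return group_r2_sum(self.meta, group, threshold=threshold,
                            clump_window=clump_window,
                            n_bootstrap=n_bootstrap, seed=seed)

    def explained_variance_difference(self, group_a: str, group_b: str,
                                      **kwargs) -> dict:
        return group_r2_difference(self.meta, group_a, group_b, **kwargs)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable overview of the fit."""
        m = self.meta
        lam = np.array(list(self.lambdas.values()))
        n_sig = int((m["P_overall"] < 5e-8).sum())
        lines = [
            "Stratified GWAS interaction meta-analysis",
            "=" * 45,
            f"study-stratum inputs : {len(self.model.study_tables)}",
            f"markers analysed     : {len(m)}",
            f"lambda_gc (min/med/max): "
            f"{lam.min():.3f} / {np.median(lam):.3f} / {lam.max():.3f}",
            f"r_age / r_sex        : {self.correlations['r_age']:.3f} / "
            f"{self.correlations['r_sex']:.3f}",
            f"genome-wide significant (P_overall < 5e-8): {n_sig}",
            "",
            "per-stratum sample sizes (max over markers):",
        ]
        for s in STRATA:
            col = m[f"N_{s}"]
            if col.notna().any():
                lines.append(f"  {s:8s}: {int(np.nanmax(col)):>10,d}")
        return textwrap.indent("\n".join(lines), "")

    def to_csv(self, path) -> None:
        self.merged.to_csv(path, sep="\t", index=False)
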
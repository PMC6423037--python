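"""End-to-end orchestration: curves -> N0 -> corrected ratios -> screening.

``run_pipeline`` drives every stage in order (optionally starting from a
simulated study), writes machine-readable outputs, and returns a
:class:`ScreenReport` whose biomarker panel and suspicious-sample list
are what a residue-control laboratory would act on.  ``screen_unknowns``
applies a fitted model to new milk samples: a sample is suspicious when
its predictive score exceeds the control population's 95th percentile.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StudyDesign, build_dose_schedule
from .simulate import SimulationConfig, simulate_expression, simulate_curves, simulate_yield
from .curves import quantify_plate
from .sessions import between_session_ratio_matrix, estimate_factors, apply_factors
from .bestkeeper import validate_references
from .expression import (REFERENCE_GENES, expression_records, assemble_matrix,
                         apply_inclusion_filter, ExpressionMatrix)
from .univariate import gene_day_comparisons, cycle_yield_table
from .multivariate import (preprocess, PCA, flag_outliers, OPLSDA,
                           rank_biomarkers, PreprocessedMatrix, OPLSDAResults)

log = logging.getLogger("rbstscreen")

__all__ = ["PipelineConfig", "ScreenReport", "run_pipeline",
           "screen_expression_matrix", "screen_unknowns"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one expression source must be active: ``simulate`` (generate
    a synthetic study), ``curves_csv`` (raw fluorescence) or ``n0_csv``
    (pre-computed N0 values with flags).
    """

    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    simulate: bool = False
    sim_config: SimulationConfig | None = None
    curves_csv: str | None = None
    n0_csv: str | None = None
    yields_csv: str | None = None
    outdir: str | None = None
    # thresholds
    efficiency_max_deviation: float = 0.05
    #: gene-level inclusion: genes detected in fewer than
    #: (100 - max_missing_pct)% of samples are treated as systematically
    #: undetected and dropped; the strict 0%-missing rule then applies to
    #: samples.  10% tolerates sporadic technical well failures in raw
    #: curve data; set 0 for structurally complete (pre-tabulated) input.
    max_missing_pct: float = 10.0
    alpha: float = 0.05
    pcorr_threshold: float = 0.4
    pca_components: int = 2
    folds: int = 7
    exclude_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sources = [self.simulate, self.curves_csv is not None,
                   self.n0_csv is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one of simulate/curves_csv/n0_csv "
                             "must be the expression source")
        if self.simulate and self.sim_config is None:
            self.sim_config = SimulationConfig(seed=self.seed,
                                               design=self.design)


@dataclass
class ScreenReport:
    counts: dict
    reference_verdicts: dict
    stability: pd.DataFrame | None
    univariate: pd.DataFrame
    yield_table: pd.DataFrame | None
    multivariate_summary: pd.DataFrame
    s_plot: pd.DataFrame
    panel: tuple[str, ...]
    outliers: dict
    suspicious_samples: tuple[str, ...]

    def to_json_dict(self) -> dict:
        return {
            "counts": self.counts,
            "reference_verdicts": self.reference_verdicts,
            "panel": list(self.panel),
            "outliers": self.outliers,
            "suspicious_samples": list(self.suspicious_samples),
            "multivariate": self.multivariate_summary.iloc[0].to_dict(),
        }


def _cq_table_from_fits(fits: pd.DataFrame) -> pd.DataFrame:
    ok = fits[fits["flag"] == "ok"]
    return ok.rename(columns={"cq": "cq"})[["sample", "gene", "cq"]]


def screen_expression_matrix(matrix: ExpressionMatrix, config: PipelineConfig
                             ) -> tuple[PreprocessedMatrix, OPLSDAResults,
                                        dict, pd.DataFrame]:
    """PCA outlier rejection + OPLS-DA on a filtered expression matrix.

    Returns (preprocessed matrix after outlier removal, fitted OPLS-DA
    results, outlier report dict, S-plot ranking table).
    """
    prep = preprocess(matrix.values, matrix.metadata["group"])
    pca = PCA(prep.X, n_components=min(config.pca_components,
                                       min(prep.X.shape) - 1)).fit()
    out = flag_outliers(pca, alpha=config.alpha)
    keep = [s for s in prep.X.index if s not in out.excluded]
    clean_vals = matrix.values.loc[keep]
    prep2 = preprocess(clean_vals, matrix.metadata.loc[keep, "group"])
    opls = OPLSDA(prep2.X, prep2.y, folds=config.folds).fit()
    splot = rank_biomarkers(opls.s_plot(), config.pcorr_threshold)
    return prep2, opls, out.to_dict(), splot


def run_pipeline(config: PipelineConfig) -> ScreenReport:
    """Execute every stage and return the screening report."""
    counts: dict = {}
    design = config.design
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def _save(df: pd.DataFrame, name: str) -> None:
        if outdir is not None and df is not None:
            df.to_csv(outdir / name, index=False)

    # -- stage 1: expression source ------------------------------------
    yields = None
    stability_df = None
    reference_verdicts: dict = {}
    if config.simulate:
        sim = config.sim_config
        design = sim.design
        log.info("simulating study (seed=%d)", sim.seed)
        expression_truth = simulate_expression(sim)
        curves = simulate_curves(expression_truth, sim)
        yields = simulate_yield(sim)
        counts["curves"] = int(curves["well"].nunique())
        _save(curves, "curves.csv")
        _save(yields, "yields.csv")
        fits, amplicons = quantify_plate(curves,
                                         config.efficiency_max_deviation)
    elif config.curves_csv:
        curves = pd.read_csv(config.curves_csv)
        counts["curves"] = int(curves["well"].nunique())
        fits, amplicons = quantify_plate(curves,
                                         config.efficiency_max_deviation)
        if config.yields_csv:
            yields = pd.read_csv(config.yields_csv)
    else:
        fits = pd.read_csv(config.n0_csv)
        amplicons = None
        if config.yields_csv:
            yields = pd.read_csv(config.yields_csv)

    counts["wells_fit"] = len(fits)
    counts["wells_ok"] = int((fits["flag"] == "ok").sum())
    _save(fits, "well_fits.csv")
    if amplicons is not None:
        _save(amplicons, "amplicon_efficiency.csv")
    log.info("quantified %d wells (%d ok)", counts["wells_fit"],
             counts["wells_ok"])

    # -- stage 2: session correction -----------------------------------
    ok = fits[(fits["flag"] == "ok") & fits["n0"].notna()].copy()
    meta_cols = [c for c in ("animal", "group", "day") if c in ok.columns]
    if "session" in ok.columns and ok["session"].nunique() > 1:
        ratio = between_session_ratio_matrix(ok, value="n0")
        factors = estimate_factors(ratio)
        ok = apply_factors(ok, factors, value="n0")
        if outdir is not None:
            factors.to_frame().to_csv(outdir / "session_factors.csv",
                                      index=False)
        counts["sessions"] = len(factors.factors)

    # -- stage 3: reference stability ----------------------------------
    if "cq" in ok.columns:
        cq = ok[ok["gene"].isin(REFERENCE_GENES)][["sample", "gene", "cq"]]
        if not cq.empty:
            bk = validate_references(cq, list(REFERENCE_GENES))
            reference_verdicts = {
                g: {"dev": s.dev, "sd": s.sd, "cv": s.cv,
                    "r": bk.correlations[g][0],
                    "consistent": s.consistent,
                    "recommended": g in bk.recommended}
                for g, s in bk.stabilities.items()}
            stability_df = pd.DataFrame(
                [{"gene": g, **v} for g, v in reference_verdicts.items()])
            _save(stability_df, "reference_stability.csv")

    # -- stage 4: relative expression + inclusion filter ----------------
    records = expression_records(ok)
    counts["expression_records"] = len(records)
    matrix = assemble_matrix(records, design)
    counts["samples_assembled"] = len(matrix.samples)
    filtered, freport = apply_inclusion_filter(
        matrix, config.max_missing_pct, config.exclude_genes)
    counts["genes_retained"] = len(freport.genes_retained)
    counts["samples_retained"] = freport.samples_retained
    if outdir is not None:
        filtered.values.to_csv(outdir / "expression_matrix.csv")
        (outdir / "filter_report.json").write_text(
            json.dumps(freport.to_dict(), indent=2))
    log.info("inclusion filter: %d genes, %d samples retained",
             counts["genes_retained"], counts["samples_retained"])

    # -- stage 5: univariate -------------------------------------------
    uni = gene_day_comparisons(records)
    _save(uni, "univariate.csv")
    ytab = None
    if yields is not None:
        ytab = cycle_yield_table(yields, design)
        _save(ytab, "cycle_yields.csv")

    # -- stage 6: multivariate + screening ------------------------------
    prep, opls, outliers, splot = screen_expression_matrix(filtered, config)
    counts["samples_multivariate"] = len(prep.X)
    counts["outliers_excluded"] = len(outliers["excluded"])
    panel = tuple(splot.loc[splot["in_panel"], "gene"])
    control_scores = opls.scores[prep.y == 0]
    threshold = float(np.percentile(control_scores, 95))
    suspicious = tuple(opls.scores.index[(opls.scores > threshold)
                                         & (prep.y == 1)])
    _save(splot, "s_plot.csv")
    summary = opls.summary()
    if outdir is not None:
        summary.to_csv(outdir / "multivariate_summary.csv", index=False)

    report = ScreenReport(counts, reference_verdicts, stability_df, uni,
                          ytab, summary, splot, panel, outliers, suspicious)
    if outdir is not None:
        (outdir / "report.json").write_text(
            json.dumps(report.to_json_dict(), indent=2, default=str))
    return report


def screen_unknowns(results: OPLSDAResults, prep: PreprocessedMatrix,
                    control_scores: np.ndarray | pd.Series,
                    new_profiles: pd.DataFrame,
                    percentile: float = 95.0) -> pd.DataFrame:
    """Flag new milk samples whose predictive score exceeds the control
    population's ``percentile``-th percentile.

    ``new_profiles``: raw relative abundances (samples x panel genes).
    Samples missing a panel gene are rejected with a reason instead of
    being scored.
    """
    threshold = float(np.percentile(np.asarray(control_scores, dtype=float),
                                    percentile))
    cols = set(prep.X.columns)
    rows = []
    ok_rows = new_profiles.index[
        new_profiles.reindex(columns=list(cols)).notna().all(axis=1)]
    bad_rows = [s for s in new_profiles.index if s not in set(ok_rows)]
    if len(ok_rows):
        Xn = prep.transform(new_profiles.loc[ok_rows])
        scores = results.predict_scores(Xn)
        for s in ok_rows:
            rows.append({"sample": s, "score": float(scores[s]),
                         "threshold": threshold,
                         "suspicious": bool(scores[s] > threshold),
                         "reason": ""})
    for s in bad_rows:
        missing = [g for g in cols
                   if g not in new_profiles.columns
                   or pd.isna(new_profiles.loc[s, g])]
        rows.append({"sample": s, "score": np.nan, "threshold": threshold,
                     "suspicious": False,
                     "reason": f"missing panel genes: {sorted(missing)}"})
    return pd.DataFrame(rows)
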
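"""From corrected N0 values to the relative-expression matrix.

Triplicate wells are aggregated per gene-sample, target N0 is divided by
the geometric mean of the three reference-gene N0s, records are pivoted
to a samples x genes matrix with study metadata, and the 0%-missing
inclusion filter drops incompletely detected target genes and then any
sample with a hole in the retained panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign, build_dose_schedule, days_since_last_dose

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "aggregate_replicates",
    "relative_expression",
    "expression_records",
    "assemble_matrix",
    "apply_inclusion_filter",
]

REFERENCE_GENES = ("UXT", "RPS9", "GPAM")


@dataclass
class ExpressionMatrix:
    """Samples x genes relative abundances plus row metadata."""

    values: pd.DataFrame              # samples x genes, NaN = undetected
    metadata: pd.DataFrame            # indexed like values: animal, group, day, days_since_dose
    completeness: pd.Series           # per-gene % of samples detected

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.metadata.index):
            raise ValueError("metadata must cover every sample row")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class FilterReport:
    genes_retained: tuple[str, ...]
    genes_dropped: tuple[str, ...]
    samples_retained: int
    samples_dropped: int
    reasons: dict

    def to_dict(self) -> dict:
        return {
            "genes_retained": list(self.genes_retained),
            "genes_dropped": list(self.genes_dropped),
            "samples_retained": self.samples_retained,
            "samples_dropped": self.samples_dropped,
            "reasons": self.reasons,
        }


def aggregate_replicates(n0: np.ndarray, flags: np.ndarray,
                         method: str = "mean") -> tuple[float, float, bool]:
    """Aggregate replicate N0s for one gene-sample.

    Only ``ok``-flagged replicates count; returns (N0, replicate CV,
    detected).  ``method``: ``mean`` (default, linear scale) or ``geometric``.
    """
    n0 = np.asarray(n0, dtype=float)
    flags = np.asarray(flags)
    ok = (flags == "ok") & np.isfinite(n0) & (n0 > 0)
    if not ok.any():
        return np.nan, np.nan, False
    vals = n0[ok]
    if method == "geometric":
        agg = float(np.exp(np.mean(np.log(vals))))
    elif method == "mean":
        agg = float(vals.mean())
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    cv = float(vals.std(ddof=1) / vals.mean()) if len(vals) > 1 else 0.0
    return agg, cv, True


def relative_expression(n0_target: float, n0_refs: tuple[float, float, float]
                        ) -> float:
    """Target N0 over the geometric mean of the three reference N0s."""
    refs = np.asarray(n0_refs, dtype=float)
    if np.any(~np.isfinite(refs)) or np.any(refs <= 0):
        raise ValueError("all three reference N0s must be positive "
                         "(sample un-normalizable)")
    return float(n0_target / np.exp(np.mean(np.log(refs))))


def expression_records(n0_table: pd.DataFrame,
                       reference_genes: tuple[str, str, str] = REFERENCE_GENES,
                       method: str = "mean") -> pd.DataFrame:
    """Aggregate replicates and normalize targets to the references.

    ``n0_table``: long table with columns sample, gene, n0, flag and any
    metadata columns (animal, group, day, session ...).  Returns one row
    per sample x target gene with ``abundance`` (relative ratio) and
    ``detected``; samples missing any reference are dropped with their
    records marked in the ``normalizable`` column of the returned frame's
    attrs.
    """
    meta_cols = [c for c in ("animal", "group", "day", "session")
                 if c in n0_table.columns]
    agg_rows = []
    for (sample, gene), g in n0_table.groupby(["sample", "gene"], sort=False):
        n0, cv, det = aggregate_replicates(g["n0"].to_numpy(),
                                           g["flag"].to_numpy(), method)
        row = {"sample": sample, "gene": gene, "n0": n0,
               "replicate_cv": cv, "detected": det}
        for c in meta_cols:
            row[c] = g[c].iloc[0]
        agg_rows.append(row)
    agg = pd.DataFrame(agg_rows)

    refs = agg[agg["gene"].isin(reference_genes)]
    ref_n0 = refs.pivot_table(index="sample", columns="gene", values="n0")
    ok_samples = ref_n0.dropna()
    ok_samples = ok_samples[(ok_samples > 0).all(axis=1)]
    geo_ref = np.exp(np.log(ok_samples[list(reference_genes)]).mean(axis=1))

    targets = agg[~agg["gene"].isin(reference_genes)].copy()
    normalizable = targets["sample"].isin(geo_ref.index)
    targets = targets[normalizable].copy()
    targets["abundance"] = targets["n0"] / targets["sample"].map(geo_ref)
    targets.loc[~targets["detected"], "abundance"] = np.nan
    dropped = sorted(set(agg["sample"]) - set(geo_ref.index))
    targets.attrs["unnormalizable_samples"] = dropped
    return targets.drop(columns=["n0"])


def assemble_matrix(records: pd.DataFrame, design: StudyDesign
                    ) -> ExpressionMatrix:
    """Pivot long records to a samples x genes matrix with metadata.

    ``records`` needs sample, gene, abundance, detected plus animal,
    group, day.  Duplicate (sample, gene) pairs are an error.
    """
    if records.empty:
        raise ValueError("no records to assemble")
    dup = records.duplicated(subset=["sample", "gene"])
    if dup.any():
        raise ValueError(
            f"duplicate (sample, gene) records: "
            f"{records.loc[dup, ['sample', 'gene']].values.tolist()[:5]}")
    values = records.pivot(index="sample", columns="gene", values="abundance")
    schedule = build_dose_schedule(design)
    meta = (records[["sample", "animal", "group", "day"]]
            .drop_duplicates("sample").set_index("sample"))
    meta["days_since_dose"] = [
        days_since_last_dose(schedule, d) if grp == "rbst" else np.nan
        for d, grp in zip(meta["day"], meta["group"])]
    meta = meta.loc[values.index]
    completeness = 100.0 * values.notna().mean(axis=0)
    return ExpressionMatrix(values, meta, completeness)


def apply_inclusion_filter(matrix: ExpressionMatrix,
                           max_missing_pct: float = 0.0,
                           exclude_genes: tuple[str, ...] = ()
                           ) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop incompletely detected genes, then samples with missing values.

    A target gene is retained when its detection completeness is at least
    ``100 - max_missing_pct`` (default: 0% missing allowed).  Samples
    with any missing value among retained genes are then excluded.
    Idempotent.  ``exclude_genes`` force-drops genes regardless of
    completeness (e.g. a detected-but-uninformative gene).
    """
    comp = matrix.completeness
    keep_genes = [g for g in matrix.genes
                  if comp[g] >= 100.0 - max_missing_pct
                  and g not in exclude_genes]
    drop_genes = [g for g in matrix.genes if g not in keep_genes]
    if not keep_genes:
        raise ValueError(
            f"no genes retained; completeness: {comp.to_dict()}")
    vals = matrix.values[keep_genes]
    keep_rows = vals.notna().all(axis=1)
    vals = vals[keep_rows]
    if vals.empty:
        raise ValueError("no samples retained after inclusion filter")
    meta = matrix.metadata.loc[vals.index]
    comp_out = 100.0 * vals.notna().mean(axis=0)
    reasons = {
        "genes": {g: f"completeness {comp[g]:.1f}% < {100 - max_missing_pct}%"
                  if g not in exclude_genes else "excluded by configuration"
                  for g in drop_genes},
        "samples_dropped": sorted(matrix.values.index[~keep_rows]),
    }
    report = FilterReport(tuple(keep_genes), tuple(drop_genes),
                          int(keep_rows.sum()), int((~keep_rows).sum()),
                          reasons)
    return ExpressionMatrix(vals, meta, comp_out), report
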
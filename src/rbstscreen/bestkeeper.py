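"""Reference-gene stability validation (BestKeeper-style descriptives).

Candidate reference genes are judged from their Cq values: low
dispersion (the BestKeeper convention reports the mean absolute
deviation from the geometric mean Cq, here ``dev``, alongside the
ordinary sample sd) and high Pearson correlation with the BestKeeper
index, the per-sample geometric mean of all candidates' Cq values.
A candidate with dev > 1 cycle is flagged inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneStability",
    "BestKeeperResult",
    "gene_descriptives",
    "bestkeeper_index",
    "correlate_with_index",
    "flag_reference_set",
    "validate_references",
]

DEV_LIMIT = 1.0          # cycles; dev above this marks a gene inconsistent
R_THRESHOLD = 0.7        # minimum index correlation for recommendation


@dataclass(frozen=True)
class GeneStability:
    gene: str
    n: int
    geo_mean_cq: float
    mean_cq: float
    min_cq: float
    max_cq: float
    dev: float          # mean |Cq - geometric mean Cq|, cycles
    sd: float           # sample standard deviation, cycles
    cv: float           # dev as % of geometric mean Cq

    @property
    def consistent(self) -> bool:
        return self.dev <= DEV_LIMIT


@dataclass(frozen=True)
class BestKeeperResult:
    index: pd.Series                     # per-sample geometric mean Cq
    correlations: dict[str, tuple[float, float]]   # gene -> (r, p)
    stabilities: dict[str, GeneStability]
    recommended: tuple[str, ...]


def gene_descriptives(gene: str, cq: np.ndarray) -> GeneStability:
    """BestKeeper descriptive statistics for one candidate's Cq values."""
    cq = np.asarray(cq, dtype=float)
    cq = cq[np.isfinite(cq)]
    if len(cq) < 3:
        raise ValueError(f"{gene}: need >= 3 finite Cq values, got {len(cq)}")
    gm = float(np.exp(np.mean(np.log(cq))))
    dev = float(np.mean(np.abs(cq - gm)))
    return GeneStability(
        gene=gene, n=len(cq), geo_mean_cq=gm, mean_cq=float(cq.mean()),
        min_cq=float(cq.min()), max_cq=float(cq.max()), dev=dev,
        sd=float(cq.std(ddof=1)), cv=100.0 * dev / gm)


def bestkeeper_index(cq_matrix: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of candidate Cq values.

    ``cq_matrix``: samples x candidate genes.  Samples with any missing
    candidate are excluded from the index.
    """
    if cq_matrix.shape[1] < 2:
        raise ValueError("BestKeeper index needs >= 2 candidate genes")
    complete = cq_matrix.dropna()
    return np.exp(np.log(complete).mean(axis=1)).rename("bestkeeper_index")


def correlate_with_index(cq: pd.Series, index: pd.Series
                         ) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform) of a gene's Cq vs the index."""
    joined = pd.concat([cq, index], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 paired values")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def flag_reference_set(stabilities: dict[str, GeneStability],
                       correlations: dict[str, tuple[float, float]],
                       r_threshold: float = R_THRESHOLD
                       ) -> tuple[str, ...]:
    """Recommend candidates that are consistent and track the index."""
    if len(stabilities) < 2:
        raise ValueError("need >= 2 candidates")
    rec = tuple(g for g, s in stabilities.items()
                if s.consistent
                and np.isfinite(correlations[g][0])
                and correlations[g][0] >= r_threshold)
    return rec


def validate_references(cq_table: pd.DataFrame,
                        candidates: list[str] | None = None,
                        r_threshold: float = R_THRESHOLD) -> BestKeeperResult:
    """Full BestKeeper validation from a long Cq table (sample, gene, cq)."""
    wide = cq_table.pivot_table(index="sample", columns="gene", values="cq")
    if candidates is None:
        candidates = list(wide.columns)
    wide = wide[candidates]
    stabilities = {g: gene_descriptives(g, wide[g].to_numpy())
                   for g in candidates}
    # a grossly unstable candidate would corrupt the index itself;
    # build it from the consistent candidates when enough remain
    consistent = [g for g in candidates if stabilities[g].consistent]
    index_genes = consistent if len(consistent) >= 2 else candidates
    index = bestkeeper_index(wide[index_genes])
    correlations = {g: correlate_with_index(wide[g], index)
                    for g in candidates}
    recommended = flag_reference_set(stabilities, correlations, r_threshold)
    return BestKeeperResult(index, correlations, stabilities, recommended)
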
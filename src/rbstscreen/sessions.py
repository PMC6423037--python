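"""Between-session factor correction for multiplicative run effects.

qPCR runs performed in separate sessions carry multiplicative scale
differences.  A per-session factor is estimated from a matrix of
between-session ratios of shared-condition means (condition = gene x
group by default) and removed by dividing observed values by it.
Factors are normalized to geometric mean 1 so corrected data keep the
original scale on average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RatioMatrix",
    "SessionFactors",
    "between_session_ratio_matrix",
    "estimate_factors",
    "apply_factors",
]


@dataclass(frozen=True)
class RatioMatrix:
    """Square matrix of between-session geometric-mean ratios.

    ``ratios[i, j]`` is the geometric mean over shared conditions of
    (condition mean in session i) / (condition mean in session j);
    ``support[i, j]`` counts the shared conditions.  NaN where a pair
    shares no condition.
    """

    sessions: tuple[str, ...]
    ratios: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sessions)
        if self.ratios.shape != (n, n) or self.support.shape != (n, n):
            raise ValueError("matrix shapes must match session count")


@dataclass(frozen=True)
class SessionFactors:
    """Multiplicative session factors with geometric mean 1."""

    factors: dict[str, float]
    n_conditions: dict[str, int] | None = None

    def __post_init__(self) -> None:
        vals = np.array(list(self.factors.values()))
        if np.any(vals <= 0):
            raise ValueError("factors must be > 0")
        gm = float(np.exp(np.mean(np.log(vals))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"factors must have geometric mean 1 (got {gm})")

    def __getitem__(self, session: str) -> float:
        return self.factors[session]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"session": s, "factor": f,
                 "n_conditions": (self.n_conditions or {}).get(s, np.nan)}
                for s, f in self.factors.items()]
        return pd.DataFrame(rows)


def _condition_means(table: pd.DataFrame, value: str,
                     condition_key: list[str]) -> pd.DataFrame:
    """Geometric condition means per session (log10 scale internally)."""
    t = table.dropna(subset=[value])
    t = t[t[value] > 0]
    logv = np.log(t[value].to_numpy())
    t = t.assign(_log=logv)
    g = t.groupby(["session"] + condition_key, observed=True)["_log"].mean()
    return g.reset_index()


def between_session_ratio_matrix(table: pd.DataFrame, value: str = "n0",
                                 condition_key: list[str] | None = None
                                 ) -> RatioMatrix:
    """Build the between-session ratio matrix from shared-condition means.

    ``condition_key`` defaults to ``["gene", "group"]``.  Raises if any
    pair of sessions shares no condition (disconnected session graph).
    """
    if condition_key is None:
        condition_key = ["gene", "group"]
    means = _condition_means(table, value, condition_key)
    sessions = tuple(sorted(means["session"].unique()))
    n = len(sessions)
    wide = means.pivot_table(index=condition_key, columns="session",
                             values="_log")
    ratios = np.full((n, n), np.nan)
    support = np.zeros((n, n), dtype=int)
    for i, si in enumerate(sessions):
        for j, sj in enumerate(sessions):
            if i == j:
                ratios[i, j] = 1.0
                support[i, j] = int(wide[si].notna().sum())
                continue
            both = wide[[si, sj]].dropna()
            support[i, j] = len(both)
            if len(both):
                ratios[i, j] = float(np.exp((both[si] - both[sj]).mean()))
    off = ~np.eye(n, dtype=bool)
    if n > 1 and np.any(np.isnan(ratios[off])):
        bad = [(sessions[i], sessions[j]) for i in range(n) for j in range(n)
               if i != j and np.isnan(ratios[i, j])]
        raise ValueError(f"disconnected session pairs (no shared conditions): {bad}")
    return RatioMatrix(sessions, ratios, support)


def estimate_factors(matrix: RatioMatrix, method: str = "geometric",
                     max_iter: int = 200, tol: float = 1e-10
                     ) -> SessionFactors:
    """Estimate session factors from a ratio matrix.

    ``geometric`` (default): factor_i = geometric mean over j of
    ratios[i, j], renormalized to geometric mean 1.  ``ml``: iterative
    maximum-likelihood refinement under log-normal errors, weighting each
    ratio by its support count; converges when the largest log-factor
    change drops below ``tol``.
    """
    logR = np.log(matrix.ratios)
    n = len(matrix.sessions)
    logf = logR.mean(axis=1)
    logf -= logf.mean()
    if method == "ml":
        w = matrix.support.astype(float)
        np.fill_diagonal(w, 0.0)
        for _ in range(max_iter):
            # log R_ij ~ logf_i - logf_j; weighted least squares = ML
            # under iid log-normal ratio errors with variance ~ 1/support
            num = (w * (logR + logf[None, :])).sum(axis=1)
            den = w.sum(axis=1)
            new = np.where(den > 0, num / den, logf)
            new -= new.mean()
            if np.max(np.abs(new - logf)) < tol:
                logf = new
                break
            logf = new
        else:
            raise RuntimeError(
                f"ML factor estimation did not converge; last iterate "
                f"{dict(zip(matrix.sessions, np.exp(logf)))}")
    elif method != "geometric":
        raise ValueError(f"unknown method {method!r}")
    n_cond = {s: int(matrix.support[i].max())
              for i, s in enumerate(matrix.sessions)}
    return SessionFactors({s: float(np.exp(v))
                           for s, v in zip(matrix.sessions, logf)}, n_cond)


def apply_factors(table: pd.DataFrame, factors: SessionFactors,
                  value: str = "n0") -> pd.DataFrame:
    """Divide observed values by their session factor.

    Adds a ``session_factor`` provenance column.  Not idempotent: the
    correction rescales data, so applying it twice divides twice.
    """
    unknown = set(table["session"].unique()) - set(factors.factors)
    if unknown:
        raise KeyError(f"sessions without a factor: {sorted(unknown)}")
    f = table["session"].map(factors.factors).to_numpy()
    out = table.copy()
    out[value] = out[value] / f
    out["session_factor"] = f
    return out
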
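"""Amplification-curve quantification: baseline, window of linearity, E, Cq, N0.

Implements the classic single-curve quantification chain for real-time
PCR: each well's raw fluorescence is baseline-corrected, a 4-6 cycle
window of log-linearity is located in the exponential phase, the
amplification efficiency E is the antilog of the log-linear slope, the
per-amplicon mean efficiency (after outlier exclusion) and a common
quantification threshold Nq yield a fractional quantification cycle Cq
and a starting concentration N0 = Nq / E_mean^Cq in arbitrary
fluorescence units.

Log base 10 is used throughout; E = 10^slope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmplificationCurve",
    "CurveFit",
    "AmpliconSummary",
    "correct_baseline",
    "find_window_of_linearity",
    "fit_sample_efficiency",
    "fit_curve",
    "summarize_amplicon_efficiency",
    "quantify_n0",
    "quantify_plate",
]

OK = "ok"
NO_AMPLIFICATION = "no_amplification"
POOR_FIT = "poor_fit"
EFFICIENCY_OUTLIER = "efficiency_outlier"

_WINDOW_LENGTHS = (4, 5, 6)
_PLATEAU_FRACTION = 0.9      # hard bound: window below 90% of observed max
_CEILING_FRACTION = 0.05     # window below 5% of the amplification ceiling
_NOISE_MULT = 3.0


@dataclass(frozen=True)
class AmplificationCurve:
    """One well's fluorescence readings over consecutive cycles."""

    well: str
    sample: str
    gene: str
    fluorescence: np.ndarray
    replicate: int = 1
    session: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.fluorescence, dtype=float)
        if f.ndim != 1 or len(f) < 10:
            raise ValueError("fluorescence must be a 1-d series of >= 10 cycles")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence values must be finite")
        object.__setattr__(self, "fluorescence", f)

    @property
    def n_cycles(self) -> int:
        return len(self.fluorescence)


@dataclass(frozen=True)
class CurveFit:
    """Result of quantifying one well."""

    well: str
    sample: str
    gene: str
    replicate: int
    session: str
    baseline: float
    window: tuple[int, int] | None
    efficiency: float
    r2: float
    slope: float
    intercept: float
    flag: str
    cq: float = np.nan
    nq: float = np.nan
    n0: float = np.nan

    @property
    def ok(self) -> bool:
        return self.flag == OK


@dataclass(frozen=True)
class AmpliconSummary:
    """Per-gene efficiency summary over a plate's wells."""

    gene: str
    mean_efficiency: float
    sd_efficiency: float
    n_used: int
    n_excluded: int


# ----------------------------------------------------------------------
# window scanning machinery (shared by baseline search and window finder)
# ----------------------------------------------------------------------

def _amplification_ceiling(corrected: np.ndarray) -> np.ndarray:
    """Per-row estimate of the amplification ceiling K.

    For a logistic amplification the largest cycle-to-cycle increment
    occurs at the inflection, where fluorescence equals K/2; twice the
    (smoothed) max-increment level therefore estimates K.  For curves
    that have not reached the inflection this underestimates K, which
    only makes the window cap more conservative.
    """
    d = np.diff(corrected, axis=1)
    kernel = np.ones(3) / 3.0
    sm = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"),
                             1, d)
    idx = np.argmax(sm, axis=1)
    return 2.0 * corrected[np.arange(corrected.shape[0]), idx + 1]


def _best_window_per_row(corrected: np.ndarray, floor: float
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For each row of ``corrected`` find the best 4-6 cycle log-linear window.

    A window qualifies when every value is positive, above ``floor`` and
    below both 90% of the row's maximum and ``_CEILING_FRACTION`` of the
    estimated amplification ceiling (keeping the window clear of the
    plateau's curvature, which would bias the slope low).  Returns arrays
    (r2, start, length), with r2 = -inf where no window qualifies.  Ties
    are broken toward later windows (higher fluorescence).
    """
    B, C = corrected.shape
    with np.errstate(invalid="ignore", divide="ignore"):
        logf = np.where(corrected > 0, np.log10(np.where(corrected > 0,
                                                         corrected, 1.0)), np.nan)
    cap = np.minimum(_PLATEAU_FRACTION * corrected.max(axis=1),
                     _CEILING_FRACTION * _amplification_ceiling(corrected)
                     )[:, None]
    usable = (corrected > floor) & (corrected < cap) & np.isfinite(logf)

    best_r2 = np.full(B, -np.inf)
    best_start = np.zeros(B, dtype=int)
    best_len = np.zeros(B, dtype=int)
    for L in _WINDOW_LENGTHS:
        if C < L:
            continue
        yw = np.lib.stride_tricks.sliding_window_view(
            np.nan_to_num(logf), L, axis=1)          # (B, C-L+1, L)
        okw = np.lib.stride_tricks.sliding_window_view(
            usable, L, axis=1).all(axis=2)           # (B, C-L+1)
        x = np.arange(L, dtype=float)
        xm = x.mean()
        sxx = ((x - xm) ** 2).sum()
        ym = yw.mean(axis=2)
        sxy = ((x - xm) * yw).sum(axis=2)
        syy = ((yw - ym[..., None]) ** 2).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(syy > 0, sxy ** 2 / (sxx * syy), 0.0)
        slope = sxy / sxx
        r2 = np.where(okw & (slope > 0), r2, -np.inf)
        for s in range(r2.shape[1]):
            col = r2[:, s]
            # >= so ties go to later/longer windows scanned afterwards
            better = col >= best_r2
            best_r2 = np.where(better, col, best_r2)
            best_start = np.where(better, s, best_start)
            best_len = np.where(better, L, best_len)
    return best_r2, best_start, best_len


def _noise_floor(corrected_early: np.ndarray) -> float:
    """3x the sd of the first five corrected cycles (background noise)."""
    return _NOISE_MULT * float(np.std(corrected_early[:5], ddof=1))


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def _background_estimate(f: np.ndarray) -> tuple[float, float, int]:
    """Mean/sd/count of the pre-takeoff background cycles.

    Iteratively grows the background region: starting from the first five
    cycles, the takeoff is the first of two consecutive cycles exceeding
    background + 3 sd, and the background is re-estimated from the cycles
    up to two before takeoff.
    """
    idx = np.arange(len(f))
    bg = idx < 5
    for _ in range(10):
        b = float(f[bg].mean())
        s = float(f[bg].std(ddof=1))
        above = f > b + _NOISE_MULT * max(s, 1e-12)
        takeoff = len(f)
        for c in range(len(f) - 1):
            if above[c] and above[c + 1]:
                takeoff = c
                break
        new_bg = idx < max(takeoff - 2, 5)
        if np.array_equal(new_bg, bg):
            break
        bg = new_bg
    return b, s, int(bg.sum())


def correct_baseline(curve: AmplificationCurve, n_grid: int = 41
                     ) -> tuple[float, np.ndarray, str]:
    """Estimate a constant baseline by r2-maximizing grid search.

    The grid is anchored on the pre-takeoff background mean and spans its
    +-3 standard-error confidence band (capped above by the early-cycle
    maximum, so a rising zero-baseline exponential is handled); the
    chosen baseline maximizes the r2 of the best log-linear window on the
    corrected series.  An unconstrained grid would trade baseline offset
    against plateau curvature and bias the efficiency low.  Returns
    (baseline, corrected series, flag); a flat curve gets flag
    ``no_amplification`` with the series median as baseline.
    """
    f = curve.fluorescence
    noise_sd = float(np.std(f[:5], ddof=1))
    rise = float(f.max() - np.median(f))
    if rise < _NOISE_MULT * max(noise_sd, 1e-12):
        b = float(np.median(f))
        return b, f - b, NO_AMPLIFICATION
    b0, s0, m = _background_estimate(f)
    if m >= len(f) - 4:
        # no takeoff: the background region swallows the whole series
        b = float(np.median(f))
        return b, f - b, NO_AMPLIFICATION
    sem = max(s0, 1e-12) / np.sqrt(m)
    lo = max(b0 - _NOISE_MULT * sem, 0.0)
    hi = min(b0 + _NOISE_MULT * sem, float(f[:5].max()))
    if hi <= lo:
        grid = np.array([min(lo, hi)])
    else:
        grid = np.linspace(lo, hi, n_grid)
    corrected = f[None, :] - grid[:, None]
    floor = _NOISE_MULT * max(s0, 1e-12)
    r2, start, length = _best_window_per_row(corrected, floor)
    if not np.any(np.isfinite(r2)):
        b = float(np.median(f))
        return b, f - b, POOR_FIT
    i = int(np.argmax(r2))
    return float(grid[i]), f - grid[i], OK


def find_window_of_linearity(corrected: np.ndarray) -> tuple[int, int]:
    """Locate the 4-6 cycle window maximizing log-linearity.

    Candidates must sit above the noise floor (3 sd of the first five
    corrected cycles) and below 90% of the plateau.  Returns 1-based
    (first, last) cycles; raises ValueError (poor fit) when no window
    qualifies.
    """
    corrected = np.asarray(corrected, dtype=float)
    floor = _noise_floor(corrected)
    r2, start, length = _best_window_per_row(corrected[None, :], floor)
    if not np.isfinite(r2[0]):
        raise ValueError("no window of linearity (poor fit)")
    first = int(start[0]) + 1
    return first, first + int(length[0]) - 1


def fit_sample_efficiency(corrected: np.ndarray, window: tuple[int, int]
                          ) -> tuple[float, float, float, float]:
    """OLS of log10 corrected fluorescence on cycle within the window.

    Returns (E, r2, slope, intercept); slope and intercept describe the
    raw fitted line (used for the Cq crossing), while E applies a
    first-order correction for logistic suppression: the local log-slope
    of a logistic is log10(E) * (1 - X/K), so the raw slope is divided by
    (1 - Xbar/Khat) with Xbar the window's mean fluorescence and Khat the
    estimated amplification ceiling.  Raises ValueError for windows
    shorter than 4 cycles or non-positive fluorescence inside the window.
    """
    corrected = np.asarray(corrected, dtype=float)
    first, last = window
    if last - first + 1 < 4:
        raise ValueError("window shorter than 4 cycles (poor fit)")
    y = corrected[first - 1:last]
    if np.any(y <= 0):
        raise ValueError("non-positive corrected fluorescence in window")
    x = np.arange(first, last + 1, dtype=float)
    slope, intercept = np.polyfit(x, np.log10(y), 1)
    yhat = intercept + slope * x
    ss_res = float(((np.log10(y) - yhat) ** 2).sum())
    ss_tot = float(((np.log10(y) - np.log10(y).mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    khat = float(_amplification_ceiling(corrected[None, :])[0])
    frac = y.mean() / khat if khat > 0 else 0.0
    factor = 1.0 - frac if 1e-6 < frac < 0.2 else 1.0
    return 10.0 ** (slope / factor), r2, float(slope), float(intercept)


def fit_curve(curve: AmplificationCurve) -> CurveFit:
    """Baseline-correct, window-find and estimate efficiency for one well."""
    baseline, corrected, flag = correct_baseline(curve)
    if flag != OK:
        return CurveFit(curve.well, curve.sample, curve.gene, curve.replicate,
                        curve.session, baseline, None, np.nan, np.nan,
                        np.nan, np.nan, flag)
    try:
        window = find_window_of_linearity(corrected)
        E, r2, slope, intercept = fit_sample_efficiency(corrected, window)
    except ValueError:
        return CurveFit(curve.well, curve.sample, curve.gene, curve.replicate,
                        curve.session, baseline, None, np.nan, np.nan,
                        np.nan, np.nan, POOR_FIT)
    return CurveFit(curve.well, curve.sample, curve.gene, curve.replicate,
                    curve.session, baseline, window, E, r2, slope,
                    intercept, OK)


def summarize_amplicon_efficiency(fits: Sequence[CurveFit],
                                  max_deviation: float = 0.05
                                  ) -> AmpliconSummary:
    """Mean efficiency per amplicon, excluding outliers.

    Per-sample efficiencies more than ``max_deviation`` from the median,
    or from non-ok wells, are excluded; the mean is over the remainder.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    gene = fits[0].gene
    ok = [f for f in fits if f.ok]
    if not ok:
        raise ValueError(f"amplicon {gene}: no quantifiable wells")
    eff = np.array([f.efficiency for f in ok])
    med = float(np.median(eff))
    keep = np.abs(eff - med) <= max_deviation
    if not np.any(keep):
        raise ValueError(f"amplicon {gene}: all efficiencies excluded as outliers")
    used = eff[keep]
    n_excluded = (len(fits) - len(ok)) + int((~keep).sum())
    return AmpliconSummary(gene, float(used.mean()),
                           float(used.std(ddof=1)) if len(used) > 1 else 0.0,
                           int(keep.sum()), n_excluded)


def _window_midpoint_fluorescence(fit: CurveFit) -> float:
    first, last = fit.window
    mid = 0.5 * (first + last)
    return 10.0 ** (fit.intercept + fit.slope * mid)


def quantify_n0(fit: CurveFit, summary: AmpliconSummary, nq: float) -> CurveFit:
    """Compute Cq and N0 for one ok well given the amplicon threshold Nq.

    Cq is the fractional cycle where the well's fitted log-linear segment
    crosses Nq; N0 = Nq / mean_E^Cq, so N0 * mean_E^Cq = Nq exactly.
    Wells whose fitted window does not bracket Nq are flagged ``poor_fit``
    (extrapolation).
    """
    if not fit.ok:
        return fit
    first, last = fit.window
    lo = fit.intercept + fit.slope * first
    hi = fit.intercept + fit.slope * last
    lnq = np.log10(nq)
    if not (min(lo, hi) - 1e-9 <= lnq <= max(lo, hi) + 1e-9):
        return replace(fit, flag=POOR_FIT, nq=nq)
    cq = (lnq - fit.intercept) / fit.slope
    n0 = nq / summary.mean_efficiency ** cq
    return replace(fit, cq=float(cq), nq=float(nq), n0=float(n0))


def quantify_plate(curves: pd.DataFrame, max_deviation: float = 0.05,
                   flag_deviation: float = 0.15
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a long-format curve table end to end.

    Expects columns well, sample, gene, replicate, session (optional),
    cycle, fluorescence.  Returns (per-well fits table, per-amplicon
    summary table); the common threshold Nq per amplicon is the
    geometric mean of window-midpoint fluorescences over its ok wells.

    Wells whose efficiency deviates from the amplicon median by more than
    ``max_deviation`` are excluded from the mean-efficiency estimate;
    only wells beyond ``flag_deviation`` are flagged
    ``efficiency_outlier`` and denied an N0 (a moderate per-well
    efficiency error does not bias N0, which uses the amplicon mean).
    """
    need = {"well", "sample", "gene", "cycle", "fluorescence"}
    missing = need - set(curves.columns)
    if missing:
        raise ValueError(f"curve table missing columns: {sorted(missing)}")
    fits: list[CurveFit] = []
    for well, g in curves.groupby("well", sort=False):
        g = g.sort_values("cycle")
        c = AmplificationCurve(
            well=str(well), sample=str(g["sample"].iloc[0]),
            gene=str(g["gene"].iloc[0]),
            replicate=int(g["replicate"].iloc[0]) if "replicate" in g else 1,
            session=str(g["session"].iloc[0]) if "session" in g else "",
            fluorescence=g["fluorescence"].to_numpy())
        fits.append(fit_curve(c))

    summaries: dict[str, AmpliconSummary] = {}
    out: list[CurveFit] = []
    by_gene: dict[str, list[CurveFit]] = {}
    for f in fits:
        by_gene.setdefault(f.gene, []).append(f)
    for gene, gfits in by_gene.items():
        okf = [f for f in gfits if f.ok]
        if not okf:
            out.extend(gfits)
            continue
        summary = summarize_amplicon_efficiency(gfits, max_deviation)
        summaries[gene] = summary
        nq = float(np.exp(np.mean([np.log(_window_midpoint_fluorescence(f))
                                   for f in okf])))
        med = float(np.median([f.efficiency for f in okf]))
        for f in gfits:
            if f.ok and abs(f.efficiency - med) > flag_deviation:
                out.append(replace(f, flag=EFFICIENCY_OUTLIER))
            elif f.ok:
                out.append(quantify_n0(f, summary, nq))
            else:
                out.append(f)

    meta_cols = [c for c in ("animal", "group", "day") if c in curves.columns]
    meta = (curves.drop_duplicates("well").set_index("well")[meta_cols]
            if meta_cols else None)
    fits_df = pd.DataFrame([{
        "well": f.well, "sample": f.sample, "gene": f.gene,
        "replicate": f.replicate, "session": f.session,
        "baseline": f.baseline,
        "window_first": f.window[0] if f.window else np.nan,
        "window_last": f.window[1] if f.window else np.nan,
        "efficiency": f.efficiency, "r2": f.r2, "cq": f.cq, "nq": f.nq,
        "n0": f.n0, "flag": f.flag,
    } for f in out])
    if meta is not None:
        fits_df = fits_df.join(meta, on="well")
    summary_df = pd.DataFrame([{
        "gene": s.gene, "mean_efficiency": s.mean_efficiency,
        "sd_efficiency": s.sd_efficiency, "n_used": s.n_used,
        "n_excluded": s.n_excluded,
    } for s in summaries.values()])
    return fits_df, summary_df
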
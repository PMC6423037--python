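"""Multivariate screening: PCA outlier rejection and OPLS-DA biomarker ranking.

The screening core of the pipeline.  Expression ratios are log10
transformed and Pareto scaled; a NIPALS PCA with Hotelling's T2 and
DModX limits removes extreme samples; an orthogonal projections to
latent structures discriminant analysis (OPLS-DA) separates
class-predictive from class-orthogonal variation, is validated by
7-fold cross-validated Q2 and CV-ANOVA, and its S-plot (covariance p1
vs correlation p(corr)1 of each gene with the predictive score) ranks
candidate biomarkers.

Model classes follow the statsmodels convention: construct from data,
``fit()`` returns a results object carrying estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PreprocessedMatrix",
    "preprocess",
    "PCA",
    "PCAResults",
    "OutlierReport",
    "flag_outliers",
    "OPLSDA",
    "OPLSDAResults",
    "CvAnovaResult",
    "cv_anova",
    "SPlotPoint",
    "rank_biomarkers",
]

NIPALS_TOL = 1e-12
NIPALS_SOFT_TOL = 1e-7
NIPALS_MAX_ITER = 2000


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

@dataclass
class PreprocessedMatrix:
    """Log10-transformed, mean-centered, Pareto-scaled data matrix.

    Pareto scaling divides each centered column by the square root of its
    standard deviation -- intermediate between unit-variance scaling and
    none.  Column means and sqrt-sd scales are stored so new samples can
    be projected and the transform inverted.
    """

    X: pd.DataFrame                     # samples x genes, processed
    y: pd.Series | None                 # 0 = control, 1 = rbst (optional)
    col_means: pd.Series                # of log10 values
    col_scales: pd.Series               # sqrt(sd) of log10 values
    dropped: tuple[str, ...] = ()       # zero-variance columns removed

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Project new raw abundances with the stored parameters."""
        cols = list(self.X.columns)
        missing = set(cols) - set(raw.columns)
        if missing:
            raise ValueError(f"new samples missing genes: {sorted(missing)}")
        r = raw[cols]
        if (r <= 0).any().any():
            raise ValueError("abundances must be > 0 for the log transform")
        return (np.log10(r) - self.col_means[cols]) / self.col_scales[cols]

    def inverse_transform(self, processed: pd.DataFrame) -> pd.DataFrame:
        cols = list(processed.columns)
        return 10.0 ** (processed * self.col_scales[cols] + self.col_means[cols])


def preprocess(values: pd.DataFrame, groups: pd.Series | None = None
               ) -> PreprocessedMatrix:
    """Log10 + mean-center + Pareto-scale a samples x genes matrix.

    ``groups`` (optional): per-sample labels, "control"/"rbst" or 0/1,
    coded into the class vector y.  Non-positive values are an error
    (the inclusion filter must run first); zero-variance columns are
    dropped.
    """
    bad = (values <= 0) | values.isna()
    if bad.any().any():
        idx = list(zip(*np.where(bad.to_numpy())))[:3]
        names = [(values.index[i], values.columns[j]) for i, j in idx]
        raise ValueError(f"non-positive or missing values, e.g. {names}")
    logx = np.log10(values)
    sd = logx.std(axis=0, ddof=1)
    dropped = tuple(sd.index[sd == 0])
    keep = [c for c in values.columns if c not in dropped]
    logx = logx[keep]
    means = logx.mean(axis=0)
    scales = np.sqrt(sd[keep])
    X = (logx - means) / scales
    y = None
    if groups is not None:
        if groups.dtype == object:
            y = groups.map({"control": 0, "rbst": 1}).astype(float)
        else:
            y = groups.astype(float)
        y = y.loc[values.index]
    return PreprocessedMatrix(X, y, means, scales, dropped)


# ----------------------------------------------------------------------
# NIPALS PCA
# ----------------------------------------------------------------------

class PCA:
    """Principal component analysis fitted by NIPALS iteration.

    Parameters
    ----------
    X : DataFrame or ndarray, preprocessed (centered) samples x variables.
    n_components : number of components to extract.
    """

    def __init__(self, X: pd.DataFrame | np.ndarray, n_components: int = 2):
        if isinstance(X, pd.DataFrame):
            self.index = X.index
            self.columns = X.columns
            self.X = X.to_numpy(dtype=float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.index = pd.RangeIndex(self.X.shape[0])
            self.columns = pd.RangeIndex(self.X.shape[1])
        if n_components > min(self.X.shape):
            raise ValueError("n_components exceeds matrix rank bound")
        self.n_components = n_components

    def fit(self) -> "PCAResults":
        X = self.X.copy()
        N, K = X.shape
        ss_total = float((X ** 2).sum())
        T = np.zeros((N, self.n_components))
        P = np.zeros((K, self.n_components))
        r2x = []
        for a in range(self.n_components):
            t = X[:, int(np.argmax((X ** 2).sum(axis=0)))].copy()
            if not np.any(t):
                raise RuntimeError(f"component {a + 1}: residual matrix is zero")
            for it in range(NIPALS_MAX_ITER):
                p = X.T @ t / (t @ t)
                p /= np.linalg.norm(p)
                t_new = X @ p
                delta = np.linalg.norm(t_new - t) / max(
                    np.linalg.norm(t_new), 1e-300)
                t = t_new
                if delta < NIPALS_TOL:
                    break
            else:
                # near-degenerate eigenvalues converge geometrically with
                # ratio lambda2/lambda1; accept a soft tolerance there
                if delta > NIPALS_SOFT_TOL:
                    raise RuntimeError(
                        f"NIPALS did not converge on component {a + 1} "
                        f"(last relative change {delta:.2e})")
            ss_before = float((X ** 2).sum())
            X -= np.outer(t, p)
            ss_after = float((X ** 2).sum())
            T[:, a] = t
            P[:, a] = p
            r2x.append((ss_before - ss_after) / ss_total)
        return PCAResults(self, T, P, np.array(r2x), ss_total)


class PCAResults:
    """Scores, loadings and explained variance of a fitted PCA."""

    def __init__(self, model: PCA, T: np.ndarray, P: np.ndarray,
                 r2x: np.ndarray, ss_total: float):
        self.model = model
        self.scores = pd.DataFrame(
            T, index=model.index,
            columns=[f"t{a + 1}" for a in range(T.shape[1])])
        self.loadings = pd.DataFrame(
            P, index=model.columns,
            columns=[f"p{a + 1}" for a in range(P.shape[1])])
        self.r2x = r2x
        self.r2x_cum = float(r2x.sum())
        self.ss_total = ss_total

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def hotelling_t2(self, alpha: float = 0.05,
                     variant: str = "n2") -> tuple[pd.Series, float]:
        """Per-sample Hotelling T2 and its (1 - alpha) limit.

        T2_i = sum_a t_ia^2 / var(t_a).  The default limit uses the
        (N^2 - 1) chemometrics variant
        A(N-1)(N+1) / (N(N-A)) * F_{1-alpha}(A, N-A); ``variant="n1"``
        selects A(N-1)/(N-A) * F.
        """
        T = self.scores.to_numpy()
        N, A = T.shape
        if N <= A:
            raise ValueError("need more samples than components")
        var = T.var(axis=0, ddof=1)
        t2 = (T ** 2 / var).sum(axis=1)
        fcrit = stats.f.ppf(1 - alpha, A, N - A)
        if variant == "n2":
            limit = A * (N - 1) * (N + 1) / (N * (N - A)) * fcrit
        elif variant == "n1":
            limit = A * (N - 1) / (N - A) * fcrit
        else:
            raise ValueError(f"unknown variant {variant!r}")
        return pd.Series(t2, index=self.scores.index, name="T2"), float(limit)

    def dmodx(self, alpha: float = 0.05) -> tuple[pd.Series, float]:
        """Normalized distance to the model in X space and its critical limit.

        DModX_i = s_i / s0 with s_i = sqrt(RSS_i / (K - A)) and pooled
        s0 = sqrt(RSS_total / ((N - A - 1)(K - A))); the critical value
        is sqrt(F_{1-alpha}(K - A, (N - A - 1)(K - A))).
        """
        X = self.model.X
        N, K = X.shape
        A = self.n_components
        if K <= A:
            raise ValueError("need more variables than components")
        E = X - self.scores.to_numpy() @ self.loadings.to_numpy().T
        rss = (E ** 2).sum(axis=1)
        s_i = np.sqrt(rss / (K - A))
        dof0 = (N - A - 1) * (K - A)
        s0 = np.sqrt(rss.sum() / dof0)
        dmodx = s_i / s0
        crit = float(np.sqrt(stats.f.ppf(1 - alpha, K - A, dof0)))
        return pd.Series(dmodx, index=self.scores.index, name="DModX"), crit

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, self.n_components + 1),
            "R2X": self.r2x,
            "R2X_cum": np.cumsum(self.r2x),
        })


@dataclass(frozen=True)
class OutlierReport:
    t2: pd.Series
    t2_limit: float
    dmodx: pd.Series
    dmodx_limit: float
    excluded: tuple[str, ...]
    reasons: dict

    def to_dict(self) -> dict:
        return {"t2_limit": self.t2_limit, "dmodx_limit": self.dmodx_limit,
                "excluded": list(self.excluded), "reasons": self.reasons}


def flag_outliers(pca: PCAResults, alpha: float = 0.05) -> OutlierReport:
    """Single-pass outlier flagging: T2 over its 95% limit or DModX over
    its critical limit."""
    t2, t2_lim = pca.hotelling_t2(alpha)
    dm, dm_lim = pca.dmodx(alpha)
    reasons = {}
    for s in t2.index:
        r = []
        if t2[s] > t2_lim:
            r.append(f"T2 {t2[s]:.2f} > {t2_lim:.2f}")
        if dm[s] > dm_lim:
            r.append(f"DModX {dm[s]:.2f} > {dm_lim:.2f}")
        if r:
            reasons[s] = "; ".join(r)
    return OutlierReport(t2, t2_lim, dm, dm_lim,
                         tuple(reasons), reasons)


# ----------------------------------------------------------------------
# OPLS-DA
# ----------------------------------------------------------------------

def _opls_fit_arrays(X: np.ndarray, y: np.ndarray, n_orth: int) -> dict:
    """Core O-PLS decomposition for a single centered response.

    Repeats (predictive weight -> orthogonal component -> deflation)
    ``n_orth`` times, then fits the final predictive component on the
    deflated matrix.
    """
    Xd = X.copy()
    yc = y - y.mean()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orth):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break
        w_o /= n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    uninformative = nw < 1e-12
    if uninformative:
        w = np.zeros_like(w)
        t = np.zeros(X.shape[0])
        p = np.zeros(X.shape[1])
        q = 0.0
    else:
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        q = float(yc @ t / (t @ t))
    return {"w": w, "t": t, "p": p, "q": q, "y_mean": float(y.mean()),
            "W_o": W_o, "T_o": T_o, "P_o": P_o, "Xd": Xd,
            "uninformative": uninformative}


def _opls_predict_arrays(fit: dict, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict (score t, yhat) for new preprocessed rows."""
    Xd = X.copy()
    for w_o, p_o in zip(fit["W_o"], fit["P_o"]):
        t_o = Xd @ w_o
        Xd -= np.outer(t_o, p_o)
    t = Xd @ fit["w"]
    yhat = fit["y_mean"] + fit["q"] * t
    return t, yhat


@dataclass(frozen=True)
class CvAnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float


def cv_anova(y: np.ndarray, press: float, n_components: int) -> CvAnovaResult:
    """ANOVA of cross-validated predictive residuals.

    Compares the cross-validated residual sum of squares (PRESS) with the
    residuals around the class mean: F = ((SS - PRESS)/d1) / (PRESS/d2)
    with d1 = fitted components (predictive + orthogonal) and
    d2 = N - d1 - 1, following the published CV-ANOVA construction for
    OPLS models.  PRESS >= SS gives F = 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    ss = float(((y - y.mean()) ** 2).sum())
    d1 = max(n_components, 1)
    d2 = max(len(y) - d1 - 1, 1)
    if press >= ss or press <= 0:
        return CvAnovaResult(0.0, d1, d2, 1.0)
    F = ((ss - press) / d1) / (press / d2)
    return CvAnovaResult(float(F), d1, d2, float(stats.f.sf(F, d1, d2)))


@dataclass(frozen=True)
class SPlotPoint:
    gene: str
    p1: float          # covariance with the predictive score
    pcorr1: float      # correlation with the predictive score
    defined: bool = True


class OPLSDA:
    """Orthogonal PLS discriminant analysis of a two-class design.

    Parameters
    ----------
    X : preprocessed samples x genes DataFrame.
    y : binary class vector (0 = control, 1 = rbst), indexed like X.
    n_orth : int or "auto"; "auto" adds orthogonal components while the
        7-fold Q2 improves by more than ``q2_tol`` (max ``max_orth``).
    folds : cross-validation folds (deterministic round-robin over
        samples sorted by id).
    """

    def __init__(self, X: pd.DataFrame, y: pd.Series,
                 n_orth: int | str = "auto", folds: int = 7,
                 max_orth: int = 3, q2_tol: float = 0.01):
        yv = np.asarray(y.loc[X.index], dtype=float)
        classes = np.unique(yv)
        if len(classes) < 2:
            raise ValueError("y must contain both classes")
        if min(np.sum(yv == c) for c in classes) < 3:
            raise ValueError("need >= 3 samples per class")
        if folds < 2:
            raise ValueError("folds must be >= 2")
        self.X = X
        self.y = pd.Series(yv, index=X.index)
        self.n_orth = n_orth
        self.folds = min(folds, len(X))
        self.max_orth = max_orth
        self.q2_tol = q2_tol

    # -- cross-validation ----------------------------------------------
    def _fold_assignment(self) -> np.ndarray:
        order = np.argsort(np.asarray(self.X.index.astype(str)))
        folds = np.empty(len(order), dtype=int)
        folds[order] = np.arange(len(order)) % self.folds
        return folds

    def _press(self, n_orth: int) -> float:
        Xv = self.X.to_numpy(dtype=float)
        yv = self.y.to_numpy()
        folds = self._fold_assignment()
        press = 0.0
        for f in range(self.folds):
            test = folds == f
            train = ~test
            if len(np.unique(yv[train])) < 2:
                raise ValueError(
                    "a training fold lost a class; use fewer folds")
            fit = _opls_fit_arrays(Xv[train], yv[train], n_orth)
            _, yhat = _opls_predict_arrays(fit, Xv[test])
            press += float(((yv[test] - yhat) ** 2).sum())
        return press

    def cross_validate_q2(self, n_orth: int) -> float:
        yv = self.y.to_numpy()
        ss = float(((yv - yv.mean()) ** 2).sum())
        return 1.0 - self._press(n_orth) / ss

    # -- fitting --------------------------------------------------------
    def fit(self) -> "OPLSDAResults":
        if self.n_orth == "auto":
            n_orth = 0
            best_q2 = self.cross_validate_q2(0)
            for k in range(1, self.max_orth + 1):
                q2 = self.cross_validate_q2(k)
                if q2 > best_q2 + self.q2_tol:
                    best_q2, n_orth = q2, k
                else:
                    break
        else:
            n_orth = int(self.n_orth)
        Xv = self.X.to_numpy(dtype=float)
        yv = self.y.to_numpy()
        fit = _opls_fit_arrays(Xv, yv, n_orth)
        # sign convention: treated-class mean score positive
        if fit["t"][yv == 1].mean() < fit["t"][yv == 0].mean():
            for key in ("w", "t", "p"):
                fit[key] = -fit[key]
            fit["q"] = -fit["q"]
        press = self._press(n_orth)
        ss_y = float(((yv - yv.mean()) ** 2).sum())
        q2 = 1.0 - press / ss_y
        return OPLSDAResults(self, fit, n_orth, q2, press)


class OPLSDAResults:
    """Fitted OPLS-DA model: components, fit statistics, S-plot."""

    def __init__(self, model: OPLSDA, fit: dict, n_orth: int,
                 q2: float, press: float):
        self.model = model
        self._fit = fit
        self.n_orth = n_orth
        self.uninformative = fit["uninformative"]
        X = model.X.to_numpy(dtype=float)
        y = model.y.to_numpy()
        t = fit["t"]
        yhat = fit["y_mean"] + fit["q"] * t
        ss_y = float(((y - y.mean()) ** 2).sum())
        self.r2y = 1.0 - float(((y - yhat) ** 2).sum()) / ss_y
        ss_x = float((X ** 2).sum())
        explained = float((np.outer(t, fit["p"]) ** 2).sum()) if t.any() else 0.0
        for t_o, p_o in zip(fit["T_o"], fit["P_o"]):
            explained += float((np.outer(t_o, p_o) ** 2).sum())
        self.r2x = explained / ss_x if ss_x > 0 else 0.0
        self.q2 = q2
        self.press = press
        self.scores = pd.Series(t, index=model.X.index, name="t1")
        self.weights = pd.Series(fit["w"], index=model.X.columns, name="w1")
        self.loadings = pd.Series(fit["p"], index=model.X.columns, name="p1")
        self.orthogonal_scores = pd.DataFrame(
            np.column_stack(fit["T_o"]) if fit["T_o"] else
            np.empty((len(model.X), 0)),
            index=model.X.index,
            columns=[f"to{k + 1}" for k in range(n_orth)][:len(fit["T_o"])])
        self.cv_anova = cv_anova(y, press, 1 + len(fit["T_o"]))

    # -- prediction -----------------------------------------------------
    def predict_scores(self, X_new: pd.DataFrame) -> pd.Series:
        """Predictive scores for new preprocessed samples."""
        t, _ = _opls_predict_arrays(self._fit, X_new.to_numpy(dtype=float))
        return pd.Series(t, index=X_new.index, name="t1")

    def predict(self, X_new: pd.DataFrame) -> pd.Series:
        _, yhat = _opls_predict_arrays(self._fit, X_new.to_numpy(dtype=float))
        return pd.Series(yhat, index=X_new.index, name="yhat")

    # -- S-plot ---------------------------------------------------------
    def s_plot(self) -> pd.DataFrame:
        """Covariance (p1) and correlation (p(corr)1) of every gene with
        the predictive score."""
        X = self.model.X.to_numpy(dtype=float)
        t = self.scores.to_numpy()
        N = len(t)
        sd_t = t.std(ddof=1)
        rows = []
        for j, gene in enumerate(self.model.X.columns):
            x = X[:, j]
            p1 = float(t @ x / (N - 1))
            sd_x = x.std(ddof=1)
            if sd_x == 0 or sd_t == 0:
                rows.append({"gene": gene, "p1": p1, "pcorr1": np.nan,
                             "defined": False})
            else:
                rows.append({"gene": gene, "p1": p1,
                             "pcorr1": p1 / (sd_t * sd_x), "defined": True})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """One-row model summary in SIMCA's conventional terms."""
        return pd.DataFrame([{
            "n_samples": len(self.model.X),
            "n_genes": self.model.X.shape[1],
            "n_orth": self.n_orth,
            "R2X": self.r2x, "R2Y": self.r2y, "Q2": self.q2,
            "CV_ANOVA_F": self.cv_anova.F,
            "CV_ANOVA_p": self.cv_anova.p,
        }])


def rank_biomarkers(s_plot: pd.DataFrame, pcorr_threshold: float = 0.4
                    ) -> pd.DataFrame:
    """Order genes by |p(corr)1| (ties by |p1|); the panel keeps genes
    above the correlation threshold."""
    sp = s_plot[s_plot["defined"]].copy()
    sp["abs_pcorr"] = sp["pcorr1"].abs()
    sp["abs_p1"] = sp["p1"].abs()
    sp = sp.sort_values(["abs_pcorr", "abs_p1"],
                        ascending=False).reset_index(drop=True)
    sp["rank"] = np.arange(1, len(sp) + 1)
    sp["in_panel"] = sp["abs_pcorr"] > pcorr_threshold
    return sp.drop(columns=["abs_pcorr", "abs_p1"])
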
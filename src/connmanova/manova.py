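"""Fixed-effects multivariate multiple regression with Wilks-lambda inference.

The model is Y = X B + U with a fixed design X whose columns are an
intercept, sex (+1/-1), diagnosis (+1/-1) and their product (the
sex-by-diagnosis interaction), so q = 3 predictors. For a subjects x parcels
response panel Y the hypothesis and error sums-of-squares-and-cross-products
(SSCP) matrices are

    E = (Y - X B)' (Y - X B),        H = T - E,

where T is the total SSCP about the column means; with an intercept in the
model H + E = T exactly. The omnibus statistic is Wilks' lambda,
Lambda = det(E) / det(E + H), transformed to an approximately F-distributed
statistic via Rao's formula; determinants are evaluated through Cholesky
log-determinants so the p = 165 case neither overflows nor loses symmetry.

Leave-one-out (reduced-model) partial tests delete one predictor at a time:
partial Lambda_j = Lambda(full) / Lambda(without j), converted by the exact
single-hypothesis-df transform F = ((1 - L)/L) * ((vE - p + 1)/p) with
(p, vE - p + 1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .cohort import CohortTable, MetricPanel
from .exceptions import (
    DegenerateDataError,
    InsufficientDFError,
    RankError,
)

PREDICTORS = ("sex", "diagnosis", "interaction")

__all__ = [
    "PREDICTORS",
    "DesignMatrix",
    "FResult",
    "build_design",
    "wilks_lambda",
    "rao_f",
    "MultivariateManova",
    "omnibus_step1",
    "predictor_loo_step2",
]


@dataclass(frozen=True)
class DesignMatrix:
    """Design with columns (intercept, sex, diagnosis, interaction); q = 3."""

    matrix: np.ndarray
    columns: tuple[str, ...] = ("intercept",) + PREDICTORS

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def q(self) -> int:
        return self.matrix.shape[1] - 1

    @property
    def predictors(self) -> np.ndarray:
        """The design without the intercept column."""
        return self.matrix[:, 1:]

    def drop(self, name: str) -> "DesignMatrix":
        """Reduced design with one predictor deleted (intercept kept)."""
        if name not in self.columns[1:]:
            raise KeyError(f"unknown predictor {name!r}")
        keep = [i for i, c in enumerate(self.columns) if c != name]
        return DesignMatrix(self.matrix[:, keep], tuple(self.columns[i] for i in keep))


def build_design(cohort: CohortTable, require_full_cells: bool = True) -> DesignMatrix:
    """Build the 2x2 factorial design from a cohort's sex/diagnosis codes.

    With all four sex-by-diagnosis cells occupied the design has full column
    rank; an empty cell raises :class:`RankError` unless
    ``require_full_cells=False``.
    """
    sex = cohort.sex.astype(float)
    dx = cohort.diagnosis.astype(float)
    if require_full_cells:
        cells = {(s, d) for s, d in zip(cohort.sex, cohort.diagnosis)}
        missing = {(s, d) for s in (1, -1) for d in (1, -1)} - cells
        if missing:
            raise RankError(f"empty sex-by-diagnosis cell(s): {sorted(missing)}")
    X = np.column_stack([np.ones_like(sex), sex, dx, sex * dx])
    return DesignMatrix(X)


# -- SSCP machinery ------------------------------------------------------------


def _fit_sscp(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit; returns (B, E, T) with T the intercept-corrected total SSCP."""
    n, k = X.shape
    if n <= k:
        raise InsufficientDFError(f"need n > {k} rows, got {n}")
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < k:
        raise RankError(f"design matrix rank {rank} < {k} columns")
    resid = Y - X @ B
    E = resid.T @ resid
    Yc = Y - Y.mean(axis=0)
    T = Yc.T @ Yc
    return B, 0.5 * (E + E.T), 0.5 * (T + T.T)


def _logdet_pd(A: np.ndarray, what: str) -> float:
    """log det of a symmetric positive-definite matrix via Cholesky."""
    try:
        c = linalg.cholesky(A, lower=True)
    except linalg.LinAlgError as exc:
        raise DegenerateDataError(
            f"{what} is singular or not positive definite; the response "
            "dimension p is too close to the error degrees of freedom - "
            "reduce p (fewer parcels) or increase the sample size"
        ) from exc
    return 2.0 * float(np.sum(np.log(np.diag(c))))


def wilks_lambda(h: np.ndarray, e: np.ndarray) -> float:
    """Wilks' Lambda = det(E) / det(E + H), via stable log-determinants."""
    h = np.asarray(h, float)
    e = np.asarray(e, float)
    if h.ndim == 0 or h.size == 1:
        hh, ee = float(np.squeeze(h)), float(np.squeeze(e))
        if ee <= 0:
            raise DegenerateDataError("scalar error SSCP must be > 0")
        return ee / (ee + hh)
    ld_e = _logdet_pd(e, "error SSCP E")
    ld_t = _logdet_pd(e + h, "total SSCP E + H")
    return float(min(1.0, np.exp(ld_e - ld_t)))


@dataclass(frozen=True)
class FResult:
    """Wilks Lambda with its Rao F transform and degrees of freedom.

    ``df2`` is Rao's (generally fractional) second df; ``df2_rounded`` is the
    integer shown in conventional report tables. ``w`` and ``t`` are the
    intermediates of the transformation.
    """

    wilks: float
    f: float
    df1: float
    df2: float
    p: float
    w: float
    t: float

    @property
    def df2_rounded(self) -> int:
        return int(round(self.df2))


def rao_f(lmbda: float, p: int, v_h: int, v_e: int) -> FResult:
    """Rao's approximate Lambda -> F transformation.

        t  = sqrt((p^2 vH^2 - 4) / (p^2 + vH^2 - 5))   (t = 1 if degenerate)
        w  = vE + vH - (p + vH + 1)/2
        d1 = p vH
        d2 = w t - (d1 - 2)/2
        F  = ((1 - Lambda^(1/t)) / Lambda^(1/t)) * d2/d1

    The transform is exact when min(p, vH) <= 2; for p = 1 it reduces to the
    univariate F with (vH, vE) df.
    """
    if not (0.0 < lmbda <= 1.0):
        if 1.0 < lmbda <= 1.0 + 1e-12:
            lmbda = 1.0
        else:
            raise DegenerateDataError(f"Wilks Lambda must be in (0, 1], got {lmbda}")
    if min(p, v_h, v_e) < 1:
        raise InsufficientDFError("p, vH and vE must all be >= 1")
    denom = p**2 + v_h**2 - 5
    t = np.sqrt((p**2 * v_h**2 - 4.0) / denom) if denom > 0 else 1.0
    w = v_e + v_h - (p + v_h + 1) / 2.0
    d1 = float(p * v_h)
    d2 = w * t - (d1 - 2.0) / 2.0
    if d2 <= 0:
        raise InsufficientDFError(
            f"second df d2 = {d2:.2f} <= 0 at p={p}, vH={v_h}, vE={v_e}"
        )
    lam_t = lmbda ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * (d2 / d1)
    pval = float(stats.f.sf(f, d1, d2))
    return FResult(wilks=float(lmbda), f=float(f), df1=d1, df2=float(d2), p=pval, w=float(w), t=float(t))


def partial_f_exact(partial_lambda: float, p: int, v_e: int) -> tuple[float, float, float, float]:
    """Exact partial-Lambda -> F for a single-df hypothesis (one predictor deleted).

    Returns (F, df1, df2, pvalue) with df (p, vE - p + 1).
    """
    df2 = v_e - p + 1
    if df2 < 1:
        raise InsufficientDFError(
            f"vE - p + 1 = {df2} < 1: too many responses (p={p}) for vE={v_e}"
        )
    lam = min(1.0, max(partial_lambda, np.finfo(float).tiny))
    f = (1.0 - lam) / lam * (df2 / p)
    return float(f), float(p), float(df2), float(stats.f.sf(f, p, df2))


# -- estimator -----------------------------------------------------------------


class MultivariateManova(BaseEstimator):
    """Wilks-lambda MANOVA of one metric panel against the 2x2 factorial design.

    Parameters
    ----------
    alpha : float
        Significance level used for reject flags.
    df_adjust : int
        Error degrees of freedom consumed upstream of this fit (e.g. the
        number of confound columns, beyond the intercept, projected out of Y
        during residualization). ``v_e_ = n - q - 1 - df_adjust``.

    Attributes (after ``fit``)
    --------------------------
    coef_ : (q+1, p) least-squares coefficients, row order = design columns.
    h_, e_, total_ : hypothesis, error and total (corrected) SSCP matrices.
    v_h_, v_e_ : hypothesis and error degrees of freedom.
    n_samples_, n_responses_ : N and p.
    """

    def __init__(self, alpha: float = 0.05, df_adjust: int = 0):
        self.alpha = alpha
        self.df_adjust = df_adjust

    def fit(self, Y, cohort: CohortTable | None = None, design: DesignMatrix | None = None):
        if design is None:
            if cohort is None:
                raise ValueError("provide either a cohort or a design")
            design = build_design(cohort)
        if isinstance(Y, MetricPanel):
            self.response_labels_ = tuple(Y.values.columns)
            Y = Y.data
        else:
            Y = np.asarray(Y, float)
            self.response_labels_ = tuple(f"y{j}" for j in range(Y.shape[1]))
        if Y.shape[0] != design.n:
            raise ValueError(f"Y has {Y.shape[0]} rows but design has {design.n}")
        self.design_ = design
        self._Y = Y
        B, E, T = _fit_sscp(design.matrix, Y)
        self.coef_ = B
        self.e_ = E
        self.total_ = T
        self.h_ = T - E
        self.v_h_ = design.q
        self.v_e_ = design.n - design.q - 1 - self.df_adjust
        if self.v_e_ < 1:
            raise InsufficientDFError(f"error df {self.v_e_} < 1")
        self.n_samples_ = design.n
        self.n_responses_ = Y.shape[1]
        return self

    def omnibus(self) -> FResult:
        """Omnibus Wilks/Rao test that no predictor has any effect."""
        lam = wilks_lambda(self.h_, self.e_)
        return rao_f(lam, self.n_responses_, self.v_h_, self.v_e_)

    def predictor_loo(self, alpha: float | None = None) -> pd.DataFrame:
        """Partial (leave-one-predictor-out) tests with BH-FDR across predictors.

        ``df1_alt``/``df2_alt`` record the alternative df bookkeeping
        (d1 = vH, d2 = vE - p) sometimes used for this test.
        """
        from .fdr import bh_fdr

        alpha = self.alpha if alpha is None else alpha
        ld_full = _logdet_pd(self.e_, "error SSCP E")
        rows = {}
        for name in self.design_.columns[1:]:
            reduced = self.design_.drop(name)
            _, e_red, _ = _fit_sscp(reduced.matrix, self._Y)
            lam = float(min(1.0, np.exp(ld_full - _logdet_pd(e_red, "reduced error SSCP"))))
            f, df1, df2, pval = partial_f_exact(lam, self.n_responses_, self.v_e_)
            rows[name] = {
                "partial_wilks": lam,
                "partial_f": f,
                "df1": df1,
                "df2": df2,
                "df1_alt": float(self.v_h_),
                "df2_alt": float(self.v_e_ - self.n_responses_),
                "p": pval,
            }
        table = pd.DataFrame.from_dict(rows, orient="index")
        p_adj, reject = bh_fdr(table["p"].to_numpy(), alpha)
        table["p_adj"] = p_adj
        table["reject"] = reject
        return table


# -- step-level wrappers -------------------------------------------------------


def omnibus_step1(
    panels: dict[str, MetricPanel],
    cohort: CohortTable,
    alpha: float = 0.05,
    df_adjust: int = 0,
    design: DesignMatrix | None = None,
) -> pd.DataFrame:
    """Per-metric omnibus Wilks/Rao tests with BH-FDR across the metrics.

    Returns one row per metric: Lambda, F, df, raw and adjusted p, and the
    FDR reject flag that gates Steps 2-4. Pass a confound-projected
    ``design`` when the panels have been residualized.
    """
    from .fdr import bh_fdr

    if design is None:
        design = build_design(cohort)
    rows = {}
    for name, panel in panels.items():
        fit = MultivariateManova(alpha=alpha, df_adjust=df_adjust).fit(panel, design=design)
        res = fit.omnibus()
        rows[name] = {
            "wilks": res.wilks,
            "f": res.f,
            "df1": res.df1,
            "df2": res.df2,
            "df2_rounded": res.df2_rounded,
            "p": res.p,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    p_adj, reject = bh_fdr(table["p"].to_numpy(), alpha)
    table["p_adj"] = p_adj
    table["reject"] = reject
    return table


def predictor_loo_step2(
    panel: MetricPanel | np.ndarray,
    cohort: CohortTable | None = None,
    alpha: float = 0.05,
    df_adjust: int = 0,
    design: DesignMatrix | None = None,
) -> pd.DataFrame:
    """Leave-one-predictor-out partial-F tests in the regression frame."""
    fit = MultivariateManova(alpha=alpha, df_adjust=df_adjust).fit(
        panel, cohort=cohort, design=design
    )
    return fit.predictor_loo()
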
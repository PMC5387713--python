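"""Preprocessing: TICV normalization, confound residualization, age^2 screen.

Every regional measure is divided by the subject's total intracranial volume
(head-size normalization), then the statistical effects of age, acquisition
site, cognitive ability (a DAS scale) and their interactions are partialed
out by ordinary least squares; all downstream inference runs on the
residuals. A reduced-model multivariate test decides whether a quadratic age
term is needed in the confound design.

Degrees-of-freedom bookkeeping: projecting k confound columns out of the
responses leaves errors of rank N - k, so the downstream error df should be
reduced accordingly. The residualizer reports its column count
(``n_confounds_``) and the pipeline subtracts it by default; setting
``adjust_df=False`` reproduces the naive vE = N - q - 1 bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import DAS_SCALES, CohortTable, MetricPanel
from .exceptions import CollinearityError, DegenerateDataError, InsufficientDFError
from .fdr import bh_fdr
from .manova import _fit_sscp, _logdet_pd, partial_f_exact

__all__ = [
    "ConfoundSpec",
    "LooTestResult",
    "TICVNormalizer",
    "ConfoundResidualizer",
    "ticv_normalize",
    "residualize",
    "quadratic_age_test",
    "quadratic_age_screen",
]


@dataclass(frozen=True)
class ConfoundSpec:
    """Which confounds enter the nuisance design.

    ``das_scales``: subset of the five DAS scores (default the general
    conceptual ability composite). ``interaction_order``: 0 = main effects
    only, 2 = plus all pairwise age/site/DAS products, 3 = plus the
    three-way products. ``adjust_df``: propagate the confound column count
    into downstream error df.
    """

    das_scales: tuple[str, ...] = ("gca",)
    interaction_order: int = 3
    adjust_df: bool = True

    def __post_init__(self) -> None:
        bad = set(self.das_scales) - set(DAS_SCALES)
        if bad:
            raise ValueError(f"unknown DAS scale(s) {sorted(bad)}; choose from {DAS_SCALES}")
        if self.interaction_order not in (0, 2, 3):
            raise ValueError("interaction_order must be 0, 2 or 3")


@dataclass(frozen=True)
class LooTestResult:
    """A reduced-model (leave-one-out) partial test result."""

    partial_wilks: float
    statistic: float
    df1: float
    df2: float
    p: float
    reject: bool


# -- TICV normalization --------------------------------------------------------


class TICVNormalizer(TransformerMixin, BaseEstimator):
    """Divide each subject's row by that subject's total intracranial volume."""

    def fit(self, cohort: CohortTable, y=None):
        ticv = cohort.ticv
        if (ticv <= 0).any():
            raise DegenerateDataError("TICV must be > 0 for every subject")
        self.ticv_ = ticv
        self.subject_ids_ = cohort.subject_ids
        return self

    def transform(self, panel: MetricPanel) -> MetricPanel:
        if tuple(panel.values.index) != self.subject_ids_:
            raise DegenerateDataError("panel subject order does not match the fitted cohort")
        return panel.with_values(panel.data / self.ticv_[:, None], normalized=True)


def ticv_normalize(panel: MetricPanel, cohort: CohortTable) -> MetricPanel:
    """Functional form of :class:`TICVNormalizer`."""
    return TICVNormalizer().fit(cohort).transform(panel)


# -- confound design and residualization ---------------------------------------


def _confound_columns(
    cohort: CohortTable,
    spec: ConfoundSpec,
    include_age_squared: bool = False,
) -> tuple[np.ndarray, list[str]]:
    f = cohort.frame
    n = len(f)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    blocks: dict[str, dict[str, np.ndarray]] = {}

    blocks["age"] = {"age": cohort.age}
    site_dummies = pd.get_dummies(f["site"], dtype=float)
    site_dummies = site_dummies.reindex(sorted(site_dummies.columns), axis=1).iloc[:, 1:]
    blocks["site"] = {f"site[{c}]": site_dummies[c].to_numpy() for c in site_dummies}
    blocks["das"] = {f"das_{s}": f[f"das_{s}"].to_numpy(float) for s in spec.das_scales}

    for block in blocks.values():
        cols.update(block)
    if spec.interaction_order >= 2:
        for b1, b2 in combinations(("age", "site", "das"), 2):
            for n1, v1 in blocks[b1].items():
                for n2, v2 in blocks[b2].items():
                    cols[f"{n1}:{n2}"] = v1 * v2
    if spec.interaction_order >= 3:
        for na, va in blocks["age"].items():
            for ns, vs in blocks["site"].items():
                for nd, vd in blocks["das"].items():
                    cols[f"{na}:{ns}:{nd}"] = va * vs * vd
    if include_age_squared:
        cols["age_sq"] = cohort.age**2
    names = list(cols)
    D = np.column_stack([cols[c] for c in names])
    _check_full_rank(D, names)
    return D, names


def _check_full_rank(D: np.ndarray, names: list[str]) -> None:
    from scipy import linalg

    _, R, piv = linalg.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps
    bad = diag <= tol
    if bad.any():
        dependent = [names[piv[i]] for i in np.flatnonzero(bad)]
        raise CollinearityError(
            f"confound design is rank deficient; dependent column(s): {dependent}"
        )


class ConfoundResidualizer(TransformerMixin, BaseEstimator):
    """Replace each parcel column by its least-squares residual against the
    confound design (intercept + confounds + requested interactions, sites
    dummy-coded). Residuals are orthogonal to every confound column and the
    projection is idempotent.

    Parameters mirror :class:`ConfoundSpec`; ``n_confounds_`` after ``fit``
    is the number of design columns beyond the intercept (the error df
    consumed by the projection).
    """

    def __init__(self, das_scales: tuple[str, ...] = ("gca",), interaction_order: int = 3):
        self.das_scales = das_scales
        self.interaction_order = interaction_order

    def fit(self, cohort: CohortTable, y=None):
        spec = ConfoundSpec(tuple(self.das_scales), self.interaction_order)
        D, names = _confound_columns(cohort, spec)
        self.design_ = D
        self.design_names_ = names
        self.n_confounds_ = D.shape[1] - 1
        self.subject_ids_ = cohort.subject_ids
        self._q, _ = np.linalg.qr(D)
        return self

    def transform(self, panel: MetricPanel) -> MetricPanel:
        if tuple(panel.values.index) != self.subject_ids_:
            raise DegenerateDataError("panel subject order does not match the fitted cohort")
        Y = panel.data
        resid = Y - self._q @ (self._q.T @ Y)
        return panel.with_values(resid)

    def transform_design(self, design):
        """Project the predictor columns of a design onto the confound-orthogonal
        complement (partial-regression / Frisch-Waugh form), keeping the
        intercept column. Hypothesis SSCPs built from the projected design are
        correctly scaled for residualized responses; without this step the
        partial tests are badly miscalibrated when many confounds are removed.
        """
        from .manova import DesignMatrix

        X = design.matrix.copy()
        X[:, 1:] = X[:, 1:] - self._q @ (self._q.T @ X[:, 1:])
        return DesignMatrix(X, design.columns)


def residualize(
    panel: MetricPanel,
    cohort: CohortTable,
    spec: ConfoundSpec | None = None,
) -> MetricPanel:
    """Functional form of :class:`ConfoundResidualizer`."""
    spec = spec or ConfoundSpec()
    est = ConfoundResidualizer(spec.das_scales, spec.interaction_order)
    return est.fit(cohort).transform(panel)


# -- quadratic age screen ------------------------------------------------------


def quadratic_age_test(
    panel: MetricPanel | np.ndarray,
    cohort: CohortTable,
    spec: ConfoundSpec | None = None,
    alpha: float = 0.05,
) -> LooTestResult:
    """Reduced-model test of the age^2 coefficient across all parcels.

    Compares the confound design with and without the age^2 column via a
    partial Wilks Lambda, converted by the exact single-df transform
    F = ((1 - L)/L) * ((vE - p + 1)/p) with (p, vE - p + 1) df, where
    vE = N - (full design column count).
    """
    spec = spec or ConfoundSpec()
    Y = panel.data if isinstance(panel, MetricPanel) else np.asarray(panel, float)
    n, p = Y.shape
    D_full, names = _confound_columns(cohort, spec, include_age_squared=True)
    D_red = D_full[:, [i for i, c in enumerate(names) if c != "age_sq"]]
    v_e = n - D_full.shape[1]
    if v_e - p + 1 < 1:
        raise InsufficientDFError(
            f"vE - p + 1 = {v_e - p + 1} < 1 for the age^2 test (n={n}, p={p})"
        )
    _, e_full, _ = _fit_sscp(D_full, Y)
    _, e_red, _ = _fit_sscp(D_red, Y)
    lam = float(min(1.0, np.exp(_logdet_pd(e_full, "full-model E") - _logdet_pd(e_red, "reduced-model E"))))
    f, df1, df2, pval = partial_f_exact(lam, p, v_e)
    return LooTestResult(
        partial_wilks=lam, statistic=f, df1=df1, df2=df2, p=pval, reject=pval <= alpha
    )


def quadratic_age_screen(
    panels: dict[str, MetricPanel],
    cohort: CohortTable,
    spec: ConfoundSpec | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Age^2 test per metric panel with BH-FDR across the metric family."""
    rows = {}
    for name, panel in panels.items():
        res = quadratic_age_test(panel, cohort, spec=spec, alpha=alpha)
        rows[name] = {
            "partial_wilks": res.partial_wilks,
            "partial_f": res.statistic,
            "df1": res.df1,
            "df2": res.df2,
            "p": res.p,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    p_adj, reject = bh_fdr(table["p"].to_numpy(), alpha)
    table["p_adj"] = p_adj
    table["reject"] = reject
    return table
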
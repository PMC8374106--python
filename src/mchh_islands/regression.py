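"""Model fits used by the analysis: logistic regression of island
presence on standardised genic predictors, |z| variable importance,
phylogenetic generalised least squares (PGLS) under Brownian motion, and
a small OLS helper with the signed-r2 display convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LogisticFit:
    predictors: list[str]
    params: pd.Series       # includes "const"
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    llf: float
    llf_null: float
    n: int
    n_dropped: int          # rows lost to listwise deletion
    converged: bool
    separation: bool
    collinear: bool


def logistic_fit(rows: pd.DataFrame, response: str,
                 predictors: Sequence[str]) -> LogisticFit:
    """Maximum-likelihood logistic regression (logit link).

    Rows with any missing predictor or response are dropped listwise; the
    dropped count is reported.  Complete/quasi-complete separation and
    collinearity are detected and flagged rather than silently returned.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    cols = [response, *predictors]
    data = rows.loc[:, cols].apply(pd.to_numeric).astype(float)
    n_before = len(data)
    data = data.dropna()
    n = len(data)
    y = data[response].to_numpy()
    if n == 0 or y.min() == y.max():
        raise ValueError("response must contain both events and non-events")
    X = sm.add_constant(data[list(predictors)], has_constant="add")

    collinear = np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=100, tol=1e-8)
        except Exception as exc:
            if collinear:
                # rank-deficient design: return a flagged, unusable fit
                nan = pd.Series(np.nan, index=X.columns)
                return LogisticFit(
                    predictors=list(predictors), params=nan, bse=nan,
                    zvalues=nan, pvalues=nan, llf=float("nan"),
                    llf_null=float("nan"), n=n, n_dropped=n_before - n,
                    converged=False, separation=False, collinear=True,
                )
            raise ValueError(f"logistic fit failed: {exc}") from exc
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                separation = True
    if not separation and np.abs(res.params.to_numpy()).max() > 1e3:
        separation = True

    return LogisticFit(
        predictors=list(predictors),
        params=res.params, bse=res.bse, zvalues=res.tvalues, pvalues=res.pvalues,
        llf=float(res.llf), llf_null=float(res.llnull), n=n,
        n_dropped=n_before - n,
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation, collinear=collinear,
    )


def variable_importance(fit: LogisticFit) -> pd.DataFrame:
    """Per-predictor importance for a logistic fit: |z| of the coefficient,
    plus the signed z whose sign encodes the direction of association."""
    if not fit.converged:
        raise ValueError("cannot rank predictors of an unconverged fit")
    if fit.collinear:
        raise ValueError("importance undefined for a collinear design")
    z = fit.zvalues.drop(labels=["const"], errors="ignore")
    return pd.DataFrame(
        {"importance": z.abs(), "signed_importance": z}
    ).loc[fit.predictors]


@dataclass
class PglsFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    covariance: pd.DataFrame  # Brownian tip covariance used
    n: int


def brownian_covariance(tree, taxa: Sequence[str]) -> pd.DataFrame:
    """Brownian-motion tip covariance: V_ij = shared root-to-tip path length.

    Computed from patristic distances as (d(root,i)+d(root,j)-d(i,j))/2.
    """
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in leaves]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    root_dist = {}
    for label in taxa:
        node, d = leaves[label], 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        root_dist[label] = d
    pdm = tree.phylogenetic_distance_matrix()
    taxon = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}
    n = len(taxa)
    V = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i == j:
                V[i, j] = root_dist[a]
            else:
                d = pdm.patristic_distance(taxon[a], taxon[b])
                V[i, j] = 0.5 * (root_dist[a] + root_dist[b] - d)
    return pd.DataFrame(V, index=list(taxa), columns=list(taxa))


def pgls_fit(y: Mapping[str, float], x: Mapping[str, float], tree,
             x_name: str = "x") -> PglsFit:
    """PGLS regression of y on x with Brownian covariance from ``tree``.

    beta = (X' V^-1 X)^-1 X' V^-1 y; t-tests on n - p degrees of freedom.
    On a star tree with equal branch lengths this reduces exactly to OLS.
    """
    import statsmodels.api as sm

    taxa = sorted(y)
    if sorted(x) != taxa:
        raise ValueError("y and x must cover the same species")
    n = len(taxa)
    if n <= 2:
        raise ValueError("PGLS needs more species than parameters (n > 2)")
    V = brownian_covariance(tree, taxa)
    yv = np.array([y[t] for t in taxa], dtype=float)
    X = pd.DataFrame({"const": 1.0, x_name: [x[t] for t in taxa]}, index=taxa)
    res = sm.GLS(yv, X, sigma=V.to_numpy()).fit()
    return PglsFit(
        params=res.params, bse=res.bse, tvalues=res.tvalues,
        pvalues=res.pvalues, covariance=V, n=n,
    )


@dataclass
class OlsFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    signed_r2: float
    n: int


def ols_fit(y, x) -> OlsFit:
    """Simple least squares of y on x; ``signed_r2 = sign(slope) * r^2``
    follows the display convention of reporting negative r2 for negative
    associations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    return OlsFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(r2), p_value=float(res.pvalue),
        signed_r2=float(np.sign(res.slope) * r2), n=len(x),
    )
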
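"""Spearman and partial Spearman correlation of metabolites with risk factors.

Partial Spearman is computed as Pearson correlation of rank residuals: all
variables are rank-transformed (average ranks on ties), the two variables of
interest are residualized on the covariates by least squares, and the
residuals are correlated; the t-approximation p-value loses one degree of
freedom per covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationResult:
    coefficients: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame      # Bonferroni-adjusted p < alpha
    alpha: float
    adjusted_for: list[str]


def _t_pvalue(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def spearman_matrix(x: pd.DataFrame, alpha: float = 0.05) -> CorrelationResult:
    """Pairwise Spearman correlations with t-approximation p-values and
    Bonferroni significance flags.

    Constant variables yield undefined (NaN) entries, flagged not
    significant.  Requires at least 3 observations.
    """
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 observations")
    cols = list(x.columns)
    ranks = x.rank(method="average")
    rho = ranks.corr(method="pearson").to_numpy()
    const = x.nunique().to_numpy() <= 1
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    p = _t_pvalue(rho.copy(), n - 2)
    np.fill_diagonal(p, 0.0)
    m = len(cols) * (len(cols) - 1) / 2  # tested pairs
    with np.errstate(invalid="ignore"):
        sig = (p * m) < alpha
    sig &= ~np.isnan(rho)
    np.fill_diagonal(sig, False)
    idx = pd.Index(cols)
    return CorrelationResult(
        coefficients=pd.DataFrame(rho, index=idx, columns=idx),
        p_values=pd.DataFrame(p, index=idx, columns=idx),
        significant=pd.DataFrame(sig, index=idx, columns=idx),
        alpha=alpha, adjusted_for=[],
    )


def partial_spearman(x, y, adjust: pd.DataFrame | None = None
                     ) -> tuple[float, float]:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates.

    With an empty covariate set this reduces exactly to the plain Spearman
    coefficient.  Collinear covariates raise with the offending columns.
    Returns ``(coefficient, p_value)``.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(xv)
    k = 0 if adjust is None else adjust.shape[1]
    if n <= k + 2:
        raise ValueError("n must exceed number of covariates + 2")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    if k == 0:
        r = float(np.corrcoef(rx, ry)[0, 1])
        return r, float(_t_pvalue(np.array([r]), n - 2)[0])
    Z = np.column_stack([np.ones(n)] +
                        [stats.rankdata(adjust[c]) for c in adjust.columns])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        bad = []
        basis = [0]
        for j in range(1, Z.shape[1]):
            if np.linalg.matrix_rank(Z[:, basis + [j]]) == len(basis) + 1:
                basis.append(j)
            else:
                bad.append(adjust.columns[j - 1])
        raise ValueError(f"collinear covariates: {bad}")
    beta_x, *_ = np.linalg.lstsq(Z, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    ex, ey = rx - Z @ beta_x, ry - Z @ beta_y
    denom = np.linalg.norm(ex) * np.linalg.norm(ey)
    if denom == 0:
        return np.nan, np.nan
    r = float(ex @ ey / denom)
    df = n - 2 - k
    return r, float(_t_pvalue(np.array([r]), df)[0])
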
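"""Epigenome-wide association testing with family-wise error control.

Each probe's M-values are regressed on case status plus optional age and
sex covariates by ordinary least squares; the case coefficient is tested
two-sided against a t distribution, and the Holm-Bonferroni step-down
procedure controls the family-wise error rate across all probes tested
jointly.  Probes that cannot be tested (zero residual variance) are kept
in the output with p_raw = 1 so probe accounting is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simcohort import RA_GROUPS

__all__ = ["EwasRow", "ewas_probe", "run_ewas", "holm_adjust"]


@dataclass
class EwasRow:
    probe_id: str
    effect: float
    se: float
    t_stat: float
    df: int
    p_raw: float


def holm_adjust(p_values, alpha: float = 0.05):
    """Holm-Bonferroni step-down adjustment.

    Sort p ascending; adjusted_(i) = max_{j<=i} min(1, (m-j+1) * p_(j));
    reject while adjusted <= alpha.  Returns (adjusted in input order,
    reject flags in input order).
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    factors = m - np.arange(m)
    adj_sorted = np.minimum(1.0, factors * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= alpha


def _ols_case(Y: np.ndarray, X: np.ndarray, case_col: int):
    """Vectorized OLS of each row of Y on the shared design X.

    Returns (effect, se, t, df, p_raw) arrays for the case column.
    Degenerate probes (zero residual variance) get p_raw = 1 when the
    effect is also zero, p_raw = 0 for an exact nonzero fit.
    """
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank-deficient (collinear covariates)")
    if n <= k:
        raise ValueError(f"need n > {k} samples for {k} model columns, got {n}")
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ Y.T)  # k x p
    resid = Y.T - X @ coef
    df = n - k
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    Rinv = np.linalg.inv(R)
    xtx_inv_diag = (Rinv @ Rinv.T)[case_col, case_col]
    se = np.sqrt(np.maximum(sigma2 * xtx_inv_diag, 0.0))
    effect = coef[case_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), np.nan)
    # residual variance indistinguishable from rounding noise => degenerate
    scale = np.maximum(np.einsum("ij,ij->j", Y.T, Y.T) / n, 1.0)
    degenerate = rss <= 1e-20 * scale
    zero_fit = degenerate & (np.abs(effect) < 1e-8 * np.sqrt(scale))
    effect = np.where(zero_fit, 0.0, effect)
    t = np.where(zero_fit, 0.0, t)
    p = np.where(zero_fit, 1.0, p)
    exact_fit = degenerate & ~zero_fit
    p = np.where(exact_fit, 0.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(exact_fit, np.sign(effect) * np.inf, t)
    return effect, se, t, df, p


def _build_design(case: np.ndarray, covariates: dict[str, np.ndarray]) -> np.ndarray:
    cols = [np.ones(case.size), case.astype(float)]
    cols.extend(np.asarray(v, float) for v in covariates.values())
    return np.column_stack(cols)


def ewas_probe(
    m_values,
    case,
    age=None,
    sex=None,
    probe_id: str = "probe",
) -> EwasRow:
    """Association test for a single probe.

    ``sex`` is a 0/1 indicator (1 = female).  Raises on a single-class
    case vector or a collinear design, naming the probe.
    """
    y = np.asarray(m_values, float)
    case = np.asarray(case, float)
    if len(np.unique(case)) < 2:
        raise ValueError(f"{probe_id}: case vector contains a single class")
    cov = {}
    if age is not None:
        cov["age"] = age
    if sex is not None:
        cov["sex"] = sex
    X = _build_design(case, cov)
    try:
        effect, se, t, df, p = _ols_case(y[None, :], X, case_col=1)
    except ValueError as exc:
        raise ValueError(f"{probe_id}: {exc}") from exc
    return EwasRow(probe_id, float(effect[0]), float(se[0]), float(t[0]), int(df),
                   float(p[0]))


def run_ewas(
    m_matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    case_groups=frozenset(RA_GROUPS),
    covariate_names: tuple[str, ...] = ("age", "sex"),
    alpha_fwer: float = 0.05,
    drop_age_zero: bool = True,
) -> pd.DataFrame:
    """EWAS over every probe in ``m_matrix``.

    ``case_groups`` defines the case class (default: all RA); every other
    group is control.  When age is a covariate, samples with age 0
    (newborn controls, whose age is on a different scale) are excluded
    by default rather than silently mixed in.

    Returns a DataFrame with columns probe_id, effect, se, t_stat, df,
    p_raw, p_holm, significant, in the input probe order.
    """
    sheet = sheet.set_index("sample_id").loc[list(m_matrix.columns)].reset_index()
    use = np.ones(len(sheet), bool)
    if "age" in covariate_names and drop_age_zero:
        use &= sheet["age"].to_numpy(float) > 0
    sub = sheet.loc[use]
    case = sub["group"].isin(case_groups).to_numpy()
    if case.all() or not case.any():
        raise ValueError("both case and control classes must be present")
    cov = {}
    for name in covariate_names:
        if name == "age":
            cov["age"] = sub["age"].to_numpy(float)
        elif name == "sex":
            cov["sex"] = (sub["sex"] == "F").to_numpy(float)
        else:
            cov[name] = sub[name].to_numpy(float)
    Y = m_matrix.loc[:, sub["sample_id"]].to_numpy(float)
    if np.isnan(Y).any():
        raise ValueError("M matrix contains missing values; run filter_probes first")
    X = _build_design(case, cov)
    effect, se, t, df, p_raw = _ols_case(Y, X, case_col=1)
    p_holm, significant = holm_adjust(p_raw, alpha_fwer)
    return pd.DataFrame(
        {
            "probe_id": m_matrix.index,
            "effect": effect,
            "se": se,
            "t_stat": t,
            "df": df,
            "p_raw": p_raw,
            "p_holm": p_holm,
            "significant": significant,
        }
    ).reset_index(drop=True)
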
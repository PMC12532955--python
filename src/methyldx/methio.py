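"""Beta/M-value transforms, cross-array harmonization and probe filtering.

M-values, M = log2(beta / (1 - beta)), are the analysis scale for the
association tests and the classifier: variance is more homoscedastic on
that scale, and under the logit-normal generative model the M-matrix is
exactly linear-Gaussian.  Beta values are kept for reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["beta_to_m", "m_to_beta", "harmonize_probes", "filter_probes"]


def beta_to_m(beta: pd.DataFrame, epsilon: float = 1e-6) -> pd.DataFrame:
    """M = log2(beta/(1-beta)) after clipping beta to [epsilon, 1-epsilon].

    Clipping bounds the transform at the degenerate endpoints 0 and 1;
    missing values stay missing.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = beta.to_numpy(float)
    b = np.clip(b, epsilon, 1.0 - epsilon)  # NaN passes through
    m = np.log2(b / (1.0 - b))
    return pd.DataFrame(m, index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse transform, beta = 2^M / (1 + 2^M)."""
    x = m.to_numpy(float)
    # numerically symmetric form of the logistic in base 2
    b = np.where(x >= 0, 1.0 / (1.0 + np.exp2(-x)), np.exp2(x) / (1.0 + np.exp2(x)))
    b[np.isnan(x)] = np.nan
    return pd.DataFrame(b, index=m.index, columns=m.columns)


def harmonize_probes(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge cohorts measured on different arrays onto their common probes.

    The output probe set is the intersection of the inputs' probe sets,
    ordered as in the first input; samples are concatenated in input
    order.  Intersection (rather than cross-array imputation) is
    conservative and deterministic.
    """
    if not matrices:
        raise ValueError("harmonize_probes needs at least one matrix")
    seen: set[str] = set()
    for mat in matrices:
        dup = seen.intersection(mat.columns)
        if dup:
            raise ValueError(f"duplicate sample id(s) across inputs: {sorted(dup)[:5]}")
        seen.update(mat.columns)
    common = set(matrices[0].index)
    for mat in matrices[1:]:
        common &= set(mat.index)
    if not common:
        raise ValueError("probe intersection across arrays is empty")
    order = [p for p in matrices[0].index if p in common]
    return pd.concat([mat.loc[order] for mat in matrices], axis=1)


def filter_probes(
    matrix: pd.DataFrame,
    max_missing_frac: float = 0.1,
    min_sd: float = 0.0,
) -> pd.DataFrame:
    """Drop unreliable probes and impute what remains.

    A probe is dropped when its missing fraction exceeds
    ``max_missing_frac`` or its standard deviation (over observed values,
    ddof=1) is below ``min_sd``.  Remaining missing values are imputed
    with the probe median, so the output has no missing values.
    """
    if not 0.0 <= max_missing_frac < 1.0:
        raise ValueError("max_missing_frac must be in [0, 1)")
    if min_sd < 0:
        raise ValueError("min_sd must be >= 0")
    vals = matrix.to_numpy(float)
    miss = np.isnan(vals).mean(axis=1)
    with np.errstate(invalid="ignore"):
        sd = np.array([
            np.nanstd(row, ddof=1) if np.sum(~np.isnan(row)) > 1 else 0.0
            for row in vals
        ])
    keep = (miss <= max_missing_frac) & (sd >= min_sd)
    if not keep.any():
        raise ValueError("filter_probes removed every probe")
    out = matrix.iloc[keep.nonzero()[0]]
    vals = out.to_numpy(float).copy()
    nan_rows = np.isnan(vals).any(axis=1).nonzero()[0]
    for i in nan_rows:
        row = vals[i]
        row[np.isnan(row)] = np.nanmedian(row)
    return pd.DataFrame(vals, index=out.index, columns=out.columns)
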
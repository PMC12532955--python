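"""Stability selection over complementary half-sample pairs.

For b = 1..B a complementary pair of disjoint, class-stratified
half-samples is drawn.  On each half an L1-dominated elastic-net
logistic path is fitted over a shared decreasing lambda grid on
within-half standardized features; a probe counts as selected in a half
at a given lambda when its coefficient is nonzero.  The selection
probability of probe j is

    pi_j = max over lambda of (#halves selecting j) / (2B),

the conventional "selected anywhere on the path" probability.  Features
are standardized within each half-sample, not globally, to avoid
leakage.  The lambda grid spans one decade below lambda_max by default,
keeping the fits in the sparse regime where selection probabilities
separate signal from noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._enet import default_lambda_grid, enet_path, lambda_max

__all__ = [
    "StabilityResult",
    "complementary_pairs",
    "stability_selection",
    "threshold_stability",
    "build_feature_panel",
]

logger = logging.getLogger(__name__)


@dataclass
class StabilityResult:
    """Per-probe selection probabilities plus run metadata."""

    pi: pd.Series  # indexed by probe_id, values in [0, 1]
    meta: dict = field(default_factory=dict)


def complementary_pairs(
    labels: np.ndarray, B: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """B complementary pairs of disjoint class-stratified half-samples.

    Each half receives floor(n_c/2) members of class c; with an odd
    class count one sample per class is left out of that pair.
    """
    labels = np.asarray(labels)
    idx_by_class = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    pairs = []
    for _ in range(B):
        h1, h2 = [], []
        for idx in idx_by_class:
            perm = rng.permutation(idx)
            half = len(idx) // 2
            h1.append(perm[:half])
            h2.append(perm[half : 2 * half])
        pairs.append((np.sort(np.concatenate(h1)), np.sort(np.concatenate(h2))))
    return pairs


def _standardize(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe


def stability_selection(
    m_matrix: pd.DataFrame,
    case_labels,
    B: int = 50,
    alpha_mix: float = 1.0,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 10,
    lambda_decades: float = 1.0,
    seed: int = 0,
    pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> StabilityResult:
    """Estimate per-probe selection probabilities.

    ``pairs`` overrides the random subsampling with an explicit list of
    complementary half-sample index pairs (used for exhaustive
    enumeration on tiny problems).
    """
    X_full = m_matrix.to_numpy(float).T  # samples x probes
    y = np.asarray(case_labels, float)
    n, p = X_full.shape
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    # the size guard protects random subsampling; explicitly enumerated
    # pairs (tiny exhaustive instances) bypass it
    if pairs is None and n // 2 < 4:
        raise ValueError(f"half-sample size {n // 2} < 4; too few samples")

    if lambda_grid is None:
        lam_max = lambda_max(_standardize(X_full), y, alpha_mix)
        lambda_grid = default_lambda_grid(lam_max, n_lambda, lambda_decades)
    lambda_grid = np.asarray(lambda_grid, float)

    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = complementary_pairs(y, B, rng)
    n_halves = 2 * len(pairs)

    counts = np.zeros((lambda_grid.size, p))
    for idx1, idx2 in pairs:
        for idx in (idx1, idx2):
            Xh = _standardize(X_full[idx])
            yh = y[idx]
            fits = enet_path(Xh, yh, lambda_grid, alpha_mix,
                             tol=tol, max_iter=max_iter)
            for li, fit in enumerate(fits):
                if not fit.converged:
                    logger.warning(
                        "half-fit did not converge at lambda=%.4g; counted as non-selected",
                        fit.lam,
                    )
                    continue
                counts[li] += fit.coef != 0
    pi = counts.max(axis=0) / n_halves
    return StabilityResult(
        pi=pd.Series(pi, index=m_matrix.index, name="pi"),
        meta={
            "B": len(pairs),
            "subsample_size": n // 2,
            "lambda_grid": [float(x) for x in lambda_grid],
            "alpha_mix": alpha_mix,
            "seed": seed,
        },
    )


def threshold_stability(result: StabilityResult, pi_threshold: float = 0.1) -> list[str]:
    """Probes with selection probability strictly greater than the threshold."""
    if not 0.0 <= pi_threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return list(result.pi.index[result.pi.to_numpy() > pi_threshold])


def build_feature_panel(ewas_ids, stability_ids) -> pd.DataFrame:
    """Union of the two discovery feature sets with provenance flags."""
    ewas_ids = list(ewas_ids)
    stability_ids = list(stability_ids)
    ewas_set, stab_set = set(ewas_ids), set(stability_ids)
    ordered = ewas_ids + [p for p in stability_ids if p not in ewas_set]
    return pd.DataFrame(
        {
            "probe_id": ordered,
            "from_ewas": [p in ewas_set for p in ordered],
            "from_stability": [p in stab_set for p in ordered],
        }
    )
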
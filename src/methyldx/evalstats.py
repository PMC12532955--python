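"""Diagnostic-performance evaluation with exact confidence intervals.

Sensitivity and specificity get exact (Clopper-Pearson) binomial
intervals via beta quantiles; the AUC point estimate is the
Mann-Whitney statistic with half-credit for ties, with a class-
stratified percentile-bootstrap interval.  Likelihood ratios, score
comparisons (Student's t), normality-gated correlation
(Shapiro-Wilk -> Pearson or Spearman) and quartile-correctness
summaries round out the report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "confusion",
    "diagnostic_metrics",
    "clopper_pearson",
    "auc_mann_whitney",
    "auc_ci_bootstrap",
    "compare_scores",
    "correlation_auto",
    "quartile_correctness",
    "evaluate",
    "round_half_up",
    "write_report",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for report display (0.885 -> 0.89)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_case(self) -> int:
        return self.tp + self.fn

    @property
    def n_control(self) -> int:
        return self.tn + self.fp


def confusion(pred, truth) -> ConfusionCounts:
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    return ConfusionCounts(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )


def diagnostic_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity, balanced accuracy and likelihood ratios.

    Undefined ratios (division by zero) are reported as ``math.inf`` or
    ``None`` rather than raising, except when a whole class is absent.
    """
    if counts.n_case == 0 and counts.n_control == 0:
        raise ValueError("no samples in either class")
    sens = counts.tp / counts.n_case if counts.n_case else None
    spec = counts.tn / counts.n_control if counts.n_control else None
    balanced = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    lr_pos = lr_neg = None
    if sens is not None and spec is not None:
        lr_pos = sens / (1.0 - spec) if spec < 1.0 else math.inf
        lr_neg = (1.0 - sens) / spec if spec > 0.0 else math.inf
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": balanced,
        "lr_pos": lr_pos,
        "lr_neg": lr_neg,
    }


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles."""
    if not (0 <= x <= n and n >= 1):
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    a = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(a / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - a / 2.0, x + 1, n - x))
    return lower, upper


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic with half-credit for ties.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_ci_bootstrap(
    scores, labels, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Class-stratified percentile bootstrap interval for the AUC."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    case = s[y == 1]
    ctrl = s[y == 0]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(case, size=case.size, replace=True)
        ks = rng.choice(ctrl, size=ctrl.size, replace=True)
        aucs[b] = auc_mann_whitney(
            np.concatenate([cs, ks]),
            np.concatenate([np.ones(cs.size), np.zeros(ks.size)]),
        )
    a = 1.0 - level
    lo, hi = np.quantile(aucs, [a / 2.0, 1.0 - a / 2.0])
    return float(lo), float(hi)


def compare_scores(scores, group_a, group_b) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance, two-sided).

    ``group_a`` / ``group_b`` are boolean masks or index arrays into
    scores; integer 0/1 arrays are interpreted as boolean masks.
    """
    s = np.asarray(scores, float)

    def _sel(g):
        g = np.asarray(g)
        if g.dtype != bool and g.size == s.size and set(np.unique(g)) <= {0, 1}:
            g = g.astype(bool)
        return s[g]

    xa, xb = _sel(group_a), _sel(group_b)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs at least two samples")
    if np.var(xa, ddof=1) == 0 and np.var(xb, ddof=1) == 0 and xa.mean() == xb.mean():
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(xa, xb, equal_var=True)
    return float(t), float(p)


def correlation_auto(x, y, normality_alpha: float = 0.05):
    """Pearson when both variables pass Shapiro-Wilk, else Spearman."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4 or y.size != x.size:
        raise ValueError("need n >= 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input")
    px = stats.shapiro(x).pvalue
    py = stats.shapiro(y).pvalue
    if px > normality_alpha and py > normality_alpha:
        r, p = stats.pearsonr(x, y)
        return "pearson", float(r), float(p)
    r, p = stats.spearmanr(x, y)
    return "spearman", float(r), float(p)


def quartile_correctness(scores, truth, cutoff: float) -> tuple[float, float]:
    """Fraction of correct calls within the bottom and top score quartiles.

    Quartiles are defined by score rank: the floor(n/4) lowest and
    highest scores (at least one sample each).
    """
    s = np.asarray(scores, float)
    y = np.asarray(truth).astype(int)
    n = s.size
    if n < 4:
        raise ValueError("need n >= 4")
    k = max(1, n // 4)
    order = np.argsort(s, kind="stable")
    calls = (s >= cutoff).astype(int)
    bottom = order[:k]
    top = order[-k:]
    return (
        float((calls[bottom] == y[bottom]).mean()),
        float((calls[top] == y[top]).mean()),
    )


def evaluate(
    scores,
    truth,
    cutoff: float,
    group_labels=None,
    subset_label: str = "all",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Full diagnostic report for one evaluation subset.

    ``truth`` is the binary case indicator, ``scores`` the continuous
    probability score, ``cutoff`` the fixed decision threshold estimated
    on training data.  ``group_labels`` (optional, per sample) adds
    per-group score medians and IQRs.
    """
    s = np.asarray(scores, float)
    y = np.asarray(truth).astype(int)
    calls = (s >= cutoff).astype(int)
    counts = confusion(calls, y)
    metrics = diagnostic_metrics(counts)
    sens_ci = clopper_pearson(counts.tp, counts.n_case, level)
    spec_ci = clopper_pearson(counts.tn, counts.n_control, level)
    auc = auc_mann_whitney(s, y)
    auc_ci = auc_ci_bootstrap(s, y, n_boot=n_boot, seed=seed, level=level)
    # balanced-accuracy CI via the same stratified bootstrap as the AUC
    rng = np.random.default_rng(seed)
    case_calls = calls[y == 1]
    ctrl_calls = calls[y == 0]
    bas = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(case_calls, size=case_calls.size, replace=True)
        ks = rng.choice(ctrl_calls, size=ctrl_calls.size, replace=True)
        bas[b] = (cs.mean() + (1 - ks).mean()) / 2.0
    a = 1.0 - level
    ba_ci = tuple(float(q) for q in np.quantile(bas, [a / 2.0, 1.0 - a / 2.0]))

    per_group = {}
    if group_labels is not None:
        gl = np.asarray(group_labels)
        for g in sorted(set(gl.tolist())):
            gs = s[gl == g]
            q1, med, q3 = np.quantile(gs, [0.25, 0.5, 0.75])
            per_group[str(g)] = {
                "n": int(gs.size),
                "median": float(med),
                "iqr": [float(q1), float(q3)],
            }
    frac_bottom, frac_top = quartile_correctness(s, y, cutoff)
    return {
        "subset": subset_label,
        "n_case": counts.n_case,
        "n_control": counts.n_control,
        "counts": {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn},
        "cutoff": float(cutoff),
        "sensitivity": {"value": metrics["sensitivity"], "ci": list(sens_ci)},
        "specificity": {"value": metrics["specificity"], "ci": list(spec_ci)},
        "balanced_accuracy": {"value": metrics["balanced_accuracy"], "ci": list(ba_ci)},
        "lr_pos": metrics["lr_pos"],
        "lr_neg": metrics["lr_neg"],
        "auc": {"value": auc, "ci": list(auc_ci)},
        "per_group_scores": per_group,
        "quartile_correctness": {"bottom": frac_bottom, "top": frac_top},
        "ci_level": level,
    }


def write_report(report: dict, directory: str | Path, stem: str = "report") -> None:
    """Write report.json plus a flat 2-dp report.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / f"{stem}.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    rows = []
    for subset, block in (report.items() if "subset" not in report else [("all", report)]):
        for key in ("sensitivity", "specificity", "balanced_accuracy", "auc"):
            entry = block[key]
            rows.append(
                {
                    "subset": block["subset"],
                    "metric": key,
                    "value": round_half_up(entry["value"]),
                    "ci_low": round_half_up(entry["ci"][0]),
                    "ci_high": round_half_up(entry["ci"][1]),
                }
            )
    pd.DataFrame(rows).to_csv(directory / f"{stem}.tsv", sep="\t", index=False)
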
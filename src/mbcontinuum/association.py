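"""Continuum-association statistics.

Kolmogorov-Smirnov tests compare the score distributions of samples
with versus without a clinico-pathological feature; gene-score
correlation screens (Spearman or Pearson) report per-quantile means and
log2 fold changes relative to the HighG4 category; p values are
adjusted by Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import LabeledMatrix, QUANTILE_ORDER, QuantileLabel, SampleTable, assign_quantile

__all__ = [
    "KSResult",
    "CorrelationResult",
    "ks_feature_scan",
    "correlation_scan",
    "bh_adjust",
]


@dataclass
class KSResult:
    feature: str
    D: float
    p: float
    p_adjusted: float
    n_with: int
    n_without: int


@dataclass
class CorrelationResult:
    gene: str
    method: str
    correlation: float  # NaN for constant genes
    p: float
    p_adjusted: float
    quantile_means: dict[str, float]
    log2_fold_change: dict[str, float]  # vs HighG4, +1 offset


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def ks_feature_scan(
    scores: Mapping[str, float],
    flags: SampleTable,
    exact_max_n: int = 25,
    min_arm: int = 3,
) -> tuple[list[KSResult], list[tuple[str, str]]]:
    """Two-sample KS tests of feature presence along the continuum.

    For each binary flag, the scores of samples with the feature are
    compared against those without ('unknown' samples excluded); the p
    value is exact (full enumeration) when the smaller arm has at most
    ``exact_max_n`` samples and asymptotic otherwise.  Features with
    fewer than ``min_arm`` samples in either arm are skipped.  BH
    adjustment runs across the tested features.

    Returns (results sorted by feature name, skipped (feature, reason)).
    """
    results: list[KSResult] = []
    skipped: list[tuple[str, str]] = []
    raw_p: list[float] = []
    for name in sorted(flags.flags):
        states = flags.flags[name]
        with_arm = [scores[s] for s, v in states.items() if v == "present" and s in scores]
        without_arm = [scores[s] for s, v in states.items() if v == "absent" and s in scores]
        if len(with_arm) < min_arm or len(without_arm) < min_arm:
            skipped.append(
                (name, f"arms {len(with_arm)}/{len(without_arm)} below minimum {min_arm}")
            )
            continue
        method = "exact" if min(len(with_arm), len(without_arm)) <= exact_max_n else "asymp"
        res = stats.ks_2samp(with_arm, without_arm, method=method)
        results.append(
            KSResult(name, float(res.statistic), float(res.pvalue), float("nan"),
                     len(with_arm), len(without_arm))
        )
        raw_p.append(float(res.pvalue))
    if not results:
        warnings.warn("no testable features")
        return [], skipped
    adj = bh_adjust(raw_p)
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results, skipped


def correlation_scan(
    expr: LabeledMatrix,
    scores: Mapping[str, float],
    method: str = "spearman",
    min_abs_fc: float = 0.0,
    pseudo_offset: float = 1.0,
) -> list[CorrelationResult]:
    """Per-gene correlation with the continuum score.

    Reports the chosen correlation with BH-adjusted p values, the mean
    expression per quantile category, and log2 fold changes of each
    category relative to HighG4 (with a +``pseudo_offset`` on the
    already-transformed expression scale).  Genes whose maximal absolute
    log2 fold change falls below ``min_abs_fc`` are dropped; constant
    genes are reported with a missing correlation.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    samples = [s for s in expr.col_ids if s in scores]
    if len(samples) < 3:
        raise ValueError("need >= 3 scored samples")
    X = expr.subset_cols(samples).to_dense()
    y = np.array([scores[s] for s in samples])
    quantiles = np.array([assign_quantile(v).value for v in y])
    cats = [q.value for q in QUANTILE_ORDER]

    results: list[CorrelationResult] = []
    pvals: list[float] = []
    testable: list[int] = []
    for i, gene in enumerate(expr.row_ids):
        x = X[i]
        q_means = {
            cat: (float(x[quantiles == cat].mean()) if (quantiles == cat).any() else float("nan"))
            for cat in cats
        }
        ref = q_means["HighG4"]
        fc = {
            cat: (
                float(np.log2((q_means[cat] + pseudo_offset) / (ref + pseudo_offset)))
                if np.isfinite(q_means[cat]) and np.isfinite(ref)
                else float("nan")
            )
            for cat in cats
        }
        if np.ptp(x) == 0:
            results.append(
                CorrelationResult(gene, method, float("nan"), float("nan"),
                                  float("nan"), q_means, fc)
            )
            continue
        if method == "spearman":
            r = stats.spearmanr(x, y)
        else:
            r = stats.pearsonr(x, y)
        results.append(
            CorrelationResult(gene, method, float(r.statistic), float(r.pvalue),
                              float("nan"), q_means, fc)
        )
        pvals.append(float(r.pvalue))
        testable.append(len(results) - 1)

    adj = bh_adjust(pvals)
    for idx, a in zip(testable, adj):
        results[idx].p_adjusted = float(a)

    if min_abs_fc > 0:
        results = [
            r for r in results
            if np.nanmax(np.abs(list(r.log2_fold_change.values()))) >= min_abs_fc
        ]
    return results
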
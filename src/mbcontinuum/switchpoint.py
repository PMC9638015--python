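"""Sigmoid switch-point analysis of CpG methylation along the continuum.

Per CpG, methylation beta values are regressed on the continuum score
with a four-parameter logistic

    beta(s) = b + (t - b) / (1 + exp((e50 - s) / delta)),

whose inflection e50 is the "switch point": the continuum coordinate at
which the CpG crosses the midpoint between its hypo- and hypermethylated
asymptotes.  Fits are aggregated over enhancer regions with the
inclusion filters (>= 5 CpGs, mean beta fold change > 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic import sigmoid_mean

__all__ = [
    "SigmoidFitConfig",
    "SigmoidFit",
    "RegionAggregate",
    "fit_sigmoid",
    "aggregate_regions",
]


@dataclass(frozen=True)
class SigmoidFitConfig:
    """Bounds and restart policy for the four-parameter logistic fit.

    e50 bounds extend slightly beyond [0, 1] to avoid boundary bias; a
    CpG only counts as "switching" when |t - b| >= ``switch_min_range``
    (below which the inflection is unidentifiable) and e50 lies in [0, 1].
    """

    e50_bounds: tuple[float, float] = (-0.2, 1.2)
    delta_bounds: tuple[float, float] = (0.005, 1.0)
    switch_min_range: float = 0.1
    max_restarts: int = 3
    seed: int = 0


@dataclass
class SigmoidFit:
    cpg_id: str
    b: float  # lower-score asymptote (beta units)
    t: float  # upper-score asymptote
    e50: float  # inflection on the score axis
    delta: float  # slope scale
    residual_sd: float
    converged: bool
    switching: bool
    direction: str  # hypo->hyper | hyper->hypo | none


def _initial_guess(s: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    order = np.argsort(s)
    s_sorted, y_sorted = s[order], y[order]
    n = len(s)
    dec = max(n // 10, 2)
    b0 = float(y_sorted[:dec].mean())
    t0 = float(y_sorted[-dec:].mean())
    # e50: score at maximal |smoothed finite-difference slope|
    win = max(n // 10, 3)
    kernel = np.ones(win) / win
    smooth = np.convolve(y_sorted, kernel, mode="valid")
    s_mid = np.convolve(s_sorted, kernel, mode="valid")
    ds = np.diff(s_mid)
    ds[ds == 0] = np.nan
    with np.errstate(invalid="ignore"):
        slope = np.diff(smooth) / ds
    if np.all(np.isnan(slope)):
        e50_0 = 0.5
    else:
        e50_0 = float(s_mid[np.nanargmax(np.abs(slope))])
    return b0, t0, e50_0, 0.1


def fit_sigmoid(
    scores: Sequence[float],
    betas: Sequence[float],
    cfg: SigmoidFitConfig = SigmoidFitConfig(),
    cpg_id: str = "cpg",
) -> SigmoidFit:
    """Fit the four-parameter logistic to (score, beta) pairs.

    Requires >= 20 paired observations with scores and betas in [0, 1].
    Initialization: asymptotes from the extreme score deciles, e50 from
    the maximal smoothed slope, delta = 0.1; up to ``max_restarts``
    jittered restarts on non-convergence.  Non-convergence yields
    ``converged=False`` and ``switching=False``.
    """
    s = np.asarray(scores, float)
    y = np.asarray(betas, float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and betas must be aligned 1-d vectors")
    if s.size < 20:
        raise ValueError(f"need >= 20 observations, got {s.size}")
    if s.min() < 0 or s.max() > 1 or y.min() < 0 or y.max() > 1:
        raise ValueError("scores and betas must lie in [0, 1]")

    lo = [0.0, 0.0, cfg.e50_bounds[0], cfg.delta_bounds[0]]
    hi = [1.0, 1.0, cfg.e50_bounds[1], cfg.delta_bounds[1]]
    b0, t0, e50_0, d0 = _initial_guess(s, y)
    p0 = [np.clip(b0, 0, 1), np.clip(t0, 0, 1), np.clip(e50_0, *cfg.e50_bounds), d0]

    rng = np.random.default_rng(cfg.seed)
    popt = None
    for attempt in range(cfg.max_restarts + 1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    sigmoid_mean, s, y, p0=p0, bounds=(lo, hi), maxfev=5000
                )
            break
        except (RuntimeError, ValueError):
            jitter = rng.normal(0, [0.05, 0.05, 0.1, 0.03])
            p0 = list(np.clip(np.asarray(p0) + jitter, lo, hi))
    if popt is None:
        return SigmoidFit(
            cpg_id, float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), converged=False, switching=False, direction="none",
        )
    b, t, e50, delta = (float(v) for v in popt)
    resid = y - sigmoid_mean(s, b, t, e50, delta)
    residual_sd = float(resid.std(ddof=min(4, s.size - 1)))
    switching = abs(t - b) >= cfg.switch_min_range and 0.0 <= e50 <= 1.0
    direction = "none"
    if switching:
        direction = "hypo->hyper" if t > b else "hyper->hypo"
    return SigmoidFit(cpg_id, b, t, e50, delta, residual_sd, True, switching, direction)


@dataclass
class RegionAggregate:
    chrom: str
    start: int  # 0-based half-open
    end: int
    name: str
    cpg_ids: list[str]
    n_cpgs: int
    mean_switch_point: float
    mean_beta_fold_change: float  # mean over CpGs of |t - b|
    included: bool


def aggregate_regions(
    fits: Sequence[SigmoidFit],
    cpg_positions: pd.DataFrame,
    regions: pd.DataFrame,
    min_cpgs: int = 5,
    min_mean_fold_change: float = 0.25,
) -> tuple[list[RegionAggregate], int]:
    """Aggregate converged switching fits over genomic regions.

    A CpG belongs to a region iff its position falls in [start, end)
    (0-based half-open) on the same chromosome.  A region is included
    when it holds >= ``min_cpgs`` switching CpGs and the mean |t - b|
    exceeds ``min_mean_fold_change`` (FDR pre-filtering of the regions
    is assumed upstream).

    ``cpg_positions`` needs columns (cpg_id, chrom, pos); ``regions``
    needs (chrom, start, end, name).  Returns the aggregates and the
    number of fitted CpGs skipped for lack of a position.
    """
    pos = cpg_positions.set_index("cpg_id")
    usable = [f for f in fits if f.converged and f.switching]
    skipped = 0
    located: list[tuple[str, int, SigmoidFit]] = []
    for f in usable:
        if f.cpg_id not in pos.index:
            skipped += 1
            continue
        located.append((str(pos.loc[f.cpg_id, "chrom"]), int(pos.loc[f.cpg_id, "pos"]), f))

    out: list[RegionAggregate] = []
    for _, reg in regions.iterrows():
        chrom, start, end = str(reg["chrom"]), int(reg["start"]), int(reg["end"])
        name = str(reg.get("name", f"{chrom}:{start}-{end}"))
        members = [f for (c, p, f) in located if c == chrom and start <= p < end]
        if not members:
            out.append(
                RegionAggregate(chrom, start, end, name, [], 0,
                                float("nan"), float("nan"), False)
            )
            continue
        e50s = np.array([f.e50 for f in members])
        fcs = np.array([abs(f.t - f.b) for f in members])
        included = len(members) >= min_cpgs and fcs.mean() > min_mean_fold_change
        out.append(
            RegionAggregate(
                chrom, start, end, name, [f.cpg_id for f in members],
                len(members), float(e50s.mean()), float(fcs.mean()), included,
            )
        )
    return out, skipped
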
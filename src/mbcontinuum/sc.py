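"""Projection of bulk metagenes onto single cells.

Cells are placed on the bulk-defined continuum: counts are depth
normalized (10,000 per cell, log1p), the most variable features are
selected by a standardized-variance criterion with a fitted
mean-variance trend, the bulk metagene basis is projected per cell, and
per-cell G3/G4 scores are computed with the bulk cohort's frozen
min-max range so cells and bulk tumors share one scale (cells may clip
at 0/1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm

from .core import LabeledMatrix, MatrixKind, QuantileLabel, assign_quantile, standardize_rows
from .nmf import MetageneBasis, project_metagenes
from .score import ContinuumScore, ScalingRange, g3g4_score

__all__ = [
    "CellScore",
    "bulk_standardization",
    "DistributionSummary",
    "select_variable_features",
    "project_cells",
    "summarize_distributions",
    "mark_top_decile",
]


@dataclass
class CellScore:
    cell_id: str
    patient_id: str
    subtype: str
    activations: dict[str, float]
    m3: float
    m4: float
    score: float
    quantile: QuantileLabel


@dataclass
class DistributionSummary:
    group: str  # patient or subtype id
    level: str  # "patient" | "subtype"
    n_cells: int
    p5: float
    median: float
    p95: float
    bin_fractions: dict[str, float]
    bulk_n: int | None
    bulk_p5: float | None
    bulk_median: float | None
    bulk_p95: float | None
    overlap_fraction: float | None  # cells inside the bulk [p5, p95] interval


def _moments(values: np.ndarray | sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mean and unbiased variance, sparse-aware."""
    if sp.issparse(values):
        n = values.shape[1]
        mean = np.asarray(values.mean(axis=1)).ravel()
        sq = np.asarray(values.multiply(values).mean(axis=1)).ravel()
        var = (sq - mean**2) * n / (n - 1)
        return mean, np.maximum(var, 0.0)
    mean = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    return mean, var


def select_variable_features(
    counts: LabeledMatrix, n: int = 5000, span: float = 0.3
) -> list[str]:
    """Top-n genes by standardized variance (variance-stabilizing trend).

    The expected SD of each gene comes from a local regression of
    log10(variance) on log10(mean) (span 0.3); counts are standardized
    against it, clipped at sqrt(n_cells), and genes ranked by the
    variance of the clipped values.  Zero-variance genes are never
    selected; if fewer than ``n`` variable genes exist they are all
    returned with a warning.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty matrix")
    mean, var = _moments(counts.values)
    variable = np.where((var > 0) & (mean > 0))[0]
    if variable.size == 0:
        raise ValueError("no gene has nonzero variance")
    if variable.size < n:
        warnings.warn(
            f"only {variable.size} variable genes available (requested {n})"
        )

    lm, lv = np.log10(mean[variable]), np.log10(var[variable])
    fitted = sm.nonparametric.lowess(lv, lm, frac=span, return_sorted=False)
    expected_sd = np.sqrt(10.0**fitted)

    n_cells = counts.shape[1]
    clip = np.sqrt(n_cells)
    X = counts.to_dense()[variable, :]
    z = (X - mean[variable, None]) / expected_sd[:, None]
    np.clip(z, -clip, clip, out=z)
    std_var = z.var(axis=1, ddof=1)

    order = variable[np.argsort(-std_var, kind="stable")]
    return [counts.row_ids[i] for i in order[:n]]


def bulk_standardization(activations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-metagene (mean, SD) of a bulk activation matrix (k x samples).

    Frozen into per-cell scoring so that cells and bulk tumors share one
    scale; constant metagenes get SD 1 (their z-scores are 0).
    """
    H = np.asarray(activations, float)
    mean = H.mean(axis=1)
    sd = H.std(axis=1)
    sd[sd == 0] = 1.0
    return mean, sd


def project_cells(
    basis: MetageneBasis,
    counts: LabeledMatrix,
    features: Sequence[str],
    bulk_range: ScalingRange,
    g3_metagene: str,
    g4_metagene: str,
    annotation: pd.DataFrame | None = None,
    standardization: tuple[np.ndarray, np.ndarray] | None = None,
    target_depth: float = 1e4,
) -> tuple[list[CellScore], list[str]]:
    """Score each cell on the bulk continuum.

    Pipeline: depth normalization to ``target_depth`` per cell + log1p,
    restriction to ``features``, the bulk projection protocol
    (column-rank + NNLS + unit-sum), standardization of each metagene
    (against the frozen bulk ``standardization`` (mean, SD) when given —
    the bulk-anchored common scale — otherwise across cells), and the
    G3/G4 score with the bulk cohort's frozen scaling range.  With both
    the standardization and the range frozen, a cell's score never
    depends on which other cells are scored.  Cells with zero counts on
    the feature set are flagged and receive no score.  ``annotation``
    (index cell_id, columns patient_id/subtype) fills the per-cell
    metadata.

    Returns (scores, flagged_cell_ids).
    """
    feats = [f for f in features if f in set(basis.feature_ids)]
    if not feats:
        raise ValueError("no overlap between features and basis")
    sub = counts.subset_rows([f for f in feats if f in set(counts.row_ids)])
    X = sub.to_dense()
    totals = X.sum(axis=0)
    flagged = [sub.col_ids[j] for j in np.where(totals == 0)[0]]
    keep = [j for j in range(X.shape[1]) if totals[j] > 0]
    X = X[:, keep]
    cells = [sub.col_ids[j] for j in keep]
    norm = np.log1p(target_depth * X / X.sum(axis=0, keepdims=True))
    lm = LabeledMatrix(norm, sub.row_ids, cells, MatrixKind.expression)

    act = project_metagenes(basis, lm)
    if standardization is not None:
        mean, sd = standardization
        H = (act.H - np.asarray(mean)[:, None]) / np.asarray(sd)[:, None]
    else:
        std = standardize_rows(
            LabeledMatrix(act.H, act.metagene_ids, act.sample_ids, MatrixKind.metagene)
        )
        H = std.to_dense()
    i3 = act.metagene_ids.index(g3_metagene)
    i4 = act.metagene_ids.index(g4_metagene)
    scores, _ = g3g4_score(H[i3], H[i4], cells, frozen_range=bulk_range)

    out: list[CellScore] = []
    for j, (cell, cs) in enumerate(zip(cells, scores)):
        patient, subtype = "", ""
        if annotation is not None and cell in annotation.index:
            patient = str(annotation.loc[cell].get("patient_id", ""))
            subtype = str(annotation.loc[cell].get("subtype", ""))
        out.append(
            CellScore(
                cell, patient, subtype,
                {mg: float(H[i, j]) for i, mg in enumerate(act.metagene_ids)},
                cs.m3, cs.m4, cs.score, cs.quantile,
            )
        )
    return out, flagged


def _summary(
    group: str, level: str, cell_scores: np.ndarray, bulk: np.ndarray | None,
    bin_width: float,
) -> DistributionSummary:
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    hist, _ = np.histogram(cell_scores, bins=edges)
    fractions = {
        f"[{edges[i]:.2f},{edges[i + 1]:.2f})": float(h / len(cell_scores))
        for i, h in enumerate(hist)
    }
    p5, med, p95 = np.percentile(cell_scores, [5, 50, 95])
    if bulk is not None and bulk.size:
        b5, bmed, b95 = np.percentile(bulk, [5, 50, 95])
        overlap = float(np.mean((cell_scores >= b5) & (cell_scores <= b95)))
        return DistributionSummary(
            group, level, len(cell_scores), float(p5), float(med), float(p95),
            fractions, int(bulk.size), float(b5), float(bmed), float(b95), overlap,
        )
    return DistributionSummary(
        group, level, len(cell_scores), float(p5), float(med), float(p95),
        fractions, None, None, None, None, None,
    )


def summarize_distributions(
    cells: Sequence[CellScore],
    bulk_scores: Sequence[ContinuumScore],
    bulk_subtypes: Mapping[str, str],
    bin_width: float = 0.25,
) -> list[DistributionSummary]:
    """Per-patient and per-subtype score-distribution summaries.

    Each group reports its 5th/50th/95th percentiles, the fraction of
    cells per score bin, and the overlap fraction: the share of cells
    inside the matched bulk subtype's [5th, 95th] percentile interval.
    Subtypes without a bulk counterpart get an undefined overlap.
    """
    bulk_by_subtype: dict[str, list[float]] = {}
    for cs in bulk_scores:
        st = bulk_subtypes.get(cs.sample_id)
        if st is not None:
            bulk_by_subtype.setdefault(st, []).append(cs.score)

    out: list[DistributionSummary] = []
    by_patient: dict[str, list[CellScore]] = {}
    by_subtype: dict[str, list[CellScore]] = {}
    for c in cells:
        by_patient.setdefault(c.patient_id, []).append(c)
        by_subtype.setdefault(c.subtype, []).append(c)

    for patient in sorted(by_patient):
        group = by_patient[patient]
        subtype = group[0].subtype
        bulk = np.array(bulk_by_subtype.get(subtype, []))
        out.append(
            _summary(patient, "patient", np.array([c.score for c in group]),
                     bulk if bulk.size else None, bin_width)
        )
    for subtype in sorted(by_subtype):
        group = by_subtype[subtype]
        bulk = np.array(bulk_by_subtype.get(subtype, []))
        out.append(
            _summary(subtype, "subtype", np.array([c.score for c in group]),
                     bulk if bulk.size else None, bin_width)
        )
    return out


def mark_top_decile(activations: Sequence[float]) -> np.ndarray:
    """Boolean mask of cells at or above the 90th activation percentile.

    With all-equal activations the percentile is degenerate and every
    cell is marked (with a warning).
    """
    a = np.asarray(activations, float)
    if a.size < 10:
        raise ValueError("need >= 10 cells")
    if np.ptp(a) == 0:
        warnings.warn("degenerate activations: all cells marked")
        return np.ones(a.size, dtype=bool)
    cutoff = np.percentile(a, 90)
    return a >= cutoff
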
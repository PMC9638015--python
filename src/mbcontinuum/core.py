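"""Shared data structures and elementary transforms.

Every pipeline stage exchanges data as :class:`LabeledMatrix` (a validated
features x samples matrix) and :class:`SampleTable` (per-sample annotation
with three-valued binary flags).  The elementary transforms here —
row standardization, robust min-max scaling and quantile-category
assignment — are the primitives the continuum score and the downstream
statistics are built from.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "MatrixKind",
    "LabeledMatrix",
    "SampleTable",
    "QuantileLabel",
    "QUANTILE_ORDER",
    "standardize_rows",
    "minmax_scale",
    "assign_quantile",
]


class MatrixKind(str, enum.Enum):
    """Semantic tag of a matrix; drives value-domain validation."""

    expression = "expression"
    beta = "beta"
    counts = "counts"
    metagene = "metagene"


class QuantileLabel(str, enum.Enum):
    """Notional fifths of the G3/G4 continuum (descriptive, not subgroups).

    A score of 0 is an archetypal group-4 tumor and 1 an archetypal
    group-3 tumor; the bins are (0, 0.2] -> HighG4 ... (0.8, 1] -> HighG3
    with the left boundary 0 folded into HighG4.
    """

    HighG4 = "HighG4"
    LowG4 = "LowG4"
    G3_5 = "G3.5"
    LowG3 = "LowG3"
    HighG3 = "HighG3"


#: Category order from the group-4 pole to the group-3 pole.
QUANTILE_ORDER: tuple[QuantileLabel, ...] = (
    QuantileLabel.HighG4,
    QuantileLabel.LowG4,
    QuantileLabel.G3_5,
    QuantileLabel.LowG3,
    QuantileLabel.HighG3,
)


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what}: {dups[:10]}")
    return ids


@dataclass
class LabeledMatrix:
    """A labeled numeric matrix with rows = features, columns = samples/cells.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix, shape (n_features, n_samples).
    row_ids, col_ids
        Unique identifiers matching the matrix dimensions.
    kind
        Semantic tag; ``beta`` requires finite values in [0, 1], ``counts``
        requires values >= 0.
    """

    values: np.ndarray | sp.spmatrix
    row_ids: list[str]
    col_ids: list[str]
    kind: MatrixKind = MatrixKind.expression

    def __post_init__(self) -> None:
        self.kind = MatrixKind(self.kind)
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 2:
                raise ValueError("values must be 2-dimensional")
        self.row_ids = _check_unique(self.row_ids, "row ids")
        self.col_ids = _check_unique(self.col_ids, "column ids")
        nr, nc = self.values.shape
        if nr != len(self.row_ids) or nc != len(self.col_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids / {len(self.col_ids)} column ids"
            )
        self._validate_domain()

    def _validate_domain(self) -> None:
        data = self.values.data if sp.issparse(self.values) else self.values
        if self.kind is MatrixKind.beta:
            if not np.all(np.isfinite(data)):
                raise ValueError("beta matrix contains non-finite values")
            if data.size and (data.min() < 0.0 or data.max() > 1.0):
                bad = self._locate(lambda v: (v < 0) | (v > 1))
                raise ValueError(f"beta values outside [0,1] at {bad}")
        elif self.kind is MatrixKind.counts:
            if data.size and data.min() < 0:
                bad = self._locate(lambda v: v < 0)
                raise ValueError(f"negative counts at {bad}")

    def _locate(self, pred) -> list[tuple[str, str]]:
        dense = self.to_dense()
        r, c = np.where(pred(dense))
        return [(self.row_ids[i], self.col_ids[j]) for i, j in zip(r[:5], c[:5])]

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.row_ids, columns=self.col_ids)

    def subset_rows(self, ids: Sequence[str]) -> "LabeledMatrix":
        idx = {r: i for i, r in enumerate(self.row_ids)}
        missing = [i for i in ids if i not in idx]
        if missing:
            raise KeyError(f"rows not present: {missing[:10]}")
        take = [idx[i] for i in ids]
        vals = self.values[take, :] if not sp.issparse(self.values) else self.values.tocsr()[take, :]
        return LabeledMatrix(vals, list(ids), list(self.col_ids), self.kind)

    def subset_cols(self, ids: Sequence[str]) -> "LabeledMatrix":
        idx = {c: i for i, c in enumerate(self.col_ids)}
        missing = [i for i in ids if i not in idx]
        if missing:
            raise KeyError(f"columns not present: {missing[:10]}")
        take = [idx[i] for i in ids]
        vals = self.values[:, take] if not sp.issparse(self.values) else self.values.tocsc()[:, take]
        return LabeledMatrix(vals, list(self.row_ids), list(ids), self.kind)


#: Allowed states of a binary clinico-pathological flag.
FLAG_STATES = ("present", "absent", "unknown")


@dataclass
class SampleTable:
    """Per-sample annotation: subgroup labels, binary flags, covariates.

    ``flags`` maps feature name -> {sample_id -> 'present'|'absent'|'unknown'};
    ``covariates`` maps name -> {sample_id -> float}.
    """

    sample_ids: list[str]
    subgroup: dict[str, str] = field(default_factory=dict)
    flags: dict[str, dict[str, str]] = field(default_factory=dict)
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        known = set(self.sample_ids)
        for name, states in self.flags.items():
            for s, v in states.items():
                if s not in known:
                    raise ValueError(f"flag {name!r} refers to unknown sample {s!r}")
                if v not in FLAG_STATES:
                    raise ValueError(
                        f"flag {name!r} sample {s!r}: state {v!r} not in {FLAG_STATES}"
                    )

    def flag_series(self, name: str) -> pd.Series:
        states = self.flags[name]
        return pd.Series(
            [states.get(s, "unknown") for s in self.sample_ids], index=self.sample_ids
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        if self.subgroup:
            df["subgroup"] = [self.subgroup.get(s, "") for s in self.sample_ids]
        for name in self.flags:
            df[name] = self.flag_series(name).values
        for name, vals in self.covariates.items():
            df[name] = [vals.get(s, np.nan) for s in self.sample_ids]
        return df


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def standardize_rows(m: LabeledMatrix) -> LabeledMatrix:
    """Standardize each row to mean 0 / unit population SD.

    Constant rows map to all-zeros.  The population SD convention
    (divide by n) is fixed so that e.g. [1, 2, 3] -> [-1.2247, 0, 1.2247].
    """
    values = m.to_dense()
    if not np.all(np.isfinite(values)):
        bad = [m.row_ids[i] for i in np.unique(np.where(~np.isfinite(values))[0])[:10]]
        raise ValueError(f"non-finite values in rows {bad}")
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population convention (ddof=0)
    out = np.where(sd > 0, (values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return LabeledMatrix(out, list(m.row_ids), list(m.col_ids), MatrixKind.metagene)


def minmax_scale(
    x: np.ndarray, robust_exclusion: bool = False, name: str = "vector"
) -> np.ndarray:
    """Scale a vector linearly to [0, 1].

    With ``robust_exclusion`` the scaling range is computed after dropping
    values beyond median +/- 4*MAD (a reproducible stand-in for ad hoc
    outlier removal) and the mapped values are clipped to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name}: non-finite values")
    if np.unique(x).size < 2:
        raise ValueError(f"{name}: constant vector cannot be min-max scaled")
    if robust_exclusion:
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad > 0:
            keep = np.abs(x - med) <= 4.0 * mad
        else:  # degenerate spread: fall back to the full range
            keep = np.ones_like(x, bool)
        lo, hi = x[keep].min(), x[keep].max()
        if hi <= lo:  # exclusion collapsed the range
            lo, hi = x.min(), x.max()
    else:
        lo, hi = x.min(), x.max()
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def assign_quantile(score: float) -> QuantileLabel:
    """Map a score in [0, 1] to its notional quantile category.

    Bins are right-closed: (0,0.2] HighG4, (0.2,0.4] LowG4, (0.4,0.6] G3.5,
    (0.6,0.8] LowG3, (0.8,1] HighG3; score 0 joins HighG4.
    """
    if not np.isfinite(score) or score < 0.0 or score > 1.0:
        raise ValueError(f"score {score!r} outside [0, 1]")
    if score <= 0.2:
        return QuantileLabel.HighG4
    if score <= 0.4:
        return QuantileLabel.LowG4
    if score <= 0.6:
        return QuantileLabel.G3_5
    if score <= 0.8:
        return QuantileLabel.LowG3
    return QuantileLabel.HighG3
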
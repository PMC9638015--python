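"""G3/G4 continuum score.

The score expresses the proportionate activation of the group-3 versus
the group-4 metagene in a sample: with bootstrap-averaged standardized
metagene values m3 and m4,

    raw = sigma(m3) / (sigma(m3) + sigma(m4)),   sigma(x) = 1/(1+exp(-x)),

and the cohort's raw values are min-max scaled to [0, 1] (0 = archetypal
group 4, 1 = archetypal group 3).  A frozen scaling range from a
reference cohort lets new samples or single cells be placed on the same
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import QuantileLabel, assign_quantile, minmax_scale

__all__ = ["ContinuumScore", "ScalingRange", "g3g4_score", "g3g4_raw"]


@dataclass
class ContinuumScore:
    sample_id: str
    m3: float
    m4: float
    raw: float
    score: float
    quantile: QuantileLabel


@dataclass(frozen=True)
class ScalingRange:
    """Frozen min/max of the raw score, persisted from a reference cohort."""

    lo: float
    hi: float

    def apply(self, raw: np.ndarray) -> np.ndarray:
        if self.hi <= self.lo:
            raise ValueError("degenerate scaling range")
        return np.clip((np.asarray(raw, float) - self.lo) / (self.hi - self.lo), 0.0, 1.0)


def g3g4_raw(m3: np.ndarray, m4: np.ndarray) -> np.ndarray:
    """Logistic proportion sigma(m3) / (sigma(m3) + sigma(m4)), in (0, 1)."""
    m3 = np.asarray(m3, float)
    m4 = np.asarray(m4, float)
    s3 = 1.0 / (1.0 + np.exp(-m3))
    s4 = 1.0 / (1.0 + np.exp(-m4))
    return s3 / (s3 + s4)


def g3g4_score(
    m3: np.ndarray,
    m4: np.ndarray,
    sample_ids: list[str] | None = None,
    robust_exclusion: bool = False,
    frozen_range: ScalingRange | None = None,
) -> tuple[list[ContinuumScore], ScalingRange]:
    """Compute per-sample continuum scores from G3/G4 metagene values.

    Applied to the samples called Grp3, Grp4 or Grp3/Grp4-indeterminate.
    With ``frozen_range`` the stored reference min/max is applied (scores
    clip at 0/1); otherwise the range is taken from this cohort, with
    optional median +/- 4*MAD outlier exclusion, and returned for reuse.
    """
    m3 = np.asarray(m3, float).ravel()
    m4 = np.asarray(m4, float).ravel()
    if m3.shape != m4.shape:
        raise ValueError("m3 and m4 must be aligned")
    if not (np.all(np.isfinite(m3)) and np.all(np.isfinite(m4))):
        raise ValueError("non-finite metagene values")
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(m3.size)]
    raw = g3g4_raw(m3, m4)
    if frozen_range is not None:
        score = frozen_range.apply(raw)
        out_range = frozen_range
    else:
        if np.unique(raw).size < 2:
            raise ValueError("degenerate cohort: all raw scores equal")
        score = minmax_scale(raw, robust_exclusion=robust_exclusion, name="raw score")
        # recover the effective range so it can be frozen for later cohorts
        if robust_exclusion:
            med = np.median(raw)
            mad = np.median(np.abs(raw - med))
            keep = np.abs(raw - med) <= 4.0 * mad if mad > 0 else np.ones_like(raw, bool)
            lo, hi = float(raw[keep].min()), float(raw[keep].max())
            if hi <= lo:
                lo, hi = float(raw.min()), float(raw.max())
        else:
            lo, hi = float(raw.min()), float(raw.max())
        out_range = ScalingRange(lo, hi)
    scores = [
        ContinuumScore(s, float(a), float(b), float(r), float(sc), assign_quantile(sc))
        for s, a, b, r, sc in zip(sample_ids, m3, m4, raw, score)
    ]
    return scores, out_range
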
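"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the continuum analysis assumes:

* bulk expression with four latent programs (WNT, SHH, G3, G4), where
  group-3/4 samples mix the G3 and G4 programs anticorrelatively along a
  latent score u in [0, 1] (u = 0: archetypal group 4, u = 1: group 3);
* beta-valued CpG methylation whose mean follows a per-CpG sigmoid of u
  ("switch" CpGs), a one-category step ("category-block" CpGs), or is
  flat ("null" CpGs), with Beta-distributed noise of precision phi;
* sparse single-cell counts whose per-cell latent scores are confined to
  subtype-specific windows of the continuum;
* binary clinical flags with logistic dependence on u.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy.random.Generator``, so a fixed config yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .core import (
    LabeledMatrix,
    MatrixKind,
    QuantileLabel,
    QUANTILE_ORDER,
    SampleTable,
    assign_quantile,
)

__all__ = [
    "ScConfig",
    "SimulationConfig",
    "SyntheticTruth",
    "sigmoid_mean",
    "generate_bulk",
    "generate_methylation",
    "generate_sc",
    "generate_feature_flags",
]

#: Default mixture over Beta distributions for the latent score u,
#: (weight, alpha, beta) per component.  Calibrated so the five quantile
#: categories are occupied at ~31/27/17/10/15%, i.e. weighted toward the
#: G4 pole with a secondary mode at the G3 pole.
DEFAULT_SCORE_MIXTURE: tuple[tuple[float, float, float], ...] = (
    (0.836, 1.23, 2.77),
    (0.164, 9.70, 1.27),
)

#: Default subtype -> continuum window for single-cell patients, ordered
#: from the most group-4-like (VIII) to the most group-3-like (II).
DEFAULT_SUBTYPE_WINDOWS: dict[str, tuple[float, float]] = {
    "VIII": (0.0, 0.25),
    "V": (0.2, 0.6),
    "I": (0.4, 0.7),
    "III": (0.5, 0.8),
    "II": (0.75, 1.0),
}

#: Default patient composition (15 patients across five subtypes).
DEFAULT_PATIENT_SUBTYPES: tuple[str, ...] = (
    ("VIII",) * 5 + ("V",) * 2 + ("I",) * 1 + ("III",) * 2 + ("II",) * 5
)


@dataclass(frozen=True)
class ScConfig:
    """Single-cell block of the simulation config."""

    depth: int = 5000
    cells_per_patient: int = 300
    patient_subtypes: tuple[str, ...] = DEFAULT_PATIENT_SUBTYPES
    subtype_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_WINDOWS)
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    Attributes
    ----------
    n_samples, n_genes, n_cpgs
        Cohort dimensions (300 bulk samples, 2,000 genes, 5,000 CpGs by
        default — desk scale).
    subgroup_proportions
        Fractions of WNT / SHH / Grp3/4 samples (must sum to 1).
    score_mixture
        (weight, alpha, beta) components of the Beta mixture generating
        the latent continuum score u of Grp3/4 samples.
    program_size
        Genes per latent expression program.
    program_amplitude
        (low, high) uniform range of per-gene program effect on the
        negative-binomial mean, in count units.
    nb_dispersion
        NB dispersion alpha (var = mu + alpha mu^2); 0 gives Poisson.
    beta_precision
        Precision phi of Beta-distributed methylation noise
        (var = mu(1-mu)/(phi+1)); ``math.inf`` disables noise.
    n_switch_cpgs, n_block_cpgs
        Number of sigmoid "switch" CpGs and of category-block CpGs per
        quantile category; the remaining CpGs are null.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_cpgs: int = 5000
    subgroup_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"WNT": 0.09, "SHH": 0.20, "Grp3/4": 0.71}
    )
    score_mixture: tuple[tuple[float, float, float], ...] = DEFAULT_SCORE_MIXTURE
    program_size: int = 100
    program_amplitude: tuple[float, float] = (50.0, 150.0)
    baseline_mean: float = 5.0
    nb_dispersion: float = 0.1
    count_noise: bool = True  # False: use the NB mean directly (noise-free)
    beta_precision: float = 50.0
    n_switch_cpgs: int = 400
    n_block_cpgs: int = 100
    sc: ScConfig = field(default_factory=ScConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.subgroup_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subgroup proportions sum to {total}, not 1")
        for n in (self.n_samples, self.n_genes, self.n_cpgs, self.program_size):
            if n <= 0:
                raise ValueError("counts must be positive")
        if self.program_size * 4 > self.n_genes:
            raise ValueError(
                f"4 programs x {self.program_size} genes exceed n_genes={self.n_genes}"
            )
        if not self.beta_precision > 0:
            raise ValueError("beta_precision must be > 0 (use math.inf for no noise)")


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generators (one record per entity)."""

    subgroup: dict[str, str] = field(default_factory=dict)
    score: dict[str, float] = field(default_factory=dict)  # Grp3/4 samples only
    program_membership: dict[str, str] = field(default_factory=dict)
    cpg_class: dict[str, str] = field(default_factory=dict)  # switch|block|null
    sigmoid_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )  # cpg -> (b, t, e50, delta)
    block_category: dict[str, QuantileLabel] = field(default_factory=dict)
    cell_patient: dict[str, str] = field(default_factory=dict)
    cell_subtype: dict[str, str] = field(default_factory=dict)
    cell_score: dict[str, float] = field(default_factory=dict)
    flag_coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        out = SyntheticTruth()
        for f in (
            "subgroup score program_membership cpg_class sigmoid_params "
            "block_category cell_patient cell_subtype cell_score flag_coefficients"
        ).split():
            getattr(out, f).update(getattr(self, f))
            getattr(out, f).update(getattr(other, f))
        return out


def sigmoid_mean(
    u: np.ndarray | float, b: float, t: float, e50: float, delta: float
) -> np.ndarray | float:
    """Four-parameter logistic mean beta(u) = b + (t-b) / (1 + exp((e50-u)/delta))."""
    return b + (t - b) / (1.0 + np.exp((e50 - np.asarray(u, float)) / delta))


def _sample_scores(rng: np.random.Generator, n: int, mixture) -> np.ndarray:
    weights = np.array([w for w, _, _ in mixture], float)
    weights = weights / weights.sum()
    comp = rng.choice(len(mixture), size=n, p=weights)
    u = np.empty(n)
    for i, (_, a, b) in enumerate(mixture):
        mask = comp == i
        u[mask] = rng.beta(a, b, size=int(mask.sum()))
    return np.clip(u, 0.0, 1.0)


def _subgroup_assignment(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Deterministic counts per subgroup (largest-remainder), random order."""
    names = list(cfg.subgroup_proportions)
    props = np.array([cfg.subgroup_proportions[k] for k in names], float)
    counts = np.floor(props * cfg.n_samples).astype(int)
    remainder = props * cfg.n_samples - counts
    for i in np.argsort(-remainder)[: cfg.n_samples - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(names, counts)
    return labels[rng.permutation(cfg.n_samples)]


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha  # NB shape: var = mu + alpha mu^2
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _bulk_model(rng: np.random.Generator, cfg: SimulationConfig):
    """Draw the shared latent model: subgroups, scores, W, baseline.

    Used by both bulk and single-cell generation so that a joint dataset
    built from one config shares the same planted programs.
    """
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    subgroups = _subgroup_assignment(rng, cfg)
    g34 = subgroups == "Grp3/4"
    u = np.full(cfg.n_samples, np.nan)
    u[g34] = _sample_scores(rng, int(g34.sum()), cfg.score_mixture)

    perm = rng.permutation(cfg.n_genes)
    membership = {g: "none" for g in gene_ids}
    W = np.zeros((cfg.n_genes, 4))
    lo, hi = cfg.program_amplitude
    for k, name in enumerate(("WNT", "SHH", "G3", "G4")):
        idx = perm[k * cfg.program_size : (k + 1) * cfg.program_size]
        W[idx, k] = rng.uniform(lo, hi, size=cfg.program_size)
        for i in idx:
            membership[gene_ids[i]] = name
    baseline = rng.gamma(2.0, cfg.baseline_mean / 2.0, size=cfg.n_genes)
    return gene_ids, subgroups, g34, u, W, baseline, membership


def generate_bulk(
    cfg: SimulationConfig,
) -> tuple[LabeledMatrix, SampleTable, SyntheticTruth]:
    """Generate a bulk expression cohort with four planted programs.

    WNT and SHH samples activate their own program at weight 1; Grp3/4
    samples activate the G3 program at weight f3(u) = u and the G4 program
    at f4(u) = 1 - u.  Negative-binomial counts around the linear mean
    model are log2(x+1)-transformed.

    Returns the expression matrix, the sample annotation and the truth.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    gene_ids, subgroups, g34, u, W, baseline, membership = _bulk_model(rng, cfg)

    # program activations, rows = (WNT, SHH, G3, G4)
    H = np.zeros((4, cfg.n_samples))
    H[0, subgroups == "WNT"] = 1.0
    H[1, subgroups == "SHH"] = 1.0
    H[2, g34] = u[g34]
    H[3, g34] = 1.0 - u[g34]

    mu = baseline[:, None] + W @ H
    counts = _nb_counts(rng, mu, cfg.nb_dispersion) if cfg.count_noise else mu
    expr = np.log2(counts + 1.0)

    table = SampleTable(sample_ids, subgroup=dict(zip(sample_ids, subgroups)))
    truth = SyntheticTruth(
        subgroup=dict(zip(sample_ids, subgroups)),
        score={s: float(u[i]) for i, s in enumerate(sample_ids) if g34[i]},
        program_membership=membership,
    )
    matrix = LabeledMatrix(expr, gene_ids, sample_ids, MatrixKind.expression)
    return matrix, table, truth


def generate_methylation(
    cfg: SimulationConfig, scores: Mapping[str, float]
) -> tuple[LabeledMatrix, SyntheticTruth]:
    """Generate a beta-value matrix for samples with known continuum scores.

    Three CpG classes are planted: ``switch`` CpGs whose mean follows a
    four-parameter sigmoid of u with per-CpG inflection e50; ``block``
    CpGs whose mean is elevated in exactly one quantile category; ``null``
    CpGs with a flat mean.  Observed values are Beta(mu*phi, (1-mu)*phi);
    phi = inf returns the means exactly.
    """
    sample_ids = list(scores)
    u = np.array([scores[s] for s in sample_ids], float)
    if u.size and (u.min() < 0 or u.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    n_block_total = cfg.n_block_cpgs * len(QUANTILE_ORDER)
    if cfg.n_switch_cpgs + n_block_total > cfg.n_cpgs:
        raise ValueError("n_cpgs too small for the requested switch/block CpGs")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    cpg_ids = [f"cg{i:06d}" for i in range(cfg.n_cpgs)]
    quantiles = np.array([assign_quantile(v).value for v in u])

    truth = SyntheticTruth()
    mu = np.empty((cfg.n_cpgs, len(sample_ids)))
    i = 0
    for _ in range(cfg.n_switch_cpgs):
        b = rng.uniform(0.05, 0.35)
        t = rng.uniform(0.65, 0.95)
        if rng.random() < 0.5:  # hyper -> hypo direction
            b, t = t, b
        e50 = rng.uniform(0.05, 0.95)
        delta = rng.uniform(0.05, 0.15)
        mu[i] = sigmoid_mean(u, b, t, e50, delta)
        truth.cpg_class[cpg_ids[i]] = "switch"
        truth.sigmoid_params[cpg_ids[i]] = (b, t, e50, delta)
        i += 1
    for cat in QUANTILE_ORDER:
        in_cat = quantiles == cat.value
        for _ in range(cfg.n_block_cpgs):
            base = rng.uniform(0.2, 0.3)
            high = rng.uniform(0.65, 0.85)
            mu[i] = np.where(in_cat, high, base)
            truth.cpg_class[cpg_ids[i]] = "block"
            truth.block_category[cpg_ids[i]] = cat
            i += 1
    for _ in range(cfg.n_cpgs - i):
        mu[i] = rng.uniform(0.1, 0.9)
        truth.cpg_class[cpg_ids[i]] = "null"
        i += 1

    phi = cfg.beta_precision
    if math.isinf(phi):
        beta = mu.copy()
    else:
        beta = rng.beta(mu * phi, (1.0 - mu) * phi)
    matrix = LabeledMatrix(beta, cpg_ids, sample_ids, MatrixKind.beta)
    truth.score = {s: float(v) for s, v in zip(sample_ids, u)}
    return matrix, truth


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Rejection-sampled truncated normal (windows are wide; cheap)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_sc(
    cfg: SimulationConfig,
) -> tuple[LabeledMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate sparse single-cell counts for subtype-constrained patients.

    Each patient carries a methylation subtype whose continuum window
    confines its cells' latent scores (truncated normal within the
    window); per-cell counts are Poisson draws at the configured depth
    from the bulk mean model evaluated at the cell's score.
    """
    sc = cfg.sc
    for st in sc.patient_subtypes:
        if st not in sc.subtype_windows:
            raise ValueError(f"no window for subtype {st!r}")
        lo, hi = sc.subtype_windows[st]
        if not (0 <= lo < hi <= 1):
            raise ValueError(f"empty or invalid window for subtype {st!r}: {(lo, hi)}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    # same latent model as generate_bulk (same seed -> same programs)
    bulk_rng = np.random.default_rng(cfg.seed)
    gene_ids, _, _, _, W, baseline, membership = _bulk_model(bulk_rng, cfg)

    truth = SyntheticTruth(program_membership=membership)
    blocks = []
    barcodes: list[str] = []
    for p, subtype in enumerate(sc.patient_subtypes):
        patient = f"P{p:02d}"
        w_lo, w_hi = sc.subtype_windows[subtype]
        center = rng.uniform(w_lo + 0.25 * (w_hi - w_lo), w_hi - 0.25 * (w_hi - w_lo))
        cell_u = _truncnorm(
            rng, center, (w_hi - w_lo) / 4.0, w_lo, w_hi, sc.cells_per_patient
        )
        mu = baseline[:, None] + W[:, 2:3] * cell_u + W[:, 3:4] * (1.0 - cell_u)
        p_gene = mu / mu.sum(axis=0, keepdims=True)
        counts = rng.poisson(sc.depth * p_gene)
        blocks.append(sp.csr_matrix(counts))
        for j in range(sc.cells_per_patient):
            bc = f"{patient}_cell{j:04d}"
            barcodes.append(bc)
            truth.cell_patient[bc] = patient
            truth.cell_subtype[bc] = subtype
            truth.cell_score[bc] = float(cell_u[j])

    counts = sp.hstack(blocks, format="csr")
    matrix = LabeledMatrix(counts, gene_ids, barcodes, MatrixKind.counts)
    annotation = pd.DataFrame(
        {
            "cell_id": barcodes,
            "patient_id": [truth.cell_patient[bc] for bc in barcodes],
            "subtype": [truth.cell_subtype[bc] for bc in barcodes],
        }
    ).set_index("cell_id")
    return matrix, annotation, truth


def generate_feature_flags(
    truth: SyntheticTruth,
    specs: Sequence[tuple[str, float, float]],
    seed: int = 0,
) -> SampleTable:
    """Draw binary clinical flags with P(present) = 1/(1+exp(-(a + b*u))).

    ``specs`` is a list of (name, a, b); only samples with a truth score
    receive a determinate state, all others are 'unknown'.
    """
    if not truth.score:
        raise ValueError("truth contains no continuum scores")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    sample_ids = list(truth.subgroup) if truth.subgroup else list(truth.score)
    scored = list(truth.score)
    u = np.array([truth.score[s] for s in scored])
    flags: dict[str, dict[str, str]] = {}
    out_truth_coef = {}
    for name, a, b in specs:
        p = expit(a + b * u)
        draw = rng.random(len(scored)) < p
        states = {s: ("present" if d else "absent") for s, d in zip(scored, draw)}
        for s in sample_ids:
            states.setdefault(s, "unknown")
        flags[name] = states
        out_truth_coef[name] = (float(a), float(b))
    truth.flag_coefficients.update(out_truth_coef)
    return SampleTable(sample_ids, subgroup=dict(truth.subgroup), flags=flags)
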
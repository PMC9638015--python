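"""Reverse-engineering the continuum score from DNA methylation.

Feature selection runs bootstrapped (80%, 100 iterations) differential
methylation tests on M-values between each quantile category and the
rest, keeps the 80 most frequently selected CpGs per comparison (five
one-vs-rest comparisons -> up to 400 unique features), and trains a
random-forest regressor subjected to recursive feature elimination
scored by repeated resampling.  The differential signal is a moderated
t-statistic with empirical-Bayes variance shrinkage, computed on
logit-transformed beta values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVR

from .core import LabeledMatrix, MatrixKind, QUANTILE_ORDER, QuantileLabel

__all__ = [
    "FeatureSelectionConfig",
    "CpGSelectionReport",
    "TrainConfig",
    "ScoreRegressor",
    "moderated_t",
    "select_features",
    "evaluate_feature_counts",
    "train_regressor",
    "predict_score",
]


# ---------------------------------------------------------------------------
# moderated t-statistic (empirical-Bayes shrunken variances)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed variances.

    Returns (d0, s0^2): the prior degrees of freedom and prior variance
    of the hierarchical variance model.  d0 = inf when the observed
    variances are less dispersed than chi^2 sampling alone explains.
    """
    s2 = np.maximum(np.asarray(s2, float), 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # less dispersion than chi^2 sampling alone: a point-mass prior at
        # the mean variance
        d0 = np.inf
        s0_2 = float(s2.mean())
    return d0, s0_2


def moderated_t(
    X: np.ndarray, group: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-group moderated t-test per row of X.

    Pooled row variances are shrunk toward a common prior fitted by
    moment-matching on log-variances; t-statistics are referred to a
    t distribution with the augmented degrees of freedom.

    Parameters
    ----------
    X : (features, samples) data matrix (M-values).
    group : boolean sample mask for group 1.

    Returns (t, p) arrays of length n_features.
    """
    g = np.asarray(group, bool)
    n1, n0 = int(g.sum()), int((~g).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs >= 2 samples")
    X1, X0 = X[:, g], X[:, ~g]
    m1, m0 = X1.mean(axis=1), X0.mean(axis=1)
    df = n1 + n0 - 2
    s2 = ((n1 - 1) * X1.var(axis=1, ddof=1) + (n0 - 1) * X0.var(axis=1, ddof=1)) / df
    d0, s0_2 = _fit_f_dist(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = 1e6
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    t = (m1 - m0) / np.maximum(se, 1e-300)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p


def _m_values(beta: np.ndarray, clamp: float = 1e-3) -> np.ndarray:
    b = np.clip(beta, clamp, 1.0 - clamp)
    return np.log2(b / (1.0 - b))


# ---------------------------------------------------------------------------
# bootstrapped feature selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSelectionConfig:
    boot_frac: float = 0.8
    n_boot: int = 100
    candidate_depth: int = 500  # CpGs counted as "selected" per bootstrap
    top_per_comparison: int = 80
    moderated: bool = True  # False: plain Welch t
    seed: int = 0


@dataclass
class CpGSelectionReport:
    """Per-comparison selection frequencies and the final feature set."""

    frequency: pd.DataFrame  # CpGs x comparisons, fraction of bootstraps
    mean_abs_t: pd.DataFrame  # CpGs x comparisons, tie-break statistic
    top_lists: dict[str, list[str]]  # comparison -> ranked top CpGs
    final_set: list[str]
    config: FeatureSelectionConfig

    def frequencies_for(self, comparison: str) -> pd.Series:
        return self.frequency[comparison]


def select_features(
    beta: LabeledMatrix,
    quantiles: Mapping[str, QuantileLabel],
    cfg: FeatureSelectionConfig = FeatureSelectionConfig(),
) -> CpGSelectionReport:
    """Bootstrapped one-vs-rest differential-methylation feature selection.

    Per bootstrap (``boot_frac`` of samples, ``n_boot`` iterations) and
    per quantile category, the ``candidate_depth`` smallest-p CpGs of a
    moderated t-test (category vs rest, on M-values) are recorded; the
    ``top_per_comparison`` most frequently recorded CpGs per comparison
    form the final set (union over comparisons).  Ties are broken by
    mean |t|, then CpG id.
    """
    if beta.kind is not MatrixKind.beta:
        raise ValueError("select_features expects a beta-value matrix")
    samples = [s for s in beta.col_ids if s in quantiles]
    if len(samples) < len(beta.col_ids):
        beta = beta.subset_cols(samples)
    labels = np.array([QuantileLabel(quantiles[s]).value for s in samples])
    cats = [q.value for q in QUANTILE_ORDER]
    for cat in cats:
        if (labels == cat).sum() < 2:
            raise ValueError(f"category {cat} has <2 samples")

    M = _m_values(beta.to_dense())
    n = len(samples)
    n_sub = int(np.floor(cfg.boot_frac * n))
    rng = np.random.default_rng(cfg.seed)
    n_cpg = len(beta.row_ids)
    counts = {cat: np.zeros(n_cpg) for cat in cats}
    t_sum = {cat: np.zeros(n_cpg) for cat in cats}
    t_n = {cat: np.zeros(n_cpg) for cat in cats}
    empty_boots = {cat: 0 for cat in cats}

    for _ in range(cfg.n_boot):
        idx = rng.choice(n, size=n_sub, replace=False)
        sub_labels = labels[idx]
        Msub = M[:, idx]
        for cat in cats:
            g = sub_labels == cat
            if g.sum() < 2 or (~g).sum() < 2:
                empty_boots[cat] += 1
                continue
            if cfg.moderated:
                t, p = moderated_t(Msub, g)
            else:
                t, p = stats.ttest_ind(
                    Msub[:, g], Msub[:, ~g], axis=1, equal_var=False
                )
            top = np.argsort(p, kind="stable")[: cfg.candidate_depth]
            counts[cat][top] += 1
            t_sum[cat][top] += np.abs(t[top])
            t_n[cat][top] += 1

    for cat, n_empty in empty_boots.items():
        if n_empty > 0.5 * cfg.n_boot:
            raise ValueError(
                f"category {cat} empty/undersized in {n_empty}/{cfg.n_boot} bootstraps"
            )

    freq = pd.DataFrame(
        {cat: counts[cat] / max(cfg.n_boot - empty_boots[cat], 1) for cat in cats},
        index=beta.row_ids,
    )
    with np.errstate(invalid="ignore"):
        mean_t = pd.DataFrame(
            {cat: np.where(t_n[cat] > 0, t_sum[cat] / np.maximum(t_n[cat], 1), 0.0)
             for cat in cats},
            index=beta.row_ids,
        )

    top_lists: dict[str, list[str]] = {}
    for cat in cats:
        order = sorted(
            range(n_cpg),
            key=lambda i: (-freq[cat].iloc[i], -mean_t[cat].iloc[i], beta.row_ids[i]),
        )
        top_lists[cat] = [beta.row_ids[i] for i in order[: cfg.top_per_comparison]]
    final = sorted(set().union(*top_lists.values()))
    return CpGSelectionReport(freq, mean_t, top_lists, final, cfg)


def evaluate_feature_counts(
    beta: LabeledMatrix,
    scores: Mapping[str, float],
    selection: CpGSelectionReport | None = None,
    candidate_counts: Sequence[int] = range(10, 101, 10),
    n_splits: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out error of a tuned RBF kernel regressor vs feature count.

    Features are ranked by their maximal per-comparison selection
    frequency (a quick selection pass is run if none is supplied); for
    each count the mean RMSE over repeated 80/20 splits is reported,
    with the plateau marked at the first count within 5% of the minimum.
    """
    samples = [s for s in beta.col_ids if s in scores]
    y = np.array([scores[s] for s in samples])
    if selection is None:
        from .core import assign_quantile

        quantiles = {s: assign_quantile(scores[s]) for s in samples}
        selection = select_features(beta, quantiles)
    rank_stat = selection.frequency.max(axis=1)
    tie = selection.mean_abs_t.max(axis=1)
    order = sorted(
        rank_stat.index, key=lambda c: (-rank_stat[c], -tie[c], c)
    )
    X_all = beta.subset_cols(samples).to_dense().T  # samples x cpgs
    col_of = {c: i for i, c in enumerate(beta.row_ids)}

    rng = np.random.default_rng(seed)
    grid = {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1]}
    rows = []
    for count in candidate_counts:
        if count > len(order):
            warnings.warn(f"count {count} exceeds available features; skipped")
            continue
        cols = [col_of[c] for c in order[:count]]
        errs = []
        for _ in range(n_splits):
            idx = rng.permutation(len(samples))
            n_tr = int(np.floor(0.8 * len(samples)))
            tr, te = idx[:n_tr], idx[n_tr:]
            svr = GridSearchCV(SVR(kernel="rbf"), grid, cv=3, scoring="neg_root_mean_squared_error")
            svr.fit(X_all[np.ix_(tr, cols)], y[tr])
            pred = np.clip(svr.predict(X_all[np.ix_(te, cols)]), 0.0, 1.0)
            errs.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
        rows.append(
            {"count": count, "rmse": float(np.mean(errs)),
             "rmse_se": float(np.std(errs, ddof=1) / np.sqrt(len(errs)))}
        )
    table = pd.DataFrame(rows)
    best = table["rmse"].min()
    table["plateau"] = False
    at = table.index[table["rmse"] <= 1.05 * best]
    if len(at):
        table.loc[at[0], "plateau"] = True
    return table


# ---------------------------------------------------------------------------
# random forest + recursive feature elimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    n_trees: int = 500
    rfe_sizes: tuple[int, ...] = (25, 50, 100, 200, 400)
    n_rfe_splits: int = 50  # repeated 80/20 resampling splits
    validation_folds: int = 10  # leave-group-out rebuilds
    seed: int = 0


@dataclass
class ScoreRegressor:
    model: RandomForestRegressor
    features: list[str]
    rfe_trace: pd.DataFrame  # size -> cross-validated RMSE (+ SE)
    validation_rmse: float
    config: TrainConfig


def _rf(cfg: TrainConfig, seed: int) -> RandomForestRegressor:
    # regression-forest conventions: mtry = p/3, terminal node size 5
    return RandomForestRegressor(
        n_estimators=cfg.n_trees, max_features=1 / 3, min_samples_leaf=5,
        random_state=seed, n_jobs=1,
    )


def train_regressor(
    beta: LabeledMatrix,
    scores: Mapping[str, float],
    selection: CpGSelectionReport,
    cfg: TrainConfig = TrainConfig(),
) -> ScoreRegressor:
    """Random-forest score regression with recursive feature elimination.

    RFE evaluates the subset sizes in ``rfe_sizes`` over repeated 80/20
    resampling splits (features re-ranked by importance within each
    split's training portion); the final size is the smallest within one
    standard error of the minimum RMSE.  Validation RMSE comes from
    ``validation_folds`` leave-group-out rebuilds of the final model.
    """
    if not selection.final_set:
        raise ValueError("empty feature selection")
    samples = [s for s in beta.col_ids if s in scores]
    if len(samples) < 30:
        raise ValueError(f"need >= 30 training samples, got {len(samples)}")
    y = np.array([scores[s] for s in samples], float)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    features = [c for c in selection.final_set if c in set(beta.row_ids)]
    X = beta.subset_rows(features).subset_cols(samples).to_dense().T

    rng = np.random.default_rng(cfg.seed)
    sizes = sorted({min(s, len(features)) for s in cfg.rfe_sizes})
    errs: dict[int, list[float]] = {s: [] for s in sizes}
    n = len(samples)
    n_tr = int(np.floor(0.8 * n))
    for _ in range(cfg.n_rfe_splits):
        idx = rng.permutation(n)
        tr, te = idx[:n_tr], idx[n_tr:]
        split_seed = int(rng.integers(2**31))
        ranker = _rf(cfg, split_seed).fit(X[tr], y[tr])
        rank = np.argsort(-ranker.feature_importances_, kind="stable")
        for s in sizes:
            cols = rank[:s]
            model = _rf(cfg, split_seed).fit(X[np.ix_(tr, cols)], y[tr])
            pred = np.clip(model.predict(X[np.ix_(te, cols)]), 0.0, 1.0)
            errs[s].append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))

    trace = pd.DataFrame(
        {
            "size": sizes,
            "rmse": [float(np.mean(errs[s])) for s in sizes],
            "rmse_se": [
                float(np.std(errs[s], ddof=1) / np.sqrt(len(errs[s]))) for s in sizes
            ],
        }
    )
    i_min = int(trace["rmse"].idxmin())
    threshold = trace.loc[i_min, "rmse"] + trace.loc[i_min, "rmse_se"]
    final_size = int(trace[trace["rmse"] <= threshold]["size"].min())

    full_seed = int(rng.integers(2**31))
    full = _rf(cfg, full_seed).fit(X, y)
    rank = np.argsort(-full.feature_importances_, kind="stable")
    retained_idx = np.sort(rank[:final_size])
    retained = [features[i] for i in retained_idx]

    # leave-group-out validation: rebuild without each fold
    folds = np.array_split(rng.permutation(n), cfg.validation_folds)
    oof = np.empty(n)
    for fold in folds:
        mask = np.ones(n, bool)
        mask[fold] = False
        model = _rf(cfg, full_seed).fit(X[np.ix_(mask, retained_idx)], y[mask])
        oof[fold] = model.predict(X[np.ix_(fold, retained_idx)])
    oof = np.clip(oof, 0.0, 1.0)
    validation_rmse = float(np.sqrt(np.mean((oof - y) ** 2)))

    final_model = _rf(cfg, full_seed).fit(X[:, retained_idx], y)
    return ScoreRegressor(final_model, retained, trace, validation_rmse, cfg)


def predict_score(reg: ScoreRegressor, beta: LabeledMatrix) -> dict[str, float]:
    """Predict continuum scores for new beta profiles (clipped to [0, 1])."""
    missing = [c for c in reg.features if c not in set(beta.row_ids)]
    if missing:
        raise KeyError(f"retained features missing from input: {missing[:10]}")
    X = beta.subset_rows(reg.features).to_dense().T
    pred = np.clip(reg.model.predict(X), 0.0, 1.0)
    return {s: float(p) for s, p in zip(beta.col_ids, pred)}
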
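"""Consensus NMF subgroup discovery.

The subgroup structure of a bulk expression cohort is estimated by
repeated non-negative matrix factorization on bootstrap subsamples:
each iteration factorizes 80% of the samples, projects the metagene
basis onto the held-out samples (column-rank normalization followed by
nonnegative least squares and unit-sum post-normalization), and
predicts each held-out sample's class by k-means nearest centroid.
Held-out votes are aggregated into per-sample consistency and a
samples x samples consensus matrix; a (rank, clusters) grid is scored
by average silhouette width, cophenetic index and mean consistency to
select the most stable solution.  Samples with <90% single-class
consistency become MB-NOS, unless group 3 + group 4 votes jointly
reach 90%, in which case they are indeterminate group 3/4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import LabeledMatrix, MatrixKind, standardize_rows

__all__ = [
    "MetageneBasis",
    "MetageneActivation",
    "ConsensusResult",
    "ModelSelectionReport",
    "SubgroupCall",
    "nmf_factorize",
    "project_metagenes",
    "consensus_classify",
    "cophenetic_index",
    "select_model",
    "call_subgroups",
    "averaged_metagenes",
]


@dataclass
class MetageneBasis:
    """Nonnegative basis W (features x k) of an NMF run."""

    W: np.ndarray
    feature_ids: list[str]
    metagene_ids: list[str]
    input_shift: float = 0.0  # subtracted from the input before factorization
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        if self.W.min() < 0:
            raise ValueError("basis contains negative entries")
        if np.any(self.W.sum(axis=0) == 0):
            raise ValueError("basis contains an all-zero metagene column")


@dataclass
class MetageneActivation:
    """Activation matrix H (k x samples).

    ``provenance`` is ``"single-run"`` (raw nonnegative H) or
    ``"bootstrap-averaged"`` (averaged across iterations and
    row-standardized, hence real-valued).
    """

    H: np.ndarray
    metagene_ids: list[str]
    sample_ids: list[str]
    provenance: str = "single-run"
    zero_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, float)
        if self.provenance == "single-run" and self.H.size and self.H.min() < -1e-12:
            raise ValueError("single-run activations must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.H, index=self.metagene_ids, columns=self.sample_ids)


@dataclass
class ConsensusResult:
    """Aggregated output of the resampled classification."""

    sample_ids: list[str]
    modal_class: dict[str, int]
    consistency: dict[str, float]  # NaN when never held out
    vote_counts: dict[str, dict[int, int]]  # held-out votes per sample
    consensus: np.ndarray  # samples x samples co-classification fraction
    activations: list[np.ndarray]  # per-iteration aligned k x n activations
    diagnostics: pd.DataFrame
    rank: int
    clusters: int
    seed: int
    never_held_out: list[str] = field(default_factory=list)


@dataclass
class ModelSelectionReport:
    grid: pd.DataFrame  # rank, clusters, cophenetic, silhouette, consistency, ...
    selected_rank: int
    selected_clusters: int
    rationale: list[str]
    results: dict[tuple[int, int], ConsensusResult] = field(default_factory=dict)


@dataclass
class SubgroupCall:
    sample_id: str
    call: str
    consistency: float
    breakdown: dict[str, float]


# ---------------------------------------------------------------------------
# factorization
# ---------------------------------------------------------------------------

def nmf_factorize(
    m: LabeledMatrix,
    k: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    record_objective: bool = False,
) -> tuple[MetageneBasis, MetageneActivation, float]:
    """Rank-k NMF by Frobenius multiplicative updates.

    Inputs with negative entries (e.g. variance-stabilized expression)
    are shifted by their global minimum; the shift is recorded on the
    basis.  Stops when the relative objective improvement drops below
    ``tol`` or after ``max_iter`` sweeps.  Returns (W, H, final
    reconstruction error), where the error is ||X - WH||_F; with
    ``record_objective`` the per-sweep objective trace is kept on the
    basis.
    """
    X = m.to_dense()
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    if k >= min(X.shape):
        raise ValueError(f"rank {k} must be < min{X.shape}")
    shift = float(min(0.0, X.min()))
    if shift < 0.0:
        X = X - shift
    eps = 1e-10
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), eps) / k)
    X = X.astype(np.float32)
    W = rng.uniform(eps, scale, size=(X.shape[0], k)).astype(np.float32)
    H = rng.uniform(eps, scale, size=(k, X.shape[1])).astype(np.float32)

    # objective via the trace identity ||X-WH||^2 = ||X||^2 - 2<W'X,H> + <W'W,HH'>,
    # checked every few sweeps (multiplicative updates are monotone regardless)
    xx = float(np.linalg.norm(X) ** 2)
    check_every = 1 if record_objective else 5
    trace: list[float] = []
    prev = None
    for it in range(max_iter):
        WtX = W.T @ X
        H *= WtX / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        if (it + 1) % check_every == 0 or it == max_iter - 1:
            WtX = W.T @ X
            HHt = H @ H.T
            obj = xx - 2.0 * float(np.sum(WtX * H)) + float(np.sum((W.T @ W) * HHt))
            if record_objective:
                trace.append(max(obj, 0.0))
            if prev is not None and prev - obj < tol * max(prev, eps) * check_every:
                prev = obj
                break
            prev = obj
    prev = max(prev, 0.0)
    W = W.astype(float)
    H = H.astype(float)

    # keep W columns informative: rescale so columns have unit max
    col_max = W.max(axis=0)
    col_max[col_max == 0] = 1.0
    W = W / col_max
    H = H * col_max[:, None]

    ids = [f"mg{j + 1}" for j in range(k)]
    basis = MetageneBasis(
        W + eps, list(m.row_ids), ids, input_shift=shift, objective_trace=trace
    )
    act = MetageneActivation(H, ids, list(m.col_ids), provenance="single-run")
    return basis, act, float(np.sqrt(prev))


def _column_ranks(X: np.ndarray) -> np.ndarray:
    """Fractional ranks within each column, scaled to (0, 1)."""
    r = rankdata(X, axis=0, method="average")
    return (r - 0.5) / X.shape[0]


def project_metagenes(basis: MetageneBasis, m: LabeledMatrix) -> MetageneActivation:
    """Project a basis onto new samples (column-rank + NNLS + unit-sum).

    Both the sample columns and the basis columns are replaced by
    fractional ranks scaled to (0, 1); each sample's activation solves
    h = argmin_{h>=0} ||a - W h||^2 and is then normalized to unit sum.
    Samples whose NNLS solution is identically zero are left as zeros
    and flagged in ``zero_samples``.
    """
    have = set(m.row_ids)
    common = [f for f in basis.feature_ids if f in have]
    if not common:
        raise ValueError("no features shared between basis and matrix")
    keep = [i for i, f in enumerate(basis.feature_ids) if f in have]
    Wr = _column_ranks(basis.W[keep, :])
    if common == list(m.row_ids):
        A = _column_ranks(m.to_dense())
    else:
        A = _column_ranks(m.subset_rows(common).to_dense())
    H, zero_idx = _nnls_unit_sum(Wr, A)
    zero = [m.col_ids[j] for j in zero_idx]
    return MetageneActivation(
        H, list(basis.metagene_ids), list(m.col_ids), "single-run", zero
    )


def _nnls_unit_sum(Wr: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Columnwise NNLS against Wr, unit-sum normalized; zero columns flagged.

    QR-reduces each problem: ||W h - a|| = ||R h - Q^T a|| + const.
    """
    Q, R = np.linalg.qr(Wr)
    rhs = Q.T @ A
    k, n = R.shape[1], A.shape[1]
    H = np.empty((k, n))
    zero: list[int] = []
    for j in range(n):
        h, _ = nnls(R, rhs[:, j])
        s = h.sum()
        if s <= 0:
            zero.append(j)
            H[:, j] = 0.0
        else:
            H[:, j] = h / s
    return H, zero


# ---------------------------------------------------------------------------
# consensus classification
# ---------------------------------------------------------------------------

def _greedy_match(score: np.ndarray) -> np.ndarray:
    """Greedy maximal assignment: perm[j] = row of `score` matched to col j."""
    score = score.copy()
    k = score.shape[0]
    perm = np.full(k, -1)
    for _ in range(k):
        i, j = np.unravel_index(np.nanargmax(score), score.shape)
        perm[j] = i
        score[i, :] = -np.inf
        score[:, j] = -np.inf
    return perm


def _align_to_reference(W_ref: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Permutation aligning W's columns to W_ref by greedy max Pearson."""
    k = W.shape[1]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(W_ref.T, W.T)[:k, k:]
    corr = np.nan_to_num(corr, nan=-1.0)
    return _greedy_match(corr.T)  # perm[j] = column of W matching ref column j


def consensus_classify(
    m: LabeledMatrix,
    k: int,
    c: int,
    n_iter: int = 250,
    frac: float = 0.8,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> ConsensusResult:
    """Resampled NMF + k-means class prediction.

    Per iteration: subsample ``floor(frac * n)`` samples without
    replacement, factorize at rank ``k``, project the basis onto all
    samples, fit k-means with ``c`` clusters on the training-sample
    activations and assign every sample to its nearest centroid.
    Metagene axes are aligned across iterations to the first run by
    greedy maximal-correlation matching of W columns, and cluster labels
    by greedy centroid matching.  Consistency is computed over held-out
    predictions only.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must be in (0, 1)")
    n = len(m.col_ids)
    n_train = int(np.floor(frac * n))
    if n_train < k + 1 or n_train >= n:
        raise ValueError(f"subsample size {n_train} incompatible with n={n}, k={k}")

    master = np.random.SeedSequence([seed, k, c])
    children = master.spawn(n_iter)
    rng = np.random.default_rng(master)
    # the rank transform of the full matrix is iteration-invariant
    A_ranked = _column_ranks(m.to_dense())

    W_ref: np.ndarray | None = None
    centroids_ref: np.ndarray | None = None
    labels_all = np.empty((n_iter, n), dtype=int)
    heldout_votes: list[dict[int, list[int]]] = [dict() for _ in range(n)]
    activations: list[np.ndarray] = []
    diag_rows = []
    votes = [dict() for _ in range(n)]  # sample -> class -> count (held-out only)

    for it in range(n_iter):
        it_seed = int(children[it].generate_state(1)[0] % (2**31))
        train = np.sort(rng.choice(n, size=n_train, replace=False))
        held = np.setdiff1d(np.arange(n), train)
        sub = m.subset_cols([m.col_ids[i] for i in train])
        basis, _, err = nmf_factorize(sub, k, seed=it_seed, tol=tol, max_iter=max_iter)
        H, _ = _nnls_unit_sum(_column_ranks(basis.W), A_ranked)

        if W_ref is None:
            perm = np.arange(k)
            W_ref = basis.W
        else:
            perm = _align_to_reference(W_ref, basis.W)
        H = H[perm, :]

        km = KMeans(n_clusters=c, n_init=10, random_state=it_seed)
        km.fit(H[:, train].T)
        centroids = km.cluster_centers_
        if centroids_ref is None:
            cperm = np.arange(c)
            centroids_ref = centroids
        else:
            d = np.linalg.norm(
                centroids_ref[:, None, :] - centroids[None, :, :], axis=2
            )
            cperm = _greedy_match(-d.T)  # cperm[ref_label] = this run's label
        # relabel: this run's label l -> reference label where cperm[ref] == l
        relabel = np.empty(c, dtype=int)
        relabel[cperm] = np.arange(c)

        raw_labels = km.predict(H.T)
        labels = relabel[raw_labels]
        labels_all[it] = labels
        for i in held:
            votes[i][labels[i]] = votes[i].get(labels[i], 0) + 1
        activations.append(H)
        diag_rows.append(
            {"iteration": it, "seed": it_seed, "reconstruction_error": err,
             "n_train": n_train, "n_heldout": len(held)}
        )

    consensus = np.zeros((n, n))
    for it in range(n_iter):
        same = labels_all[it][:, None] == labels_all[it][None, :]
        consensus += same
    consensus /= n_iter
    np.fill_diagonal(consensus, 1.0)

    modal: dict[str, int] = {}
    consistency: dict[str, float] = {}
    vote_counts: dict[str, dict[int, int]] = {}
    never: list[str] = []
    for i, s in enumerate(m.col_ids):
        v = votes[i]
        vote_counts[s] = dict(v)
        if not v:
            never.append(s)
            modal[s] = int(np.bincount(labels_all[:, i]).argmax())
            consistency[s] = float("nan")
            continue
        total = sum(v.values())
        best = max(sorted(v), key=lambda cl: v[cl])
        modal[s] = int(best)
        consistency[s] = v[best] / total

    if never:
        warnings.warn(f"{len(never)} samples never held out; consistency undefined")

    return ConsensusResult(
        sample_ids=list(m.col_ids),
        modal_class=modal,
        consistency=consistency,
        vote_counts=vote_counts,
        consensus=consensus,
        activations=activations,
        diagnostics=pd.DataFrame(diag_rows),
        rank=k,
        clusters=c,
        seed=seed,
        never_held_out=never,
    )


def cophenetic_index(C: np.ndarray) -> float:
    """Cophenetic correlation of average-linkage clustering of 1 - C.

    Returns NaN (flagged missing) when the consensus distances are
    constant, in which case the correlation is undefined.
    """
    C = np.asarray(C, float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("consensus matrix must be square symmetric")
    D = squareform(1.0 - C, checks=False)
    if D.size == 0 or np.ptp(D) == 0:
        return float("nan")
    Z = sch.linkage(D, method="average")
    coph, _ = sch.cophenet(Z, D)
    return float(coph)


def averaged_metagenes(
    runs: Sequence[np.ndarray],
    metagene_ids: Sequence[str],
    sample_ids: Sequence[str],
) -> MetageneActivation:
    """Average aligned per-iteration activations, then row-standardize.

    Every activation matrix must be k x n on the same aligned metagene
    axes; the bootstrap-averaged form has mean 0 / SD 1 per metagene.
    """
    if len(runs) < 2:
        raise ValueError("need >= 2 aligned runs")
    stack = np.stack([np.asarray(r, float) for r in runs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    missing = [sample_ids[j] for j in np.where(np.isnan(mean).any(axis=0))[0]]
    if missing:
        raise ValueError(f"samples absent from all runs: {missing[:10]}")
    lm = LabeledMatrix(mean, list(metagene_ids), list(sample_ids), MatrixKind.metagene)
    out = standardize_rows(lm)
    return MetageneActivation(
        out.to_dense(), list(metagene_ids), list(sample_ids), "bootstrap-averaged"
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def _redundant_metagenes(cr: ConsensusResult, threshold: float = 0.02) -> list[str]:
    """Metagenes that are the argmax for fewer than `threshold` of samples."""
    mean_act = np.mean(np.stack(cr.activations), axis=0)  # k x n
    share = np.bincount(mean_act.argmax(axis=0), minlength=mean_act.shape[0])
    share = share / mean_act.shape[1]
    return [f"mg{j + 1}" for j in np.where(share < threshold)[0]]


def select_model(
    m: LabeledMatrix,
    ranks: Sequence[int] = range(3, 11),
    clusters: Sequence[int] = range(3, 11),
    n_iter: int = 250,
    frac: float = 0.8,
    seed: int = 0,
    consistency_tol: float = 0.005,
    redundancy_threshold: float = 0.02,
    keep_results: bool = False,
    **nmf_kwargs,
) -> ModelSelectionReport:
    """Score a (rank, clusters) grid and select the most stable solution.

    Selection rationale: (i) choose c as the smallest cluster count at
    which the average silhouette width (on distance 1 - C) attains its
    per-rank maximum for the majority of ranks; (ii) among cells with
    that c, choose the smallest rank whose mean consistency is within
    ``consistency_tol`` of the maximum and which has no redundant
    metagene (argmax share below ``redundancy_threshold``).
    """
    ranks = list(ranks)
    clusters = list(clusters)
    if not ranks or not clusters:
        raise ValueError("empty model grid")
    rows = []
    results: dict[tuple[int, int], ConsensusResult] = {}
    for k in ranks:
        for c in clusters:
            try:
                cr = consensus_classify(
                    m, k, c, n_iter=n_iter, frac=frac, seed=seed, **nmf_kwargs
                )
                labels = np.array([cr.modal_class[s] for s in cr.sample_ids])
                D = 1.0 - cr.consensus
                np.fill_diagonal(D, 0.0)
                if np.unique(labels).size > 1:
                    sil = float(silhouette_score(D, labels, metric="precomputed"))
                else:
                    sil = float("nan")
                cons = float(np.nanmean(list(cr.consistency.values())))
                redundant = _redundant_metagenes(cr, redundancy_threshold)
                rows.append(
                    {"rank": k, "clusters": c, "cophenetic": cophenetic_index(cr.consensus),
                     "silhouette": sil, "mean_consistency": cons,
                     "redundant_metagenes": ",".join(redundant), "failed": False}
                )
                results[(k, c)] = cr
            except Exception as exc:  # non-converged / degenerate cells
                rows.append(
                    {"rank": k, "clusters": c, "cophenetic": float("nan"),
                     "silhouette": float("nan"), "mean_consistency": float("nan"),
                     "redundant_metagenes": "", "failed": True, "error": str(exc)}
                )
    grid = pd.DataFrame(rows)
    ok = grid[~grid["failed"]]
    if ok.empty:
        raise RuntimeError("no model grid cell converged")

    rationale: list[str] = []
    # (i) silhouette-maximizing cluster count per rank; majority vote
    argmax_counts: dict[int, int] = {c: 0 for c in clusters}
    n_ranks_scored = 0
    for k in ranks:
        sub = ok[ok["rank"] == k].dropna(subset=["silhouette"])
        if sub.empty:
            continue
        n_ranks_scored += 1
        best = sub["silhouette"].max()
        attaining = sorted(sub[sub["silhouette"] >= best - 1e-12]["clusters"])
        argmax_counts[attaining[0]] += 1
        rationale.append(
            f"rank {k}: silhouette max {best:.3f} attained first at c={attaining[0]}"
        )
    majority = [
        c for c in sorted(argmax_counts)
        if argmax_counts[c] * 2 > n_ranks_scored
    ]
    if majority:
        c_sel = majority[0]
        rationale.append(
            f"c={c_sel} attains the per-rank silhouette maximum for a majority "
            f"of ranks ({argmax_counts[c_sel]}/{n_ranks_scored})"
        )
    else:
        c_sel = min(
            sorted(argmax_counts), key=lambda c: (-argmax_counts[c], c)
        )
        rationale.append(
            f"no majority cluster count; c={c_sel} attains the maximum most often "
            f"({argmax_counts[c_sel]}/{n_ranks_scored})"
        )

    # (ii) smallest rank within tolerance of max consistency, no redundancy
    cand = ok[(ok["clusters"] == c_sel)].dropna(subset=["mean_consistency"])
    if cand.empty:
        raise RuntimeError(f"no scored cells at c={c_sel}")
    best_cons = cand["mean_consistency"].max()
    eligible = cand[
        (cand["mean_consistency"] >= best_cons - consistency_tol)
        & (cand["redundant_metagenes"] == "")
    ]
    if eligible.empty:
        eligible = cand[cand["mean_consistency"] >= best_cons - consistency_tol]
        rationale.append(
            "all near-maximal-consistency ranks carry redundant metagenes; "
            "redundancy constraint relaxed"
        )
    k_sel = int(eligible["rank"].min())
    rationale.append(
        f"at c={c_sel}: max mean consistency {best_cons:.4f}; smallest rank within "
        f"{consistency_tol} with no redundant metagene is k={k_sel}"
    )

    return ModelSelectionReport(
        grid=grid,
        selected_rank=k_sel,
        selected_clusters=c_sel,
        rationale=rationale,
        results=results if keep_results else {(k_sel, c_sel): results[(k_sel, c_sel)]},
    )


# ---------------------------------------------------------------------------
# subgroup calls
# ---------------------------------------------------------------------------

def call_subgroups(
    cr: ConsensusResult, cluster_to_name: Mapping[int, str]
) -> list[SubgroupCall]:
    """Apply the consistency rules to per-sample held-out votes.

    A sample whose modal class reaches >= 90% of held-out votes keeps
    that class's name.  Otherwise, if Grp3 + Grp4 votes jointly reach
    90% the sample is Grp3/Grp4-indeterminate, else MB-NOS.
    """
    observed = {cl for v in cr.vote_counts.values() for cl in v}
    observed.update(cr.modal_class.values())
    unmapped = sorted(observed - set(cluster_to_name))
    if unmapped:
        raise ValueError(f"clusters without a name: {unmapped}")

    calls: list[SubgroupCall] = []
    for s in cr.sample_ids:
        v = cr.vote_counts[s]
        total = sum(v.values())
        if total == 0:
            calls.append(SubgroupCall(s, "MB-NOS", float("nan"), {}))
            continue
        by_name: dict[str, float] = {}
        for cl, count in v.items():
            name = cluster_to_name[cl]
            by_name[name] = by_name.get(name, 0.0) + count / total
        top = max(sorted(by_name), key=lambda nm: by_name[nm])
        top_frac = by_name[top]
        combined34 = by_name.get("Grp3", 0.0) + by_name.get("Grp4", 0.0)
        if top_frac >= 0.9:
            call = top
        elif combined34 >= 0.9:
            call = "Grp3/Grp4-indeterminate"
        else:
            call = "MB-NOS"
        calls.append(SubgroupCall(s, call, top_frac, by_name))
    return calls
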
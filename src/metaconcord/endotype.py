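"""Multi-view integration and endotype clustering.

Views (viral, bacterial genus, bacterial species, host, diversity) are
prevalence-filtered (microbial features must be present in >= 30% of
samples, host transcripts in >= 50%), z-scored per feature, and factorized
into shared sample factors by a block-scaled singular value decomposition:
each view is scaled to unit total variance so no single view dominates, the
views are concatenated along features, and the left singular vectors of the
samples-by-features matrix (scaled by singular values) give the factor
scores. With a single view this reduces exactly to principal-component
scores; at full rank the reconstruction is exact. The factorization backend
is pluggable — any method returning shared sample factors can be swapped in.

Cluster count is chosen by majority vote of the gap statistic, mean
silhouette width and the within-sum-of-squares elbow, followed by k-means
(best of several seeded restarts); a forced k is also supported and both
are reported by the pipeline. Cluster agreement between two labelings is
the maximal fraction of co-assigned samples over label bijections.
Per-view effect sizes use a PERMANOVA-style R^2 = SS_between / SS_total on
pairwise Euclidean distances, with a permutation p-value (full enumeration
when feasible).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, factorial
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ViewMatrix",
    "FactorModel",
    "ClusteringResult",
    "EffectSize",
    "build_views",
    "factorize",
    "select_k",
    "kmeans_cluster",
    "cluster_agreement",
    "permanova_r2",
]


@dataclass
class ViewMatrix:
    name: str
    matrix: pd.DataFrame      # features x samples, z-scored rows
    prevalence_filter: float
    dropped_low_prevalence: int = 0
    dropped_zero_variance: int = 0


@dataclass
class FactorModel:
    n_factors: int
    factors: pd.DataFrame                      # samples x n_factors
    loadings: dict[str, pd.DataFrame]          # view -> features x n_factors
    variance_explained: pd.DataFrame           # views x factors
    view_scale: dict[str, float]               # per-view total-variance scale

    def reconstruct(self, view: str) -> pd.DataFrame:
        """Low-rank reconstruction of a (scaled) view, features x samples."""
        L = self.loadings[view].to_numpy()
        F = self.factors.to_numpy()
        rec = L @ F.T / self.view_scale[view]
        return pd.DataFrame(rec, index=self.loadings[view].index, columns=self.factors.index)


@dataclass
class ClusteringResult:
    labels: dict[str, int]
    k: int
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    embedding: Optional[pd.DataFrame] = None


@dataclass(frozen=True)
class EffectSize:
    view: str
    r_squared: float
    p: float
    n_permutations: int
    pseudo_f: float


def build_views(
    sources: Mapping[str, pd.DataFrame],
    microbe_prevalence: float = 0.30,
    host_prevalence: float = 0.50,
    host_views: Sequence[str] = ("host",),
    diversity_rows: Optional[Mapping[str, pd.DataFrame]] = None,
    presence: Optional[Mapping[str, pd.DataFrame]] = None,
) -> list[ViewMatrix]:
    """Prevalence-filter and z-score each view.

    ``sources`` maps view name to a features x samples value matrix (already
    normalized; presence defaults to value != 0 and not NaN, but an explicit
    boolean detection mask per view can be supplied — needed for scales like
    the ALR whose undetected cells carry a finite floor value).
    ``diversity_rows`` maps a view name to extra rows (e.g. Shannon and
    richness) appended before scaling. All views must share the same samples.
    """
    sample_sets = {frozenset(df.columns) for df in sources.values()}
    if len(sample_sets) != 1:
        raise ValueError("all views must share the same samples")
    views: list[ViewMatrix] = []
    for name, df in sources.items():
        thr = host_prevalence if name in host_views else microbe_prevalence
        if presence and name in presence:
            present = presence[name].reindex(index=df.index, columns=df.columns).fillna(False)
        else:
            present = df.notna() & (df != 0)
        prev = present.mean(axis=1)
        kept = df.loc[prev >= thr].copy()
        n_low = len(df) - len(kept)
        kept = kept.fillna(0.0)
        if diversity_rows and name in diversity_rows:
            kept = pd.concat([kept, diversity_rows[name]])
        sd = kept.std(axis=1, ddof=0)
        n_const = int((sd == 0).sum())
        kept = kept.loc[sd > 0]
        if len(kept) < 2:
            raise ValueError(f"view {name!r} has fewer than 2 usable features")
        z = kept.sub(kept.mean(axis=1), axis=0).div(kept.std(axis=1, ddof=0), axis=0)
        views.append(ViewMatrix(name, z, thr, n_low, n_const))
    return views


def factorize(views: Sequence[ViewMatrix], n_factors: int) -> FactorModel:
    """Shared sample factors via block-scaled SVD of the concatenated views.

    Each view block is divided by its Frobenius norm (unit total variance
    for z-scored rows) before concatenation. Sign convention: within each
    factor the largest-magnitude loading is positive, making the result
    deterministic for a given input.
    """
    samples = list(views[0].matrix.columns)
    n = len(samples)
    if n_factors > n - 1:
        raise ValueError(f"n_factors {n_factors} exceeds n_samples - 1 = {n - 1}")
    scales: dict[str, float] = {}
    blocks = []
    row_index: list[tuple[str, str]] = []
    for v in views:
        norm = float(np.linalg.norm(v.matrix.to_numpy()))
        scales[v.name] = 1.0 / norm if norm > 0 else 1.0
        blocks.append(v.matrix.to_numpy() * scales[v.name])
        row_index += [(v.name, f) for f in v.matrix.index]
    X = np.vstack(blocks)                     # features x samples
    A = X.T                                   # samples x features
    A = A - A.mean(axis=0, keepdims=True)     # rows are z-scored, so ~0 already
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    k = min(n_factors, len(S))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    factors = pd.DataFrame(
        U * S, index=samples, columns=[f"F{j + 1}" for j in range(k)]
    )
    loadings: dict[str, pd.DataFrame] = {}
    ve = {}
    offset = 0
    for v in views:
        m = len(v.matrix.index)
        block_v = Vt[:, offset: offset + m].T       # features x k
        loadings[v.name] = pd.DataFrame(
            block_v, index=v.matrix.index, columns=factors.columns
        )
        total = float(np.sum((v.matrix.to_numpy() * scales[v.name]) ** 2))
        per_factor = (S**2) * np.sum(block_v**2, axis=0)
        ve[v.name] = per_factor / total if total > 0 else per_factor * 0.0
        offset += m
    variance_explained = pd.DataFrame(ve, index=factors.columns).T
    return FactorModel(
        n_factors=k, factors=factors, loadings=loadings,
        variance_explained=variance_explained, view_scale=scales,
    )


def _within_ss(points: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        grp = points[labels == c]
        w += float(((grp - grp.mean(axis=0)) ** 2).sum())
    return w


def kmeans_cluster(
    points: pd.DataFrame | np.ndarray,
    k: int,
    restarts: int = 10,
    seed: int = 0,
) -> ClusteringResult:
    """Lloyd's k-means, best of ``restarts`` seeded initializations.

    Labels are canonicalized: clusters ordered by decreasing size, ties by
    the first sample index they contain.
    """
    if isinstance(points, pd.DataFrame):
        index = list(points.index)
        X = points.to_numpy(dtype=float)
    else:
        X = np.asarray(points, dtype=float)
        index = [str(i) for i in range(len(X))]
    if k > len(X):
        raise ValueError(f"k={k} exceeds n={len(X)}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    order = sorted(
        np.unique(raw),
        key=lambda c: (-int((raw == c).sum()), int(np.argmax(raw == c))),
    )
    remap = {c: i for i, c in enumerate(order)}
    labels = {index[i]: remap[raw[i]] for i in range(len(X))}
    return ClusteringResult(labels=labels, k=int(len(order)))


def _gap_statistic(
    X: np.ndarray, k: int, b_ref: int, rng: np.random.Generator, restarts: int
) -> tuple[float, float]:
    """Tibshirani gap: E_B[log W_ref] - log W_obs with a uniform-box
    reference; returns (gap, s_k)."""
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(rng.integers(2**31 - 1)),
                algorithm="lloyd").fit(X)
    w_obs = _within_ss(X, km.labels_)
    lo, hi = X.min(axis=0), X.max(axis=0)
    logs = []
    for _ in range(b_ref):
        ref = rng.uniform(lo, hi, size=X.shape)
        km_r = KMeans(n_clusters=k, n_init=1,
                      random_state=int(rng.integers(2**31 - 1)), algorithm="lloyd").fit(ref)
        logs.append(np.log(max(_within_ss(ref, km_r.labels_), 1e-300)))
    logs = np.asarray(logs)
    gap = float(logs.mean() - np.log(max(w_obs, 1e-300)))
    s_k = float(logs.std(ddof=0) * np.sqrt(1.0 + 1.0 / b_ref))
    return gap, s_k


def select_k(
    points: pd.DataFrame | np.ndarray,
    k_range: tuple[int, int] = (2, 6),
    b_ref: int = 20,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by majority vote of gap statistic,
    silhouette width and the within-SS elbow; ties go to the smallest k."""
    X = points.to_numpy(dtype=float) if isinstance(points, pd.DataFrame) else np.asarray(points, float)
    n = len(X)
    if n < 4:
        raise ValueError("select_k needs at least 4 samples")
    lo, hi = k_range
    ks = [k for k in range(lo, hi + 1) if 2 <= k <= n - 1]
    if not ks:
        raise ValueError(f"empty k range {k_range} for n={n}")
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd").fit(X)
        wss = _within_ss(X, km.labels_)
        sil = float(silhouette_score(X, km.labels_)) if len(np.unique(km.labels_)) > 1 else np.nan
        gap, s_k = _gap_statistic(X, k, b_ref, rng, restarts)
        rows.append({"k": k, "within_ss": wss, "silhouette": sil, "gap": gap, "gap_se": s_k})
    diag = pd.DataFrame(rows).set_index("k")

    # gap rule: smallest k with gap(k) >= gap(k+1) - se(k+1)
    gap_k = ks[-1]
    for i, k in enumerate(ks[:-1]):
        if diag.loc[k, "gap"] >= diag.loc[ks[i + 1], "gap"] - diag.loc[ks[i + 1], "gap_se"]:
            gap_k = k
            break
    sil_k = int(diag["silhouette"].idxmax())
    # elbow: largest drop-off in the within-SS decrease (maximum curvature)
    if len(ks) >= 3:
        w = diag["within_ss"].to_numpy()
        curv = (w[:-2] - w[1:-1]) - (w[1:-1] - w[2:])
        elbow_k = ks[1 + int(np.argmax(curv))]
    else:
        elbow_k = ks[0]
    votes = [gap_k, sil_k, elbow_k]
    counts = {k: votes.count(k) for k in set(votes)}
    best = max(counts.values())
    chosen = min(k for k, c in counts.items() if c == best)
    diag["vote"] = [votes.count(k) for k in diag.index]
    return int(chosen), diag.reset_index()


def cluster_agreement(
    a: ClusteringResult | Mapping[str, int], b: ClusteringResult | Mapping[str, int]
) -> tuple[float, dict[int, int]]:
    """Maximal fraction of identically assigned samples over label bijections
    (exhaustive for <= 6 labels, Hungarian assignment otherwise)."""
    la = a.labels if isinstance(a, ClusteringResult) else dict(a)
    lb = b.labels if isinstance(b, ClusteringResult) else dict(b)
    if set(la) != set(lb):
        raise ValueError("clusterings cover different sample sets")
    samples = sorted(la)
    ka = sorted(set(la.values()))
    kb = sorted(set(lb.values()))
    n = len(samples)
    cont = np.zeros((len(ka), len(kb)), dtype=int)
    ia = {c: i for i, c in enumerate(ka)}
    ib = {c: i for i, c in enumerate(kb)}
    for s in samples:
        cont[ia[la[s]], ib[lb[s]]] += 1
    if max(len(ka), len(kb)) <= 6:
        best, best_map = -1, {}
        small, large, transpose = (ka, kb, False) if len(ka) <= len(kb) else (kb, ka, True)
        for perm in itertools.permutations(range(len(large)), len(small)):
            m = sum(
                cont[i, perm[i]] if not transpose else cont[perm[i], i]
                for i in range(len(small))
            )
            if m > best:
                best = m
                if not transpose:
                    best_map = {ka[i]: kb[perm[i]] for i in range(len(small))}
                else:
                    best_map = {ka[perm[i]]: kb[i] for i in range(len(small))}
        return best / n, best_map
    ri, ci = linear_sum_assignment(-cont)
    matches = int(cont[ri, ci].sum())
    return matches / n, {ka[i]: kb[j] for i, j in zip(ri, ci)}


def _perm_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """R^2 and pseudo-F from squared pairwise distances (condensed form)."""
    n = len(labels)
    ss_total = d2.sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    sq = squareform(d2)
    for g in groups:
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            ss_within += sq[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    a = len(groups)
    dfb, dfw = a - 1, n - a
    f = (ss_between / dfb) / (ss_within / dfw) if dfw > 0 and ss_within > 0 else np.inf
    return float(r2), float(f)


def permanova_r2(
    data: pd.DataFrame | np.ndarray,
    labels: Mapping[str, int] | Sequence[int],
    n_permutations: int = 999,
    seed: int = 0,
    view: str = "",
    is_distance: bool = False,
) -> EffectSize:
    """Distance-based effect size of a grouping on a composition.

    ``data`` is samples x features (Euclidean distances computed) or a
    square distance matrix (``is_distance=True``). The p-value is by label
    permutation; when the number of distinct label arrangements is at most
    ``n_permutations`` the full enumeration is used instead.
    """
    if isinstance(data, pd.DataFrame):
        sample_ids = list(data.index)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        sample_ids = [str(i) for i in range(len(X))]
    if isinstance(labels, Mapping):
        lab = np.asarray([labels[s] for s in sample_ids])
    else:
        lab = np.asarray(list(labels))
    if len(np.unique(lab)) < 2:
        raise ValueError("permanova needs at least 2 groups")
    d = squareform(X, checks=False) if is_distance else pdist(X, metric="euclidean")
    d2 = d**2
    r2_obs, f_obs = _perm_stats(d2, lab)

    counts = {g: int((lab == g).sum()) for g in np.unique(lab)}
    n = len(lab)
    n_arrangements = factorial(n)
    for c in counts.values():
        n_arrangements //= factorial(c)
    rng = np.random.default_rng(seed)
    if n_arrangements <= n_permutations:
        from sympy.utilities.iterables import multiset_permutations

        stats = [
            _perm_stats(d2, np.asarray(perm))[1]
            for perm in multiset_permutations(list(lab))
        ]
        p = float(np.mean([s >= f_obs - 1e-12 for s in stats]))
        n_used = len(stats)
    else:
        ge = 1  # the identity permutation
        for _ in range(n_permutations):
            perm = rng.permutation(lab)
            if _perm_stats(d2, perm)[1] >= f_obs - 1e-12:
                ge += 1
        p = ge / (n_permutations + 1)
        n_used = n_permutations
    return EffectSize(view=view, r_squared=r2_obs, p=p, n_permutations=n_used, pseudo_f=f_obs)
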
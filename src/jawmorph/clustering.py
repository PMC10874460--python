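"""Consensus clustering into functional feeding groups.

Three clustering algorithms (Ward hierarchical, K-means, and partitioning
around medoids) are each run at the K selected by the gap statistic over a
defined K range (default 2-10, 2000 reference bootstrap cycles). Their
solutions are combined label-free through a taxon x taxon coassignment
matrix: composite groups are the connected components of the graph with an
edge wherever at least two of the three algorithms agree. Nested
subclustering of each composite group yields the finer feeding subgroups.

scikit-learn provides K-means, silhouettes and the adjusted Rand index;
SciPy provides Ward linkage; PAM (build + swap) and the gap statistic are
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    silhouette_samples,
)

__all__ = [
    "GapStatisticResult",
    "ClusterSolution",
    "ConsensusClassification",
    "cluster_once",
    "pam",
    "gap_statistic",
    "consensus_cluster",
    "subcluster",
    "validate_clusters",
    "variation_of_information",
]

ALGORITHMS = ("hierarchical", "kmeans", "pam")
DEFAULT_K_RANGE = tuple(range(2, 11))  # K in 2..10
DEFAULT_B = 2000  # gap-statistic reference cycles


@dataclass
class GapStatisticResult:
    algorithm: str
    k_values: list
    gap: np.ndarray
    se: np.ndarray
    log_wk: np.ndarray
    B: int
    selected_k: int
    seed: int = None

    def __post_init__(self):
        if not (len(self.gap) == len(self.se) == len(self.k_values)):
            raise ValueError("gap/se/k_values lengths differ")
        if self.selected_k not in self.k_values:
            raise ValueError("selected_k not in k_values")


@dataclass
class ClusterSolution:
    algorithm: str
    k: int
    labels: dict  # taxon -> cluster id (int)
    objective: float = None


@dataclass
class ConsensusClassification:
    """Composite feeding-group classification with per-algorithm detail."""

    level: str  # "FFG" or "FFsG"
    labels: dict  # taxon -> group id or "unstable"
    per_algorithm: list  # ClusterSolution per algorithm
    coassignment: np.ndarray  # taxa x taxa fractions in {0, 1/3, 2/3, 1}
    taxa: list
    agreement_rate: float
    silhouette: dict = field(default_factory=dict)
    external: dict = field(default_factory=dict)
    gap_results: list = field(default_factory=list)

    def group_members(self):
        out = {}
        for t, g in self.labels.items():
            if g != "unstable":
                out.setdefault(g, []).append(t)
        return out


# -- single-algorithm clustering -------------------------------------------------


def pam(X, k, seed=None, max_swap_iter=100):
    """Partitioning around medoids (BUILD + SWAP) on Euclidean distances.

    Deterministic given the data (BUILD is greedy; SWAP takes the best
    improving swap each pass). Returns (labels, total cost).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        # gain of adding candidate c = sum of reductions in nearest distance
        gains = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = list(medoids)
    # SWAP
    for _ in range(max_swap_iter):
        Dm = D[:, medoids]
        order = np.argsort(Dm, axis=1)
        d1 = Dm[np.arange(n), order[:, 0]]
        nearest = order[:, 0]
        d2 = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best = (0.0, None)
        for mi in range(k):
            is_m = nearest == mi
            for h in range(n):
                if h in medoids:
                    continue
                dh = D[:, h]
                delta = np.where(
                    is_m, np.minimum(dh, d2) - d1, np.minimum(0.0, dh - d1)
                ).sum()
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
    Dm = D[:, medoids]
    labels = np.argmin(Dm, axis=1)
    return labels, float(Dm.min(axis=1).sum())


def cluster_once(X, k, algorithm, seed=None, restarts=25):
    """Cluster a matrix into k groups with one named algorithm."""
    X = np.asarray(X, dtype=float)
    if algorithm == "hierarchical":
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        obj = _pooled_within_ss(X, labels)
    elif algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=restarts,
                    random_state=None if seed is None else int(seed) % (2**32))
        labels = km.fit_predict(X)
        obj = float(km.inertia_)
    elif algorithm == "pam":
        labels, obj = pam(X, k, seed=seed)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    labels = _relabel(labels)
    if len(set(labels)) != k:
        # Ward/k-means can return fewer groups on degenerate data
        warnings.warn(f"{algorithm}: {len(set(labels))} non-empty of {k} requested")
    return np.asarray(labels)


def _relabel(labels):
    """Canonical labels: 0..k-1 in order of first appearance."""
    mapping = {}
    out = []
    for l in labels:
        if l not in mapping:
            mapping[l] = len(mapping)
        out.append(mapping[l])
    return np.asarray(out)


def _pooled_within_ss(X, labels):
    tot = 0.0
    for g in np.unique(labels):
        sub = X[labels == g]
        tot += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(tot)


# -- gap statistic ----------------------------------------------------------------


def _reference_box(X):
    """Uniform reference distribution over the PCA-aligned bounding box."""
    mu = X.mean(axis=0)
    Xc = X - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)
    return mu, Vt, lo, hi


def gap_statistic(data, algorithm="kmeans", k_range=DEFAULT_K_RANGE,
                  B=DEFAULT_B, seed=None, restarts=25):
    """Gap-statistic selection of the cluster number K.

    For each K, ``Gap(K) = mean_b log W*_Kb - log W_K`` where W is the pooled
    within-cluster sum of squares and the B reference datasets are uniform
    over the principal-component-aligned bounding box of the data. The
    simulation standard error carries the sqrt(1 + 1/B) factor, and K is the
    smallest value with ``Gap(K) >= Gap(K+1) - se(K+1)`` (argmax fallback).
    """
    X = np.asarray(data, dtype=float)
    n = len(X)
    k_range = [int(k) for k in k_range]
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    if B < 10:
        warnings.warn(f"B={B} reference cycles is very small")
    rng = np.random.default_rng(seed)
    mu, Vt, lo, hi = _reference_box(X)
    eps = 1e-12

    def logw(M, k, s):
        labels = cluster_once(M, k, algorithm, seed=s, restarts=restarts)
        w = _pooled_within_ss(M, labels)
        if w <= eps:
            warnings.warn("zero within-cluster dispersion; eps-floored")
            w = eps
        return np.log(w)

    log_wk = np.array([logw(X, k, rng.integers(2**31)) for k in k_range])
    log_wkb = np.empty((B, len(k_range)))
    for b in range(B):
        Z = rng.uniform(lo, hi, size=X.shape) @ Vt + mu
        for j, k in enumerate(k_range):
            log_wkb[b, j] = logw(Z, k, rng.integers(2**31))
    gap = log_wkb.mean(axis=0) - log_wk
    se = log_wkb.std(axis=0) * np.sqrt(1.0 + 1.0 / B)
    selected = None
    for j in range(len(k_range) - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            selected = k_range[j]
            break
    if selected is None:
        selected = k_range[int(np.argmax(gap))]
    return GapStatisticResult(
        algorithm=algorithm, k_values=k_range, gap=gap, se=se,
        log_wk=log_wk, B=B, selected_k=selected, seed=seed,
    )


# -- consensus ---------------------------------------------------------------------


def consensus_cluster(data, taxa=None, k_range=DEFAULT_K_RANGE, B=DEFAULT_B,
                      seed=None, threshold=2.0 / 3.0, restarts=25,
                      algorithms=ALGORITHMS, level="FFG"):
    """Composite feeding groups from three-algorithm classification consensus.

    Each algorithm clusters at its own gap-selected K; the coassignment
    matrix records the fraction of algorithms placing each taxon pair
    together, and composite groups are connected components of the graph
    with edges at coassignment >= ``threshold``. Singleton components, and
    taxa whose removal disconnects their component (tie bridges), are
    flagged "unstable".
    """
    X = np.asarray(data, dtype=float)
    n = len(X)
    if taxa is None:
        taxa = [f"t{i + 1}" for i in range(n)]
    taxa = list(taxa)
    if np.allclose(X, X[0]):
        raise ValueError("all rows identical; nothing to cluster")
    k_range = [k for k in k_range if k <= n - 1]
    ss = np.random.SeedSequence(seed)
    algo_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(algorithms))]

    gaps, solutions = [], []
    co = np.zeros((n, n))
    for alg, s in zip(algorithms, algo_seeds):
        g = gap_statistic(X, algorithm=alg, k_range=k_range, B=B, seed=s,
                          restarts=restarts)
        labels = cluster_once(X, g.selected_k, alg, seed=s + 1, restarts=restarts)
        gaps.append(g)
        solutions.append(
            ClusterSolution(algorithm=alg, k=g.selected_k,
                            labels=dict(zip(taxa, labels.tolist())))
        )
        co += (labels[:, None] == labels[None, :]).astype(float)
    co /= len(algorithms)

    adj = co >= threshold - 1e-12
    np.fill_diagonal(adj, True)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    unstable = np.zeros(n, dtype=bool)
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if len(members) == 1:
            unstable[members[0]] = True
            continue
        sub = adj[np.ix_(members, members)]
        for i in range(len(members)):
            keep = np.ones(len(members), dtype=bool)
            keep[i] = False
            nc, _ = connected_components(csr_matrix(sub[np.ix_(keep, keep)]),
                                         directed=False)
            if nc > 1:
                unstable[members[i]] = True

    # name stable components by decreasing size
    comp_sizes = {}
    for c in range(n_comp):
        members = np.flatnonzero((comp == c) & ~unstable)
        if len(members):
            comp_sizes[c] = len(members)
    names = {}
    for rank, c in enumerate(
        sorted(comp_sizes, key=lambda c: (-comp_sizes[c], c)), start=1
    ):
        names[c] = f"{level}{rank}"
    labels = {}
    for i, t in enumerate(taxa):
        labels[t] = "unstable" if unstable[i] else names[comp[i]]

    sil = {}
    stable = ~unstable
    stable_labels = [labels[taxa[i]] for i in np.flatnonzero(stable)]
    if stable.sum() > 2 and len(set(stable_labels)) >= 2:
        widths = silhouette_samples(X[stable], np.asarray(stable_labels))
        for i, w in zip(np.flatnonzero(stable), widths):
            sil[taxa[i]] = float(w)
    return ConsensusClassification(
        level=level,
        labels=labels,
        per_algorithm=solutions,
        coassignment=co,
        taxa=taxa,
        agreement_rate=float(stable.mean()),
        silhouette=sil,
        gap_results=gaps,
    )


def subcluster(data, parent, k_range=DEFAULT_K_RANGE, B=DEFAULT_B, seed=None,
               min_split=4, **kwargs):
    """Consensus clustering nested within each parent composite group.

    ``parent`` is a :class:`ConsensusClassification` (or taxon -> label
    mapping). Groups with fewer than ``min_split`` taxa pass through as a
    single subgroup; subgroup ids are namespaced by their parent group.
    """
    X = np.asarray(data, dtype=float)
    parent_labels = parent.labels if isinstance(parent, ConsensusClassification) else dict(parent)
    taxa = (
        parent.taxa if isinstance(parent, ConsensusClassification)
        else list(parent_labels)
    )
    if set(parent_labels) != set(taxa) or len(taxa) != len(X):
        raise ValueError("parent labels do not cover the clustered taxon set")
    idx = {t: i for i, t in enumerate(taxa)}
    groups = {}
    for t, g in parent_labels.items():
        groups.setdefault(g, []).append(t)

    ss = np.random.SeedSequence(seed)
    child_seeds = iter(
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(groups))
    )
    labels = {}
    children = []
    for g in sorted(groups):
        members = sorted(groups[g], key=idx.get)
        s = next(child_seeds)
        if g == "unstable":
            for t in members:
                labels[t] = "unstable"
            continue
        if len(members) < min_split:
            for t in members:
                labels[t] = f"{g}.1"
            continue
        sub_k = [k for k in k_range if k <= len(members) - 1]
        subX = X[[idx[t] for t in members]]
        if not sub_k or np.allclose(subX, subX[0]):
            for t in members:
                labels[t] = f"{g}.1"
            continue
        child = consensus_cluster(
            subX, taxa=members, k_range=sub_k, B=B, seed=s, level="sub", **kwargs
        )
        children.append((g, child))
        for t in members:
            l = child.labels[t]
            labels[t] = "unstable" if l == "unstable" else f"{g}.{l[3:]}"

    n = len(taxa)
    co = np.zeros((n, n))
    arr = np.array([labels[t] for t in taxa])
    stable = arr != "unstable"
    co[np.ix_(stable, stable)] = (
        arr[stable][:, None] == arr[stable][None, :]
    ).astype(float)
    sil = {}
    if stable.sum() > 2 and len(set(arr[stable])) >= 2:
        widths = silhouette_samples(X[stable], arr[stable])
        for i, w in zip(np.flatnonzero(stable), widths):
            sil[taxa[i]] = float(w)
    return ConsensusClassification(
        level="FFsG",
        labels=labels,
        per_algorithm=[c for _, c in children],
        coassignment=co,
        taxa=taxa,
        agreement_rate=float(stable.mean()),
        silhouette=sil,
    )


# -- validation --------------------------------------------------------------------


def variation_of_information(labels_a, labels_b):
    """Variation of information between two partitions (nats; 0 = identical)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    cats_a, inv_a = np.unique(a, return_inverse=True)
    cats_b, inv_b = np.unique(b, return_inverse=True)
    joint = np.zeros((len(cats_a), len(cats_b)))
    for i, j in zip(inv_a, inv_b):
        joint[i, j] += 1
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    hi = -(pa[pa > 0] * np.log(pa[pa > 0])).sum()
    hj = -(pb[pb > 0] * np.log(pb[pb > 0])).sum()
    mi = (joint[nz] * (np.log(joint[nz])
                       - np.log(pa[nz.nonzero()[0]])
                       - np.log(pb[nz.nonzero()[1]]))).sum()
    return float(hi + hj - 2.0 * mi)


def _chance_corrected_agreement(labels_a, labels_b):
    """Best-matched agreement rate, corrected for chance (Hungarian match)."""
    from scipy.optimize import linear_sum_assignment

    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    cats_a, inv_a = np.unique(a, return_inverse=True)
    cats_b, inv_b = np.unique(b, return_inverse=True)
    C = np.zeros((len(cats_a), len(cats_b)))
    for i, j in zip(inv_a, inv_b):
        C[i, j] += 1
    ri, ci = linear_sum_assignment(-C)
    acc = C[ri, ci].sum() / len(a)
    expected = max(1.0 / len(cats_a), 1.0 / len(cats_b))
    if expected >= 1.0:
        return 0.0
    return float((acc - expected) / (1.0 - expected))


def validate_clusters(classification, data, reference_partition):
    """Internal (silhouette) and external validation of a classification.

    External metrics compare against a reference partition (e.g. clades):
    adjusted Rand index, variation of information, and a chance-corrected
    best-match agreement rate. Unstable taxa are excluded.
    """
    labels = (
        classification.labels
        if isinstance(classification, ConsensusClassification)
        else dict(classification)
    )
    taxa = (
        classification.taxa
        if isinstance(classification, ConsensusClassification)
        else list(labels)
    )
    if set(reference_partition) != set(taxa):
        raise ValueError("reference partition covers a different taxon set")
    X = np.asarray(data, dtype=float)
    arr = np.array([labels[t] for t in taxa])
    ref = np.array([reference_partition[t] for t in taxa])
    stable = arr != "unstable"
    report = {"n": len(taxa), "n_stable": int(stable.sum())}
    if stable.sum() > 2 and len(set(arr[stable])) >= 2:
        widths = silhouette_samples(X[stable], arr[stable])
        report["silhouette_mean"] = float(widths.mean())
        report["silhouette"] = {
            taxa[i]: float(w) for i, w in zip(np.flatnonzero(stable), widths)
        }
    else:
        report["silhouette_mean"] = float("nan")
        report["silhouette"] = {}
    report["adjusted_rand"] = float(adjusted_rand_score(ref[stable], arr[stable]))
    report["variation_of_information"] = variation_of_information(
        ref[stable], arr[stable]
    )
    report["corrected_agreement"] = _chance_corrected_agreement(
        ref[stable], arr[stable]
    )
    return report
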
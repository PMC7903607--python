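"""Patient stratification: pairwise clustering, silhouette-guided k
selection, ANOVA cluster annotation, and hypergeometric disease enrichment.

The default clustering backend is a deterministic-annealing pairwise
clustering (DAPWC): soft cluster memberships are iterated to a mean-field
fixed point at each temperature of a geometric cooling schedule, starting
from the largest distance scale, until the assignment is effectively
hard.  A PAM k-medoids backend is provided as an algorithmically
independent cross-check.  Both consume only the pairwise distance
matrix (Euclidean over imputed, normalized clinotype vectors by default).

Cluster–disease enrichment is the upper-tail hypergeometric probability
of observing at least κ patients with disease D in a cluster of size η,
drawn from Ν patients of whom Κ carry the disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .datamodel import ClinotypeMatrix

logger = logging.getLogger(__name__)


class ClusteringError(RuntimeError):
    pass


def pairwise_distances(matrix: ClinotypeMatrix | pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Symmetric patient × patient distance matrix (zero diagonal).

    Requires a complete matrix — run imputation first.
    """
    values = matrix.values if isinstance(matrix, ClinotypeMatrix) else matrix
    if values.isna().any().any():
        raise ValueError("matrix has missing cells; impute before computing distances")
    D = squareform(pdist(values.to_numpy(), metric=metric))
    return pd.DataFrame(D, index=values.index, columns=values.index)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # per-patient cluster label in 1..k
    k: int
    silhouette_score: float
    method: str

    def members(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]


def silhouette(labels: pd.Series | np.ndarray, D: pd.DataFrame | np.ndarray) -> float:
    """Mean silhouette width from a precomputed distance matrix.

    Per point, s = (b − a) / max(a, b) with a the mean distance to the
    point's own cluster (excluding itself) and b the smallest mean
    distance to another cluster.  Points in singleton clusters
    contribute s = 0.
    """
    lab = np.asarray(labels.values if isinstance(labels, pd.Series) else labels)
    Dm = np.asarray(D.values if isinstance(D, pd.DataFrame) else D, dtype=float)
    n = len(lab)
    clusters = np.unique(lab)
    if len(clusters) < 2:
        raise ValueError("silhouette needs at least two clusters")
    sizes = {c: int((lab == c).sum()) for c in clusters}
    # mean distance from every point to every cluster
    mean_to = np.empty((n, len(clusters)))
    for j, c in enumerate(clusters):
        mean_to[:, j] = Dm[:, lab == c].sum(axis=1)
    s = np.zeros(n)
    for i in range(n):
        ci = np.flatnonzero(clusters == lab[i])[0]
        size_own = sizes[lab[i]]
        if size_own == 1:
            s[i] = 0.0
            continue
        a = mean_to[i, ci] / (size_own - 1)
        b = min(
            mean_to[i, j] / sizes[c]
            for j, c in enumerate(clusters)
            if c != lab[i]
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def _mean_field_cost(Dm: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Per point/cluster assignment cost for pairwise clustering.

    cost(i, c) = avg distance of i to cluster c − ½ avg within-cluster
    distance of c, under the soft memberships M.
    """
    m = M.sum(axis=0)  # soft cluster sizes
    m = np.maximum(m, 1e-12)
    S = Dm @ M  # (n, k): summed distance of i to cluster c
    avg = S / m
    within = np.einsum("ic,ic->c", M, S) / (2.0 * m**2)
    return avg - within


def _dapwc(
    Dm: np.ndarray,
    k: int,
    rng: np.random.Generator,
    cooling: float = 0.95,
    t_min_fraction: float = 1e-3,
    mf_tol: float = 1e-6,
    mf_max_iter: int = 100,
) -> np.ndarray:
    n = Dm.shape[0]
    M = np.full((n, k), 1.0 / k) + 0.01 * rng.random((n, k))
    M /= M.sum(axis=1, keepdims=True)
    T0 = float(Dm.max())
    if T0 <= 0:
        # all points identical; arbitrary but deterministic split
        return np.arange(n) % k
    T = T0
    T_min = t_min_fraction * T0
    while T > T_min:
        # tiny symmetry-breaking jitter so clusters do not collapse onto
        # identical membership vectors during cooling
        M = M * (1.0 + 1e-3 * rng.random((n, k)))
        M /= M.sum(axis=1, keepdims=True)
        for _ in range(mf_max_iter):
            cost = _mean_field_cost(Dm, M)
            logits = -cost / T
            logits -= logits.max(axis=1, keepdims=True)
            M_new = np.exp(logits)
            M_new /= M_new.sum(axis=1, keepdims=True)
            delta = np.abs(M_new - M).max()
            M = M_new
            if delta < mf_tol:
                break
        T *= cooling
    # zero-temperature limit: hard reassignment until stable
    labels = M.argmax(axis=1)
    for _ in range(mf_max_iter):
        H = np.zeros((n, k))
        H[np.arange(n), labels] = 1.0
        cost = _mean_field_cost(Dm, H)
        new_labels = cost.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels


def _kmedoids(
    Dm: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 200, n_init: int = 5
) -> np.ndarray:
    """PAM-style alternating k-medoids; best of ``n_init`` restarts."""
    best_labels = None
    best_cost = np.inf
    for _ in range(n_init):
        labels, cost = _kmedoids_once(Dm, k, rng, max_iter)
        if cost < best_cost:
            best_cost = cost
            best_labels = labels
    return best_labels


def _kmedoids_once(
    Dm: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, float]:
    n = Dm.shape[0]
    # k-medoids++ style init: spread the starting medoids out
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        dist_to_near = Dm[:, medoids].min(axis=1)
        probs = dist_to_near**2
        if probs.sum() <= 0:
            candidates = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(candidates)))
            continue
        medoids.append(int(rng.choice(n, p=probs / probs.sum())))
    medoids = np.array(sorted(set(medoids)))
    while len(medoids) < k:  # degenerate duplicates
        extra = int(rng.integers(n))
        if extra not in medoids:
            medoids = np.sort(np.append(medoids, extra))

    labels = Dm[:, medoids].argmin(axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                far = int(np.argmax(Dm[:, medoids].min(axis=1)))
                new_medoids[c] = far
                continue
            within = Dm[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(np.argmin(within))]
        new_labels = Dm[:, new_medoids].argmin(axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    cost = float(Dm[np.arange(n), medoids[labels]].sum())
    return labels, cost


def cluster(
    D: pd.DataFrame,
    k: int,
    method: str = "dapwc",
    seed: int = 0,
    max_retries: int = 3,
    **kwargs,
) -> ClusterAssignment:
    """Cluster patients from a distance matrix into k non-empty groups.

    ``method`` is "dapwc" (default) or "kmedoids".  Runs that converge
    with an empty cluster are retried with a perturbed initialization up
    to ``max_retries`` times before raising.
    """
    n = D.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, n-1]={[2, n - 1]}, got {k}")
    Dm = np.asarray(D, dtype=float)
    backend = {"dapwc": _dapwc, "kmedoids": _kmedoids}.get(method)
    if backend is None:
        raise ValueError(f"unknown clustering method {method!r}")
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + 1000 * attempt)
        raw = backend(Dm, k, rng, **kwargs)
        counts = np.bincount(raw, minlength=k)
        if (counts > 0).sum() == k:
            labels = pd.Series(raw + 1, index=D.index, name="cluster")
            return ClusterAssignment(
                labels=labels,
                k=k,
                silhouette_score=silhouette(labels, D),
                method=method,
            )
        logger.warning("empty cluster at convergence (attempt %d); retrying", attempt + 1)
    raise ClusteringError(f"clustering produced an empty cluster after {max_retries} attempts")


def select_k(
    D: pd.DataFrame,
    k_range: range | list[int],
    method: str = "dapwc",
    seed: int = 0,
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Cluster at every k in the range; return the assignment maximizing Si.

    The companion table lists the silhouette score per k (NaN for k that
    failed, which are skipped with a warning).
    """
    rows = []
    best: ClusterAssignment | None = None
    for k in k_range:
        try:
            assignment = cluster(D, k, method=method, seed=seed)
        except (ClusteringError, ValueError) as exc:
            logger.warning("k=%d failed: %s", k, exc)
            rows.append({"k": k, "silhouette": np.nan})
            continue
        rows.append({"k": k, "silhouette": assignment.silhouette_score})
        if best is None or assignment.silhouette_score > best.silhouette_score:
            best = assignment
    if best is None:
        raise ClusteringError("no k in the range produced a valid clustering")
    return best, pd.DataFrame(rows)


def anova_annotate(
    matrix: ClinotypeMatrix | pd.DataFrame,
    assignment: ClusterAssignment,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA across clusters for every clinotype.

    Returns a DataFrame indexed by clinotype with F, p_value,
    significant (p < α) and a degenerate flag for zero within-group
    variance (F = 0, p = 1 when the group means also coincide; p = 0
    when they differ).
    """
    values = matrix.values if isinstance(matrix, ClinotypeMatrix) else matrix
    labels = assignment.labels
    rows = []
    for clin in values.columns:
        groups = [
            values.loc[labels.index[labels == c], clin].dropna().to_numpy()
            for c in range(1, assignment.k + 1)
        ]
        groups = [g for g in groups if len(g) > 0]
        grand = np.concatenate(groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        ssb = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
        degenerate = False
        if ssw <= 1e-300:
            degenerate = True
            if ssb <= 1e-300:
                F, p = 0.0, 1.0
            else:
                F, p = np.inf, 0.0
        else:
            F, p = stats.f_oneway(*groups)
            F, p = float(F), float(p)
        rows.append(
            {
                "clinotype": clin,
                "F": F,
                "p_value": p,
                "significant": p < alpha,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("clinotype")


@dataclass(frozen=True)
class EnrichmentQuery:
    """Hypergeometric query: Ν patients total, Κ with the disease,
    η in the cluster, κ with the disease inside the cluster."""

    n_total: int  # Ν
    n_disease: int  # Κ
    cluster_size: int  # η
    n_disease_in_cluster: int  # κ

    def __post_init__(self) -> None:
        N, K, eta, kappa = (
            self.n_total,
            self.n_disease,
            self.cluster_size,
            self.n_disease_in_cluster,
        )
        if not (0 <= K <= N and 0 <= eta <= N):
            raise ValueError("need Κ ≤ Ν and η ≤ Ν")
        if not 0 <= kappa <= min(K, eta):
            raise ValueError("need κ ≤ min(Κ, η)")


@dataclass(frozen=True)
class EnrichmentResult:
    query: EnrichmentQuery
    p_value: float
    enriched: bool  # p < 0.05


def enrichment(
    n_total: int,
    n_disease: int,
    cluster_size: int,
    n_disease_in_cluster: int,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment p-value.

    p = P[at least κ disease patients in a uniformly drawn cluster of
    size η], summed from τ = κ to min(Κ, η); κ = 0 gives p = 1.
    """
    query = EnrichmentQuery(n_total, n_disease, cluster_size, n_disease_in_cluster)
    p = float(
        stats.hypergeom.sf(
            n_disease_in_cluster - 1, n_total, n_disease, cluster_size
        )
    )
    p = min(1.0, max(0.0, p))
    return EnrichmentResult(query, p, p < alpha)


def enrichment_table(
    assignment: ClusterAssignment,
    diagnoses,
    disease_codes: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of each disease code (prefix match) in each cluster."""
    labels = assignment.labels
    N = len(labels)
    rows = []
    for code in disease_codes:
        prefix = code.strip().upper()
        carriers = {
            r.patient_id for r in diagnoses if r.icd10_code.upper().startswith(prefix)
        } & set(labels.index)
        K = len(carriers)
        for c in range(1, assignment.k + 1):
            members = set(assignment.members(c))
            res = enrichment(N, K, len(members), len(members & carriers), alpha)
            rows.append(
                {
                    "disease": prefix,
                    "cluster": c,
                    "cluster_size": len(members),
                    "n_disease": K,
                    "n_in_cluster": len(members & carriers),
                    "p_value": res.p_value,
                    "enriched": res.enriched,
                }
            )
    return pd.DataFrame(rows)


def mds_coordinates(D: pd.DataFrame, n_components: int = 3) -> pd.DataFrame:
    """Classical multidimensional scaling of a distance matrix.

    Provides point-cloud coordinates for external 3-D viewers.
    """
    Dm = np.asarray(D, dtype=float)
    n = Dm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dm**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(
        coords, index=D.index, columns=[f"dim{i + 1}" for i in range(len(order))]
    )
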
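"""Scoring, selection, clustering and embedding of spatiotemporal patterns.

Each gene (or phenotype property) is summarized by its spectral
coefficient vector c on the orthonormal domain basis.  Coefficients are
standardized per gene so patterns can be compared independent of global
shifts and scaling,

    k_m = (c_m - delta_{m,0} * mu / p0) / sigma,

where mu and sigma are the gene's mean and standard deviation over all
in-domain samples and p0 is the value of the constant basis function.
The spatiotemporal ranking R = P / E opposes pattern energy
P = sum_{m>=1} k_m^2 to the standardized representation error E.  Genes
are selected by a weighted-median cut on R, clustered by k-medoids (PAM)
on cosine distance between k-vectors, and embedded in 2-D by metric MDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import MDS


@dataclass
class RescaledCoefficients:
    """Standardized spectral coefficients with per-gene mean/SD."""

    k: np.ndarray            # (n_genes, M+1)
    mu: np.ndarray
    sigma: np.ndarray
    gene_ids: list[str]
    constant: np.ndarray = field(default=None)   # sigma == 0 flags

    def __post_init__(self) -> None:
        if self.constant is None:
            self.constant = np.asarray(self.sigma) == 0


@dataclass
class PatternScores:
    """Representation error E, pattern score P, ranking R = P/E, selection."""

    E: np.ndarray
    P: np.ndarray
    R: np.ndarray
    gene_ids: list[str]
    selected: np.ndarray = field(default=None)


def rescale(c: np.ndarray, expression: np.ndarray, p0: float,
            gene_ids: list[str] | None = None) -> RescaledCoefficients:
    """Standardize coefficient vectors per gene.

    Parameters
    ----------
    c : array (n_genes, M+1)
        Raw spectral coefficients (stacked fit across replicates).
    expression : array (n_genes, n_samples)
        In-domain expression values used for the fit, pooled across
        replicates; supplies mu and sigma.
    p0 : float
        Value of the constant basis function.

    Constant genes (sigma = 0) cannot be standardized; their k rows are
    zero and they are flagged for exclusion from scoring.
    """
    c = np.asarray(c, float)
    expression = np.asarray(expression, float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(c.shape[0])]
    mu = expression.mean(axis=1)
    sigma = expression.std(axis=1)
    const = sigma == 0
    safe = np.where(const, 1.0, sigma)
    k = c.copy()
    k[:, 0] -= mu / p0
    k /= safe[:, None]
    k[const] = 0.0
    return RescaledCoefficients(k=k, mu=mu, sigma=sigma,
                                gene_ids=list(gene_ids), constant=const)


def scores(g_rows: np.ndarray, resc: RescaledCoefficients,
           design: np.ndarray, perfect_fit_tol: float = 1e-12) -> PatternScores:
    """Pattern scores per gene from standardized residuals and k-vectors.

    E = || (g - mu)/sigma - design @ k ||^2 over the pooled in-domain
    samples, P = sum_{m>=1} k_m^2, R = P / E.  A perfect representation
    (E below ``perfect_fit_tol``, i.e. zero up to round-off of the
    standardized residual) gets an infinite-R sentinel and ranks top.
    Constant genes get R = 0.
    """
    g_rows = np.asarray(g_rows, float)
    safe = np.where(resc.constant, 1.0, resc.sigma)
    z = (g_rows - resc.mu[:, None]) / safe[:, None]
    resid = z - resc.k @ design.T
    E = np.sum(resid**2, axis=1)
    P = np.sum(resc.k[:, 1:]**2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(E > perfect_fit_tol, P / E, np.inf)
    R = np.where(resc.constant, 0.0, R)
    P = np.where(resc.constant, 0.0, P)
    return PatternScores(E=E, P=P, R=R, gene_ids=list(resc.gene_ids))


def select(sc: PatternScores, fraction: float = 0.5) -> np.ndarray:
    """Weighted-median selection of patterned genes.

    Order genes by R ascending and find the largest N_c such that the
    cumulative R fraction is <= ``fraction``; genes ranked above N_c are
    selected, so the selected set carries at least 1 - fraction of the
    total ranking mass.  Infinite-R sentinels are always selected and are
    excluded from the cumulative denominator.
    """
    R = np.asarray(sc.R, float)
    finite = np.isfinite(R)
    total = R[finite].sum()
    selected = np.zeros(R.size, dtype=bool)
    selected[~finite] = True
    if total > 0:
        order = np.argsort(R[finite], kind="stable")
        idx = np.flatnonzero(finite)[order]
        cum = np.cumsum(R[idx]) / total
        n_c = int(np.searchsorted(cum, fraction, side="right"))
        selected[idx[n_c:]] = True
    sc.selected = selected
    return selected


def cosine_similarity(k: np.ndarray) -> np.ndarray:
    """Cosine similarity between k-vectors over the non-constant modes.

    The m = 0 component is excluded: similarity compares pattern shape,
    not offset.  Genes whose higher-mode vector is exactly zero have no
    defined direction; a warning is raised and their rows are NaN.
    """
    v = np.asarray(k, float)[:, 1:]
    norms = np.linalg.norm(v, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero pattern vector(s); similarity undefined",
                      RuntimeWarning, stacklevel=2)
    safe = np.where(zero, 1.0, norms)
    u = v / safe[:, None]
    d = np.clip(u @ u.T, -1.0, 1.0)
    np.fill_diagonal(d, 1.0)
    d[zero, :] = np.nan
    d[:, zero] = np.nan
    return d


def _pam(dist: np.ndarray, n_clusters: int, seed: int,
         max_iter: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """PAM k-medoids: greedy BUILD then SWAP to a local optimum."""
    n = dist.shape[0]
    rng = np.random.default_rng(seed)  # reserved for tie shuffles; BUILD is greedy
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < n_clusters:
        cur = dist[:, medoids].min(axis=1)
        # gain of adding each candidate
        gains = np.maximum(cur[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = list(sorted(medoids))
    for _ in range(max_iter):
        d_med = dist[:, medoids]
        cost = d_med.min(axis=1).sum()
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            d_rest = dist[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = np.minimum(d_rest, dist[:, h]).sum()
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = sorted(medoids)
    med = np.array(medoids)
    labels = np.argmin(dist[:, med], axis=1)
    return labels, med


@dataclass
class PatternClustering:
    labels: np.ndarray
    medoids: np.ndarray
    gene_ids: list[str]
    cost: float


def cluster(similarity: np.ndarray, n_clusters: int, seed: int = 0,
            gene_ids: list[str] | None = None) -> PatternClustering:
    """k-medoids (PAM) on cosine distance 1 - similarity.

    The medoid of each cluster is the member minimizing the summed
    distance to the others; labels are deterministic given the seed.
    """
    sim = np.asarray(similarity, float)
    n = sim.shape[0]
    if n_clusters < 1 or n_clusters > n:
        raise ValueError("n_clusters must be in [1, n_genes]")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    labels, med = _pam(dist, n_clusters, seed)
    cost = float(dist[np.arange(n), med[labels]].sum())
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    return PatternClustering(labels=labels, medoids=med,
                             gene_ids=list(gene_ids), cost=cost)


def elbow_curve(similarity: np.ndarray, k_range, seed: int = 0) -> dict[int, float]:
    """Total PAM cost for each candidate cluster count."""
    return {int(k): cluster(similarity, int(k), seed).cost for k in k_range}


def mean_pattern(k_members: np.ndarray, basis, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Reconstruction of the mean member coefficient vector on a grid."""
    from .basis import reconstruct
    kbar = np.asarray(k_members, float).mean(axis=0)
    return reconstruct(kbar, basis, t, p)


def mds_embed(similarity: np.ndarray, seed: int = 0) -> tuple[np.ndarray, float]:
    """Metric MDS of 1 - similarity, initialized by classical scaling.

    Returns (coords, stress).  Classical-scaling initialization plus the
    fixed seed makes the embedding deterministic.
    """
    dist = 1.0 - np.asarray(similarity, float)
    np.fill_diagonal(dist, 0.0)
    n = dist.shape[0]
    # classical scaling init: double-centred squared distances
    d2 = dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:2]
    init = V[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))
    mds = MDS(n_components=2, metric="precomputed", metric_mds=True,
              n_init=1, init="classical_mds", random_state=seed,
              normalized_stress=False)
    coords = mds.fit_transform(dist, init=init)
    return coords, float(mds.stress_)


def neighbor_functions(coords: np.ndarray, point: np.ndarray,
                       gene_ids: list[str], function_table: dict[str, str],
                       n: int = 50, min_category_size: int = 10) -> dict[str, int]:
    """Function-category counts among the n nearest genes to a point.

    Categories with fewer than ``min_category_size`` genes in the table
    are merged into "other".  Ties at the n-th distance are broken by
    gene id order.
    """
    coords = np.asarray(coords, float)
    if n > coords.shape[0]:
        raise ValueError("n exceeds the number of genes")
    from collections import Counter
    sizes = Counter(function_table.values())
    def cat(g: str) -> str:
        c = function_table.get(g, "other")
        return c if sizes.get(c, 0) >= min_category_size else "other"
    d = np.linalg.norm(coords - np.asarray(point, float)[None, :], axis=1)
    order = sorted(range(len(gene_ids)), key=lambda i: (d[i], gene_ids[i]))
    counts: dict[str, int] = {}
    for i in order[:n]:
        c = cat(gene_ids[i])
        counts[c] = counts.get(c, 0) + 1
    return counts
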
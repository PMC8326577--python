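"""Bacterial association networks from Gaussian graphical models.

Under a multivariate Gaussian model of CLR-transformed abundances, a
zero in the precision (inverse covariance) matrix means two species are
conditionally independent given all others; nonzeros define association
edges.  The precision matrix is estimated by l1-penalized maximum
likelihood (graphical lasso) along a regularization path, the penalty is
chosen by stability selection (StARS), and the selected edge set is
stabilized by bootstrap refits: an edge survives only if it reappears in
at least f*r of r bootstrap precision matrices.  The resulting network
is unweighted and signed (sign of the implied partial correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

__all__ = [
    "PrecisionEstimate",
    "AssociationNetwork",
    "lambda_path",
    "glasso_path",
    "stars_select",
    "bootstrap_stabilize",
    "apply_stability_rule",
    "support_matrix",
    "build_network",
    "eigenvector_centrality",
    "compare_networks",
]

#: Entries of the estimated precision matrix smaller than this (absolute)
#: are numerical dust, not edges.
EDGE_TOL = 1e-8

DEFAULT_BOOTSTRAP_R = 50
DEFAULT_BOOTSTRAP_F = 0.8


def _empirical_cov(values: np.ndarray | pd.DataFrame) -> np.ndarray:
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x D matrix with n >= 2")
    S = np.cov(X, rowvar=False, ddof=0)
    if not np.isfinite(S).all():
        raise ValueError("covariance matrix contains non-finite entries")
    return S


def _fit_glasso(S: np.ndarray, lam: float, ridge: float = 1e-6) -> np.ndarray:
    """One graphical-lasso fit; a small ridge guards ill-conditioned S.

    The coordinate-descent solver is run to a 5e-4 duality gap — edges are
    read off at |entry| > 1e-8, far above the residual solver error.
    """
    D = S.shape[0]
    Sr = S + ridge * np.trace(S) / D * np.eye(D)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            _, precision = graphical_lasso(Sr, alpha=lam, tol=5e-4, max_iter=100)
        except FloatingPointError:
            _, precision = graphical_lasso(
                Sr + 0.01 * np.trace(S) / D * np.eye(D), alpha=lam,
                tol=5e-4, max_iter=100,
            )
    return precision


def support_matrix(omega: np.ndarray, tol: float = EDGE_TOL) -> np.ndarray:
    """Boolean off-diagonal support of a precision matrix."""
    sup = np.abs(omega) > tol
    np.fill_diagonal(sup, False)
    return sup


def lambda_path(
    S: np.ndarray, n_lambdas: int = 30, min_ratio: float = 0.01
) -> np.ndarray:
    """Decreasing log-spaced penalty path from lambda_max down.

    ``lambda_max`` (the largest absolute off-diagonal covariance) is the
    smallest penalty yielding an empty graph.
    """
    off = S.copy()
    np.fill_diagonal(off, 0.0)
    lam_max = float(np.abs(off).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(min_ratio * lam_max), n_lambdas)


@dataclass
class PrecisionEstimate:
    """A selected sparse precision matrix with its path metadata."""

    species: list[str]
    omega: np.ndarray
    lam: float
    path_lambdas: np.ndarray | None = None
    instabilities: np.ndarray | None = None
    bootstrap_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.omega, self.omega.T, atol=1e-8):
            raise ValueError("precision matrix must be symmetric")
        if (np.diag(self.omega) <= 0).any():
            raise ValueError("precision diagonal must be strictly positive")


def glasso_path(
    values: np.ndarray | pd.DataFrame, lambdas: np.ndarray
) -> list[np.ndarray]:
    """Graphical-lasso precision matrices along a penalty path."""
    S = _empirical_cov(values)
    return [_fit_glasso(S, float(lam)) for lam in lambdas]


def stars_select(
    values: np.ndarray | pd.DataFrame,
    lambdas: np.ndarray | None = None,
    subsample_count: int = 20,
    subsample_size: int | None = None,
    beta: float = 0.1,
    seed: int | None = 0,
) -> dict:
    """Choose the penalty by the stability approach (StARS).

    For each penalty, graphs are estimated on ``subsample_count``
    subsamples (without replacement, default size ``min(floor(10*sqrt(n)),
    0.8n)``); the edge-wise instability is the mean over all species
    pairs of ``2*theta*(1-theta)`` with ``theta`` the edge's selection
    frequency.  After monotonizing with a running supremum along the
    path (densest direction), the selected penalty is the smallest one
    whose monotonized instability stays at or below ``beta``.
    """
    X = np.asarray(values, dtype=float)
    n, D = X.shape
    S = _empirical_cov(X)
    if lambdas is None:
        lambdas = lambda_path(S)
    lambdas = np.asarray(sorted(lambdas, reverse=True), dtype=float)
    if subsample_size is None:
        subsample_size = min(int(np.floor(10 * np.sqrt(n))), max(2, int(0.8 * n)))
    if subsample_size > n:
        raise ValueError("subsample_size cannot exceed n")

    rng = np.random.default_rng(seed)
    replace = subsample_size == n  # degenerate: identical subsamples
    theta = np.zeros((len(lambdas), D, D))
    for _ in range(subsample_count):
        idx = (
            np.arange(n)
            if replace
            else rng.choice(n, size=subsample_size, replace=False)
        )
        Ssub = np.cov(X[idx], rowvar=False, ddof=0)
        for li, lam in enumerate(lambdas):
            theta[li] += support_matrix(_fit_glasso(Ssub, float(lam)))
    theta /= subsample_count

    iu = np.triu_indices(D, k=1)
    instability = np.array(
        [(2 * t * (1 - t))[iu].mean() for t in theta]
    )
    monotone = np.maximum.accumulate(instability)  # sup along decreasing lambda

    ok = monotone <= beta
    if ok.any():
        lam_star = float(lambdas[np.where(ok)[0].max()])
    else:
        warnings.warn("no penalty met the instability bound; using the largest")
        lam_star = float(lambdas[0])
    return {
        "lambda_star": lam_star,
        "lambdas": lambdas,
        "instability": instability,
        "monotone_instability": monotone,
        "edge_frequencies": theta,
    }


def bootstrap_stabilize(
    values: np.ndarray | pd.DataFrame,
    lam: float,
    r: int = DEFAULT_BOOTSTRAP_R,
    f: float = DEFAULT_BOOTSTRAP_F,
    seed: int | None = 0,
    species: list[str] | None = None,
) -> PrecisionEstimate:
    """Bootstrap-stabilized precision matrix at a fixed penalty.

    The full-data precision matrix is refit on ``r`` bootstrap resamples
    (with replacement, size n); an off-diagonal entry is kept only when
    it is nonzero in the full fit *and* nonzero in at least ``f*r``
    bootstrap fits.  The diagonal is untouched, and stabilization can
    only remove edges, never add them.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must lie in [0, 1]")
    if r < 1:
        raise ValueError("r must be >= 1")
    X = np.asarray(values, dtype=float)
    n, D = X.shape
    if isinstance(values, pd.DataFrame):
        species = list(values.columns)
    if species is None:
        species = [f"sp{i:03d}" for i in range(D)]

    S = _empirical_cov(X)
    omega = _fit_glasso(S, lam)

    rng = np.random.default_rng(seed)
    counts = np.zeros((D, D), dtype=int)
    for _ in range(r):
        idx = rng.integers(0, n, size=n)
        Sb = np.cov(X[idx], rowvar=False, ddof=0)
        counts += support_matrix(_fit_glasso(Sb, lam))

    omega_prime = apply_stability_rule(omega, counts, r, f)

    return PrecisionEstimate(
        species=list(species),
        omega=omega_prime,
        lam=float(lam),
        bootstrap_counts=counts,
    )


def apply_stability_rule(
    omega: np.ndarray, counts: np.ndarray, r: int, f: float
) -> np.ndarray:
    """Zero every off-diagonal entry not reproduced in >= f*r bootstrap fits.

    An entry survives only when it is nonzero in the full-data fit and
    its (i, j) position was nonzero in at least ``f*r`` of the ``r``
    bootstrap precision matrices (the boundary count ``ceil(f*r)`` is
    kept, one fewer is dropped).  The diagonal passes through untouched.
    """
    keep = support_matrix(omega) & (counts >= f * r - 1e-9)
    omega_prime = np.where(keep, omega, 0.0)
    np.fill_diagonal(omega_prime, np.diag(omega))
    return omega_prime


@dataclass
class AssociationNetwork:
    """Unweighted signed association graph over species."""

    species: list[str]
    graph: nx.Graph
    degree: pd.Series = field(init=False)
    evc: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.degree = pd.Series(
            {s: self.graph.degree(s) for s in self.species}, name="degree"
        )
        if self.graph.number_of_nodes() > 0:
            self.evc = eigenvector_centrality(self.graph).reindex(self.species)
        else:
            self.evc = pd.Series(dtype=float, name="evc")

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges()}

    def edge_sign(self, a: str, b: str) -> int:
        return self.graph.edges[a, b]["sign"]

    @property
    def negative_edge_fraction(self) -> float:
        m = self.graph.number_of_edges()
        if m == 0:
            return 0.0
        neg = sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] < 0)
        return neg / m

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "sign": d["sign"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "sign"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(estimate: PrecisionEstimate) -> AssociationNetwork:
    """Signed unweighted graph from a (stabilized) precision matrix.

    An edge links i and j whenever the off-diagonal entry is nonzero;
    its sign is the sign of the implied partial correlation
    ``-omega_ij / sqrt(omega_ii * omega_jj)`` (so a negative precision
    entry is a positive association).
    """
    omega = estimate.omega
    species = estimate.species
    g = nx.Graph()
    g.add_nodes_from(species)
    D = len(species)
    diag = np.diag(omega)
    for i in range(D):
        for j in range(i + 1, D):
            if abs(omega[i, j]) > EDGE_TOL:
                pcor = -omega[i, j] / np.sqrt(diag[i] * diag[j])
                g.add_edge(species[i], species[j], sign=int(np.sign(pcor)))
    return AssociationNetwork(species=list(species), graph=g)


def eigenvector_centrality(
    graph: nx.Graph, tol: float = 1e-12, max_iter: int = 100_000
) -> pd.Series:
    """Eigenvector centrality x_i = sum_j A_ij x_j by power iteration.

    Computed on the unweighted, unsigned adjacency.  For disconnected
    graphs the leading eigenvector is taken on the largest connected
    component (ties broken toward the component containing the first
    node) and other nodes score zero; the result is nonnegative with
    unit Euclidean norm.  A unit diagonal shift makes the iteration
    convergent on bipartite components without changing the eigenvector.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot compute centrality of an empty graph")
    nodes = list(graph.nodes())
    components = sorted(
        nx.connected_components(graph),
        key=lambda c: (-len(c), min(nodes.index(v) for v in c)),
    )
    comp = sorted(components[0], key=nodes.index)
    A = nx.to_numpy_array(graph.subgraph(comp), nodelist=comp, weight=None)
    k = len(comp)
    x = np.full(k, 1.0 / np.sqrt(k))
    if A.sum() > 0:
        M = A + np.eye(k)
        for _ in range(max_iter):
            x_new = M @ x
            x_new /= np.linalg.norm(x_new)
            if np.abs(x_new - x).max() < tol:
                x = x_new
                break
            x = x_new
    x = np.abs(x)
    x /= np.linalg.norm(x)
    out = pd.Series(0.0, index=pd.Index(nodes), name="evc")
    out[comp] = x
    return out


def compare_networks(
    net_a: AssociationNetwork,
    net_b: AssociationNetwork,
    da_labels: dict[str, str] | None = None,
    top_k: int = 10,
    names: tuple[str, str] = ("a", "b"),
) -> dict:
    """Edge-set and centrality comparison between two networks.

    Reports the edges unique to each network and shared, the overlap of
    the top-k eigenvector-centrality node sets, the fraction of
    (connected) nodes in each differential-abundance category, and the
    fraction of each network's unique edges touching a DA-elevated
    species.
    """
    if set(net_a.species) != set(net_b.species):
        raise ValueError("networks must share a node universe")
    da_labels = da_labels or {}
    ea, eb = net_a.edges, net_b.edges
    shared = ea & eb
    unique_a, unique_b = ea - eb, eb - ea

    def top_set(net: AssociationNetwork) -> set[str]:
        return set(net.evc.sort_values(ascending=False).head(top_k).index)

    top_a, top_b = top_set(net_a), top_set(net_b)

    def node_categories(net: AssociationNetwork) -> dict[str, float]:
        connected = [s for s in net.species if net.degree[s] > 0]
        if not connected:
            return {}
        cats = pd.Series([da_labels.get(s, "not_da") for s in connected])
        return (cats.value_counts() / len(connected)).to_dict()

    def elevated_fraction(edges: set[frozenset]) -> float:
        if not edges:
            return 0.0
        hit = sum(
            1
            for e in edges
            if any(da_labels.get(v) == "elevated" for v in e)
        )
        return hit / len(edges)

    return {
        "n_edges": {names[0]: len(ea), names[1]: len(eb)},
        "shared_edges": shared,
        "unique_edges": {names[0]: unique_a, names[1]: unique_b},
        "n_unique": {names[0]: len(unique_a), names[1]: len(unique_b)},
        "top_k_overlap": len(top_a & top_b),
        "top_k_nodes": {names[0]: top_a, names[1]: top_b},
        "node_category_fractions": {
            names[0]: node_categories(net_a),
            names[1]: node_categories(net_b),
        },
        "negative_edge_fraction": {
            names[0]: net_a.negative_edge_fraction,
            names[1]: net_b.negative_edge_fraction,
        },
        "unique_edge_elevated_fraction": {
            names[0]: elevated_fraction(unique_a),
            names[1]: elevated_fraction(unique_b),
        },
    }
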
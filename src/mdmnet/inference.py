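"""Co-occurrence network inference from compositional count tables.

The primary route mirrors the SpiecEasi "mb" pipeline: counts are
centered-log-ratio (CLR) transformed, a sparse conditional-dependence
graph is estimated by Meinshausen-Buhlmann neighborhood selection
(an L1-penalized regression of every taxon on all others), and the
penalty is chosen by StARS - the Stability Approach to Regularization
Selection - at an instability threshold of 0.05.  SparCC and Pearson
correlation networks are provided as alternate constructions.

Penalty parameterization: columns are standardized (zero mean, unit
population variance), and the lasso objective is
``(1/2n)||y - Xb||^2 + lam * ||b||_1``; under this scaling a penalty at
or above the largest absolute empirical correlation shrinks every
neighborhood to the empty set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from .community import CommunityTable
from .taxonomy import RANKS, TaxonomyAssignment

__all__ = [
    "CLRMatrix",
    "StARSConfig",
    "CooccurrenceNetwork",
    "clr_transform",
    "mb_neighborhoods",
    "symmetrize",
    "stars_select",
    "stars_select_matrix",
    "sparcc",
    "pearson_correlation",
    "correlation_network",
    "build_network",
    "write_edge_list",
    "write_node_attributes",
    "write_graphml",
]


# ---------------------------------------------------------------------------
# CLR


@dataclass
class CLRMatrix:
    """Samples x OTUs matrix of centered log-ratio values."""

    values: np.ndarray  # (n_samples, n_otus)
    otu_ids: list[str]
    sample_ids: list[str]
    pseudocount: float


def clr_transform(table: CommunityTable, pseudocount: float = 1.0) -> CLRMatrix:
    """CLR transform: ``log(x + c)`` minus the per-sample mean log.

    Every output row sums to zero.  A nonpositive pseudocount is only
    legal when the table holds strictly positive counts.
    """
    x = table.counts.to_numpy(dtype=float).T  # samples x OTUs
    if pseudocount <= 0 and (x <= 0).any():
        raise ValueError("nonpositive pseudocount requires strictly positive counts")
    logs = np.log(x + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return CLRMatrix(clr, list(table.counts.index), list(table.counts.columns), pseudocount)


def _standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-population-variance columns; constant columns -> 0."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = x - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


# ---------------------------------------------------------------------------
# MB neighborhood selection


def _supports_at_path(
    xs: np.ndarray, lambdas: np.ndarray, tol: float = 1e-6
) -> np.ndarray:
    """Neighborhood supports for every node at every penalty.

    ``xs`` is a standardized samples x p matrix; returns a boolean array
    of shape (n_lambda, p, p) where ``[k, j, i]`` says column ``i`` is in
    the selected neighborhood of node ``j`` at ``lambdas[k]``.
    """
    n, p = xs.shape
    n_lam = len(lambdas)
    support = np.zeros((n_lam, p, p), dtype=bool)
    order = np.argsort(lambdas)[::-1]  # lasso_path wants decreasing penalties
    lam_desc = lambdas[order]
    for j in range(p):
        y = xs[:, j]
        if not y.any():  # constant column: empty neighborhood
            continue
        others = np.delete(np.arange(p), j)
        _, coefs, _ = lasso_path(xs[:, others], y, alphas=lam_desc, tol=tol)
        sel = np.abs(coefs) > 1e-10  # (p-1, n_lam), in lam_desc order
        for pos, k in enumerate(order):
            support[k, j, others] = sel[:, pos]
    return support


def mb_neighborhoods(clr: CLRMatrix, lam: float) -> list[set[int]]:
    """Meinshausen-Buhlmann neighborhoods at a single penalty.

    Each OTU's CLR column is regressed on all others (both standardized)
    with an L1 penalty ``lam``; the support of the solution is its
    neighborhood, returned as column-index sets aligned with
    ``clr.otu_ids``.
    """
    x = np.asarray(clr.values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in CLR matrix")
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 samples and 2 OTUs")
    xs = _standardize(x)
    support = _supports_at_path(xs, np.array([float(lam)]))
    return [set(np.nonzero(support[0, j])[0]) for j in range(p)]


def symmetrize(
    neighborhoods: Sequence[set[int]], rule: str = "or"
) -> set[tuple[int, int]]:
    """Combine directed neighborhoods into an undirected edge set."""
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    p = len(neighborhoods)
    edges: set[tuple[int, int]] = set()
    for j, neigh in enumerate(neighborhoods):
        for i in neigh:
            if i == j:
                continue
            a, b = min(i, j), max(i, j)
            if rule == "or" or (j in neighborhoods[i]):
                edges.add((a, b))
    if rule == "and":
        edges = {
            (a, b)
            for (a, b) in edges
            if b in neighborhoods[a] and a in neighborhoods[b]
        }
    return edges


# ---------------------------------------------------------------------------
# StARS


@dataclass
class StARSConfig:
    """Configuration for StARS penalty selection.

    ``beta`` is the instability threshold (0.05 as used throughout);
    ``subsample_size`` defaults to ``min(floor(10*sqrt(n)), floor(0.8n))``.
    ``lambda_path`` (decreasing) defaults to ``n_lambda`` log-spaced
    values from the largest absolute off-diagonal correlation of the
    standardized CLR data down to ``lambda_min_ratio`` times it.
    """

    lambda_path: np.ndarray | None = None
    beta: float = 0.05
    n_subsamples: int = 20
    subsample_size: int | None = None
    seed: int = 0
    n_lambda: int = 20
    lambda_min_ratio: float = 0.05
    symmetrize_rule: str = "or"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.beta < 0.5:
            raise ValueError("beta must lie in (0, 0.5)")
        if self.lambda_path is not None:
            path = np.asarray(self.lambda_path, dtype=float)
            if (path <= 0).any() or (np.diff(path) >= 0).any():
                raise ValueError("lambda_path must be positive and strictly decreasing")
            self.lambda_path = path

    def resolved_subsample_size(self, n: int) -> int:
        if self.subsample_size is not None:
            if not 0 < self.subsample_size < n:
                raise ValueError("subsample_size must lie in (0, n)")
            return self.subsample_size
        return max(2, min(int(10 * math.sqrt(n)), int(0.8 * n)))


@dataclass
class CooccurrenceNetwork:
    """Undirected co-occurrence graph over retained OTUs.

    ``nodes`` are all OTUs the inference was run on ("selected" in the
    node-accounting sense); ``edges`` are sorted id pairs.  Taxonomy is
    carried along so Known/Unknown flags can be read at any rank.
    """

    nodes: list[str]
    edges: set[tuple[str, str]]
    taxonomy: dict[str, TaxonomyAssignment]
    method: str
    lambda_: float | None = None
    threshold: float | None = None
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    stars_warning: bool = False
    instability: float | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a > b:
                raise ValueError("edges must be stored as sorted id pairs")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge endpoint not a node: ({a!r}, {b!r})")

    @property
    def n_selected(self) -> int:
        return len(self.nodes)

    @property
    def connected_nodes(self) -> list[str]:
        touched = {v for e in self.edges for v in e}
        return [n for n in self.nodes if n in touched]

    def degree(self) -> pd.Series:
        deg = dict.fromkeys(self.nodes, 0)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return pd.Series(deg, dtype=int)

    def unknown_flags(self, rank: str) -> pd.Series:
        return pd.Series(
            {n: self.taxonomy[n].unknown_at[rank] for n in self.nodes}, dtype=bool
        )

    def labels(self, rank: str) -> pd.Series:
        return pd.Series({n: self.taxonomy[n].label(rank) for n in self.nodes})

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e, weight=self.weights.get(e, 1.0))
        return g

    def report(self) -> dict:
        """Table-1-style accounting: selected/connected nodes, edges, ratio."""
        connected = len(self.connected_nodes)
        return {
            "selected_nodes": self.n_selected,
            "connected_nodes": connected,
            "edges": len(self.edges),
            "edge_node_ratio": (len(self.edges) / connected) if connected else float("nan"),
        }


def _default_lambda_path(xs: np.ndarray, n_lambda: int, min_ratio: float) -> np.ndarray:
    n = xs.shape[0]
    corr = xs.T @ xs / n
    np.fill_diagonal(corr, 0.0)
    lam_max = float(np.abs(corr).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def stars_select_matrix(
    x: np.ndarray, cfg: StARSConfig
) -> tuple[set[tuple[int, int]], dict]:
    """StARS + MB on a raw samples x variables matrix (already transformed).

    The workhorse behind :func:`stars_select`; also usable directly on
    Gaussian data.  Returns the selected undirected edge set (column
    index pairs) and a diagnostics dict (selected penalty, instability
    path, subsample size, warning flag).
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input matrix")
    n, p = x.shape
    xs_full = _standardize(x)
    path = (
        cfg.lambda_path
        if cfg.lambda_path is not None
        else _default_lambda_path(xs_full, cfg.n_lambda, cfg.lambda_min_ratio)
    )
    n_lam = len(path)
    b = cfg.resolved_subsample_size(n)
    rng = np.random.default_rng(cfg.seed)
    theta = np.zeros((n_lam, p, p))
    for _ in range(cfg.n_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        xs = _standardize(x[idx])
        support = _supports_at_path(xs, path)
        if cfg.symmetrize_rule == "or":
            sym = support | support.transpose(0, 2, 1)
        else:
            sym = support & support.transpose(0, 2, 1)
        theta += sym
    theta /= cfg.n_subsamples
    xi = 2.0 * theta * (1.0 - theta)
    iu = np.triu_indices(p, k=1)
    instability = xi[:, iu[0], iu[1]].mean(axis=1)
    monotone = np.maximum.accumulate(instability)  # path is decreasing in lambda
    feasible = np.nonzero(monotone <= cfg.beta)[0]
    warned = False
    if feasible.size:
        k = int(feasible[-1])
    else:
        warnings.warn("no penalty met the StARS instability bound; using sparsest")
        k, warned = 0, True
    lam_sel = float(path[k])
    support = _supports_at_path(xs_full, np.array([lam_sel]))[0]
    neighborhoods = [set(np.nonzero(support[j])[0]) for j in range(p)]
    edges_idx = symmetrize(neighborhoods, cfg.symmetrize_rule)
    info = {
        "lambda": lam_sel,
        "lambda_path": path,
        "instability_path": monotone,
        "selected_index": k,
        "subsample_size": b,
        "warning": warned,
        "_xs_full": xs_full,
    }
    return edges_idx, info


def stars_select(table: CommunityTable, cfg: StARSConfig) -> CooccurrenceNetwork:
    """Infer an MB network with the penalty chosen by StARS.

    For each penalty, edge-presence frequencies are estimated over
    ``n_subsamples`` random sample subsets (drawn without replacement);
    per-edge instability is ``2 * theta * (1 - theta)`` and the total
    instability ``D(lambda)`` is its mean over all node pairs.  After
    monotonization (running max from the sparse end), the smallest
    penalty - the densest graph - with instability <= ``beta`` is
    selected and the model is refit on the full data.
    """
    clr = clr_transform(table, cfg.pseudocount)
    edges_idx, info = stars_select_matrix(clr.values, cfg)
    ids = clr.otu_ids
    xs_full = info.pop("_xs_full")
    lam_sel = info["lambda"]
    path, monotone = info["lambda_path"], info["instability_path"]
    k, warned = info["selected_index"], info["warning"]
    b = info["subsample_size"]
    weights = _refit_weights(xs_full, edges_idx, lam_sel, ids)
    edges = {tuple(sorted((ids[i], ids[j]))) for i, j in edges_idx}
    return CooccurrenceNetwork(
        nodes=list(ids),
        edges=edges,
        taxonomy={o: table.taxonomy[o] for o in ids},
        method="mb",
        lambda_=lam_sel,
        weights=weights,
        provenance={
            "prevalence_threshold_samples": table.meta.get("prevalence_threshold_samples"),
            "seed": cfg.seed,
            "beta": cfg.beta,
            "n_subsamples": cfg.n_subsamples,
            "subsample_size": b,
            "lambda_path": [float(v) for v in path],
            "instability_path": [float(v) for v in monotone],
            "selected_index": k,
        },
        stars_warning=warned,
        instability=float(monotone[k]),
    )


def _refit_weights(
    xs: np.ndarray, edges_idx: set[tuple[int, int]], lam: float, ids: Sequence[str]
) -> dict[tuple[str, str], float]:
    """Signed edge weights from the lasso refit (max-|coef| of the two directions)."""
    if not edges_idx:
        return {}
    p = xs.shape[1]
    coefs = np.zeros((p, p))
    touched = {v for e in edges_idx for v in e}
    for j in sorted(touched):
        y = xs[:, j]
        if not y.any():
            continue
        others = np.delete(np.arange(p), j)
        model = Lasso(alpha=lam, fit_intercept=False, tol=1e-6, max_iter=50_000)
        model.fit(xs[:, others], y)
        coefs[j, others] = model.coef_
    weights = {}
    for i, j in edges_idx:
        w = coefs[i, j] if abs(coefs[i, j]) >= abs(coefs[j, i]) else coefs[j, i]
        weights[tuple(sorted((ids[i], ids[j])))] = float(w)
    return weights


# ---------------------------------------------------------------------------
# SparCC


def _basis_correlations(
    t_full: np.ndarray, t_work: np.ndarray, m: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the basis-variance system on the (possibly reduced) t_work;
    correlations are always reported against the full variation matrix."""
    row_sums = t_work.sum(axis=1)
    # least squares tolerates the near-singular systems the exclusion
    # rounds can produce on small taxon sets
    omega2 = np.linalg.lstsq(m, row_sums, rcond=None)[0]
    clipped = omega2
    if (omega2 <= 0).any():
        warnings.warn("negative basis variances in SparCC; clipped to epsilon")
        clipped = np.clip(omega2, np.finfo(float).eps, None)
    omega = np.sqrt(clipped)
    r = (clipped[:, None] + clipped[None, :] - t_full) / (2.0 * np.outer(omega, omega))
    return np.clip(r, -1.0, 1.0), omega2


def sparcc(
    table: CommunityTable,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Classic SparCC basis correlations from compositional counts.

    Each iteration draws per-sample fraction estimates from a
    Dirichlet(counts + 1), computes the log-ratio variation matrix
    ``t_ij = var(log(f_i / f_j))``, solves the approximate basis-variance
    linear system, and iteratively excludes the strongest-correlated
    pair (|r| above ``exclusion_threshold``) before re-solving, up to
    ``exclusion_rounds`` times.  The returned correlation matrix is the
    average over iterations, symmetric with unit diagonal.
    """
    counts = table.counts.to_numpy(dtype=float)
    p, n = counts.shape
    if p < 4:
        raise ValueError("SparCC needs at least 4 taxa (basis system underdetermined)")
    rng = np.random.default_rng(seed)
    acc = np.zeros((p, p))
    for _ in range(n_iterations):
        fracs = np.empty_like(counts)
        for s in range(n):
            fracs[:, s] = rng.dirichlet(counts[:, s] + 1.0)
        logf = np.log(fracs)
        # variation matrix: var over samples of log(f_i / f_j)
        t = np.var(logf[:, None, :] - logf[None, :, :], axis=2, ddof=1)
        m = np.ones((p, p)) + np.diag(np.full(p, p - 2.0))
        t_work = t.copy()
        r, omega2 = _basis_correlations(t, t_work, m)
        excl_count = np.zeros(p, dtype=int)
        excluded = np.zeros((p, p), dtype=bool)
        for _round in range(exclusion_rounds):
            r_off = np.abs(np.triu(r, k=1))
            r_off[excluded] = 0.0
            # never strip a taxon below 3 remaining partners
            blocked = excl_count >= p - 4
            r_off[blocked, :] = 0.0
            r_off[:, blocked] = 0.0
            i, j = np.unravel_index(np.argmax(r_off), r_off.shape)
            if r_off[i, j] <= exclusion_threshold:
                break
            excluded[i, j] = excluded[j, i] = True
            t_work[i, j] = t_work[j, i] = 0.0
            m[i, j] = m[j, i] = 0.0
            m[i, i] -= 1.0
            m[j, j] -= 1.0
            excl_count[i] += 1
            excl_count[j] += 1
            r_new, omega2_new = _basis_correlations(t, t_work, m)
            if (omega2_new <= 0).any():
                # the reduced system went degenerate; keep the previous fit
                break
            r, omega2 = r_new, omega2_new
        acc += r
    r_mean = acc / n_iterations
    r_mean = np.clip((r_mean + r_mean.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r_mean, 1.0)
    ids = table.otu_ids
    return pd.DataFrame(r_mean, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Correlation networks


def pearson_correlation(
    table: CommunityTable, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations (on CLR-transformed counts) with t-transform p values."""
    clr = clr_transform(table, pseudocount)
    x = clr.values
    n = x.shape[0]
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -0.9999999999, 0.9999999999)
    from scipy import stats as sps

    tstat = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    pval = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(pval, 0.0)
    ids = table.otu_ids
    return (
        pd.DataFrame(r, index=ids, columns=ids),
        pd.DataFrame(pval, index=ids, columns=ids),
    )


def correlation_network(
    corr: pd.DataFrame,
    threshold: float,
    pvalues: pd.DataFrame | None = None,
    alpha: float = 0.05,
    taxonomy: Mapping[str, TaxonomyAssignment] | None = None,
    method: str = "pearson",
) -> CooccurrenceNetwork:
    """Binarize a correlation matrix into a network.

    Edge iff ``|r| >= threshold`` and, when p values are supplied,
    ``p <= alpha``; signed correlations are kept as edge weights.
    """
    r = corr.to_numpy(dtype=float)
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    ids = list(corr.index)
    pv = pvalues.to_numpy(dtype=float) if pvalues is not None else None
    edges: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    p = len(ids)
    for i in range(p):
        for j in range(i + 1, p):
            if abs(r[i, j]) >= threshold and (pv is None or pv[i, j] <= alpha):
                e = tuple(sorted((ids[i], ids[j])))
                edges.add(e)
                weights[e] = float(r[i, j])
    from .taxonomy import parse_lineage

    tax = (
        {o: taxonomy[o] for o in ids}
        if taxonomy is not None
        else {o: parse_lineage("", o) for o in ids}
    )
    return CooccurrenceNetwork(
        nodes=ids,
        edges=edges,
        taxonomy=tax,
        method=method,
        threshold=threshold,
        weights=weights,
    )


def build_network(table: CommunityTable, method: str = "mb", **params) -> CooccurrenceNetwork:
    """Dispatch wrapper over the three inference routes.

    ``method="mb"`` accepts :class:`StARSConfig` fields as keyword
    arguments; ``"sparcc"`` and ``"pearson"`` additionally accept
    ``threshold`` (default 0.3) and ``alpha`` (default 0.05) for
    binarization.  Provenance (method, prevalence threshold, seed) is
    recorded on the returned network.
    """
    if method == "mb":
        cfg = StARSConfig(**params)
        return stars_select(table, cfg)
    if method == "sparcc":
        threshold = params.pop("threshold", 0.3)
        params.pop("alpha", None)
        corr = sparcc(table, **params)
        net = correlation_network(corr, threshold, taxonomy=table.taxonomy, method="sparcc")
        net.provenance.update(
            prevalence_threshold_samples=table.meta.get("prevalence_threshold_samples"),
            seed=params.get("seed", 0),
        )
        return net
    if method == "pearson":
        threshold = params.pop("threshold", 0.3)
        alpha = params.pop("alpha", 0.05)
        corr, pvals = pearson_correlation(table, params.pop("pseudocount", 1.0))
        net = correlation_network(
            corr, threshold, pvalues=pvals, alpha=alpha,
            taxonomy=table.taxonomy, method="pearson",
        )
        net.provenance.update(
            prevalence_threshold_samples=table.meta.get("prevalence_threshold_samples"),
            alpha=alpha,
        )
        return net
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# I/O


def write_edge_list(net: CooccurrenceNetwork, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("source\ttarget\tweight\tmethod\n")
        for a, b in sorted(net.edges):
            w = net.weights.get((a, b), 1.0)
            fh.write(f"{a}\t{b}\t{w:.6g}\t{net.method}\n")


def write_node_attributes(
    net: CooccurrenceNetwork, path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        rank_cols = [f"{r}_label" for r in RANKS] + [f"{r}_unknown" for r in RANKS]
        fh.write("otu_id\t" + "\t".join(rank_cols) + "\n")
        for node in net.nodes:
            a = net.taxonomy[node]
            labels = [a.rank_labels[r] for r in RANKS]
            flags = [str(int(a.unknown_at[r])) for r in RANKS]
            fh.write(node + "\t" + "\t".join(labels + flags) + "\n")


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    import networkx as nx

    g = net.to_networkx()
    for node in g.nodes:
        a = net.taxonomy[node]
        for r in RANKS:
            g.nodes[node][f"{r}_label"] = a.rank_labels[r]
            g.nodes[node][f"{r}_unknown"] = bool(a.unknown_at[r])
    nx.write_graphml(g, path)
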
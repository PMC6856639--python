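"""Species-level indices of the realized Eltonian niche.

From the aggregated animal × plant interaction count matrix each taxon
receives six indices: degree, species strength (sum of the partners'
dependencies on the focal taxon), betweenness in the unweighted one-mode
projection, Shannon partner diversity (nats), the node specialization
index (mean shortest-path length to all other same-level taxa in the
projection), and the complementary specialization d' — the
Kullback-Leibler deviation of the taxon's partner-use distribution from
partner availability, standardized to [0, 1] between its feasible integer
minimum and maximum.

The d' extremes are found over integer allocations of the focal taxon's
A_i interactions to partners, each partner usable at most up to its
observed marginal total; the minimum by exact greedy descent on the
separable convex divergence, the maximum by an exact dynamic program over
allocations; exhaustive enumeration replaces both for small problems
(A_i ≤ 12, ≤ 4 partners).
"""

from __future__ import annotations

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "clean_matrix",
    "frequency_indices",
    "d_prime",
    "one_mode_projection",
    "projection_indices",
    "species_level",
    "d_statistic",
    "d_extremes",
    "INDEX_NAMES",
]

INDEX_NAMES = (
    "degree",
    "species_strength",
    "betweenness",
    "partner_diversity",
    "node_specialization_index",
    "d_prime",
)

_EXHAUSTIVE_MAX_TOTAL = 12
_EXHAUSTIVE_MAX_PARTNERS = 4


def _as_matrix(matrix) -> pd.DataFrame:
    m = pd.DataFrame(matrix)
    values = m.to_numpy()
    if (values < 0).any():
        raise ValueError("interaction counts must be nonnegative")
    if not np.allclose(values, np.round(values)):
        raise ValueError("interaction counts must be integers")
    return m.astype(int)


def clean_matrix(matrix) -> pd.DataFrame:
    """Drop all-zero rows/columns (they carry no realized niche) with a warning."""
    m = _as_matrix(matrix)
    zero_rows = m.index[m.sum(axis=1) == 0].tolist()
    zero_cols = m.columns[m.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        warnings.warn(
            f"dropping zero-margin taxa from interaction matrix: rows {zero_rows}, columns {zero_cols}"
        )
        m = m.drop(index=zero_rows, columns=zero_cols)
    if m.size == 0 or m.to_numpy().sum() == 0:
        raise ValueError("interaction matrix has no positive entries")
    return m


def _orient(matrix: pd.DataFrame, level: str) -> pd.DataFrame:
    if level == "rows":
        return matrix
    if level == "columns":
        return matrix.T
    raise ValueError("level must be 'rows' or 'columns'")


def frequency_indices(matrix, level: str = "rows") -> pd.DataFrame:
    """Degree, species strength, and Shannon partner diversity per taxon.

    For a focal taxon i (rows orientation): degree = #{j : a_ij > 0};
    strength = Σ_j a_ij / A_j (dependencies of its partners on it);
    partner diversity = −Σ_j p'_ij ln p'_ij with p'_ij = a_ij / A_i.
    """
    m = _orient(clean_matrix(matrix), level)
    a = m.to_numpy(dtype=float)
    row_tot = a.sum(axis=1)
    col_tot = a.sum(axis=0)
    degree = (a > 0).sum(axis=1)
    strength = (a / col_tot[None, :]).sum(axis=1)
    p = a / row_tot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    diversity = -plogp.sum(axis=1)
    return pd.DataFrame(
        {"degree": degree, "species_strength": strength, "partner_diversity": diversity},
        index=m.index,
    )


def d_statistic(counts: np.ndarray, q: np.ndarray) -> float:
    """Unstandardized d: Σ_{a_j>0} p'_j ln(p'_j / q_j)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty allocation")
    p = counts / total
    mask = counts > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _enumerate_allocations(total: int, caps: tuple[int, ...]):
    """All integer vectors 0 ≤ a ≤ caps with Σ a = total."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    head_max = min(caps[0], total)
    for first in range(head_max + 1):
        for rest in _enumerate_allocations(total - first, caps[1:]):
            yield (first, *rest)


def _extremes_exhaustive(total: int, q: np.ndarray, caps: np.ndarray) -> tuple[float, float]:
    values = [
        d_statistic(np.array(a, dtype=float), q)
        for a in _enumerate_allocations(total, tuple(int(c) for c in caps))
    ]
    return min(values), max(values)


def _d_min_greedy(total: int, q: np.ndarray, caps: np.ndarray) -> float:
    """Exact minimum of d over capped integer allocations.

    d·A_i = Σ_j a_j ln(a_j/(A_i q_j)) is separable and convex in each a_j,
    so adding the A_i units one at a time, each to the partner with the
    smallest marginal increment, reaches the global integer minimum.
    """
    n = len(q)
    alloc = np.zeros(n, dtype=int)
    log_target = np.log(total * q)

    def increment(j: int) -> float:
        x = alloc[j]
        new = (x + 1) * (np.log(x + 1) - log_target[j])
        old = x * (np.log(x) - log_target[j]) if x > 0 else 0.0
        return new - old

    for _ in range(total):
        candidates = [j for j in range(n) if alloc[j] < caps[j]]
        j_best = min(candidates, key=increment)
        alloc[j_best] += 1
    return d_statistic(alloc, q)


def _d_max_dp(total: int, q: np.ndarray, caps: np.ndarray) -> float:
    """Exact maximum of d over capped integer allocations.

    The folklore shortcut — fill the rarest partners to capacity — is not
    the true maximum (a capacity-limited rare partner can force a mixed
    allocation that a point mass on a common partner beats), so the
    maximum is found by dynamic programming over partners with the number
    of allocated interactions as state: O(Σ_j cap_j × A_i) updates.
    """
    minus_inf = -np.inf
    # unnormalized objective Σ_j a_j (ln a_j − ln(A q_j)); divide by A at the end
    log_target = np.log(total * q)
    best = np.full(total + 1, minus_inf)
    best[0] = 0.0
    for j in range(len(q)):
        cap = int(min(caps[j], total))
        x = np.arange(cap + 1, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(x > 0, x * (np.log(np.maximum(x, 1.0)) - log_target[j]), 0.0)
        new = np.full(total + 1, minus_inf)
        for use in range(cap + 1):
            cand = best[: total + 1 - use] + f[use]
            np.maximum(new[use:], cand, out=new[use:])
        best = new
    return float(best[total] / total)


def d_extremes(total: int, q: np.ndarray, caps: np.ndarray) -> tuple[float, float]:
    """Feasible (d_min, d_max) for A_i = ``total`` given availabilities q.

    Allocations are capped by the partners' observed marginal totals; the
    exhaustive search is used when the problem is small enough.
    """
    if total <= _EXHAUSTIVE_MAX_TOTAL and len(q) <= _EXHAUSTIVE_MAX_PARTNERS:
        return _extremes_exhaustive(total, q, caps)
    return _d_min_greedy(total, q, caps), _d_max_dp(total, q, caps)


def d_prime(matrix, level: str = "rows", use_exhaustive: bool | None = None) -> pd.Series:
    """Standardized complementary specialization d' ∈ [0, 1] per taxon.

    d'_i = (d_i − d_min)/(d_max − d_min); a degenerate standardization
    (d_max = d_min, e.g. a single partner column) yields 0.
    ``use_exhaustive`` forces the extreme-allocation route (True/False)
    instead of the size-based default.
    """
    m = _orient(clean_matrix(matrix), level)
    a = m.to_numpy(dtype=float)
    col_tot = a.sum(axis=0)
    grand = a.sum()
    q = col_tot / grand
    caps = col_tot.astype(int)
    out = {}
    for i, taxon in enumerate(m.index):
        counts = a[i]
        total = int(counts.sum())
        if total == 0:
            raise ValueError(f"taxon {taxon}: empty interaction row")
        d_obs = d_statistic(counts, q)
        if use_exhaustive is None:
            d_min, d_max = d_extremes(total, q, caps)
        elif use_exhaustive:
            d_min, d_max = _extremes_exhaustive(total, q, caps)
        else:
            d_min, d_max = _d_min_greedy(total, q, caps), _d_max_dp(total, q, caps)
        if d_max > d_min:
            value = (d_obs - d_min) / (d_max - d_min)
        else:
            value = 0.0
        out[taxon] = float(np.clip(value, 0.0, 1.0))
    return pd.Series(out, name="d_prime")


def one_mode_projection(matrix, level: str = "rows") -> nx.Graph:
    """Unweighted projection: same-level taxa linked iff they share a partner."""
    m = _orient(clean_matrix(matrix), level)
    if len(m.index) < 2:
        raise ValueError("one-mode projection needs at least 2 taxa at the level")
    a = m.to_numpy() > 0
    graph = nx.Graph()
    graph.add_nodes_from(m.index)
    shared = a @ a.T
    taxa = list(m.index)
    for u, v in itertools.combinations(range(len(taxa)), 2):
        if shared[u, v] > 0:
            graph.add_edge(taxa[u], taxa[v])
    return graph


def projection_indices(projection: nx.Graph) -> pd.DataFrame:
    """Betweenness and node specialization index (NSI) from the projection.

    Betweenness is shortest-path betweenness normalized by (n−1)(n−2)/2
    (0 for all nodes when n < 3).  NSI is the mean shortest-path length to
    the other same-level taxa; unreachable taxa are excluded from the mean
    (flagged in ``fully_reachable``) and a taxon reaching nobody gets NaN.
    """
    n = projection.number_of_nodes()
    if n < 3:
        betweenness = {node: 0.0 for node in projection}
    else:
        betweenness = nx.betweenness_centrality(projection, normalized=True)
    nsi = {}
    fully_reachable = {}
    warned = False
    for node in projection:
        lengths = nx.single_source_shortest_path_length(projection, node)
        lengths.pop(node, None)
        reachable = len(lengths)
        fully_reachable[node] = reachable == n - 1
        if reachable < n - 1 and not warned:
            warnings.warn("disconnected one-mode projection: NSI excludes unreachable taxa")
            warned = True
        nsi[node] = float(np.mean(list(lengths.values()))) if reachable else float("nan")
    return pd.DataFrame(
        {
            "betweenness": pd.Series(betweenness),
            "node_specialization_index": pd.Series(nsi),
            "fully_reachable": pd.Series(fully_reachable),
        }
    )


def species_level(matrix) -> pd.DataFrame:
    """All six indices for every animal (rows) and plant (columns) taxon."""
    m = clean_matrix(matrix)
    frames = []
    for level, trophic in (("rows", "animal"), ("columns", "plant")):
        indices = frequency_indices(m, level)
        indices["d_prime"] = d_prime(m, level)
        oriented = _orient(m, level)
        if len(oriented.index) >= 2:
            proj = projection_indices(one_mode_projection(m, level))
        else:
            proj = pd.DataFrame(
                {
                    "betweenness": [0.0],
                    "node_specialization_index": [float("nan")],
                    "fully_reachable": [True],
                },
                index=oriented.index,
            )
        block = indices.join(proj)
        block.insert(0, "taxon", block.index)
        block.insert(1, "trophic_level", trophic)
        frames.append(block.reset_index(drop=True))
    out = pd.concat(frames, ignore_index=True)
    return out[
        ["taxon", "trophic_level", *INDEX_NAMES, "fully_reachable"]
    ]
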
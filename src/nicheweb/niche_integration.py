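"""Interconnectedness of the three niche types.

Per trophic level and scale, every taxon carries ten indices: marginality
and volume of the realized Grinnellian (environment) and fundamental
Eltonian (trait) niches, plus the six bipartite role indices.  Pairwise
Pearson correlations among the ten indices define a significance-filtered
network (edge weight r², sign recorded), whose weighted modularity and
eigenvalue-variance integration summarize how strongly specialization in
one niche type predicts specialization in the others.  Cross-scale and
interaction-frequency correlations follow the same Pearson machinery.
"""

from __future__ import annotations

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INDEX_COLUMNS",
    "assemble_index_matrix",
    "pairwise_correlations",
    "r_squared_from_t",
    "build_correlation_network",
    "modularity_partition",
    "integration_index",
    "cross_scale_correlation",
    "abundance_correlation",
    "network_to_dict",
]

#: The ten per-taxon indices, niche-space measures first.
INDEX_COLUMNS = (
    "grinnellian_marginality",
    "grinnellian_volume",
    "trait_marginality",
    "trait_volume",
    "degree",
    "species_strength",
    "betweenness",
    "partner_diversity",
    "node_specialization_index",
    "d_prime",
)

_NICHE_TYPE_COLUMNS = {
    "grinnellian": ("grinnellian_marginality", "grinnellian_volume"),
    "trait": ("trait_marginality", "trait_volume"),
}


def assemble_index_matrix(niche_summaries: pd.DataFrame, role_indices: pd.DataFrame) -> pd.DataFrame:
    """Outer-join niche summaries and role indices into taxa × 10 indices.

    ``niche_summaries`` holds rows (taxon, niche_type ∈ {grinnellian,
    trait}, marginality, volume); ``role_indices`` the six role columns per
    taxon.  Taxa missing one niche type keep NaN there — correlations are
    later computed pairwise-complete.
    """
    pieces = []
    for niche_type, (m_col, v_col) in _NICHE_TYPE_COLUMNS.items():
        block = niche_summaries[niche_summaries["niche_type"] == niche_type]
        if block["taxon"].duplicated().any():
            dupes = sorted(block.loc[block["taxon"].duplicated(), "taxon"].unique())
            raise ValueError(f"duplicate {niche_type} rows for taxa: {dupes}")
        pieces.append(
            block.set_index("taxon")[["marginality", "volume"]].rename(
                columns={"marginality": m_col, "volume": v_col}
            )
        )
    if role_indices["taxon"].duplicated().any():
        dupes = sorted(role_indices.loc[role_indices["taxon"].duplicated(), "taxon"].unique())
        raise ValueError(f"duplicate role rows for taxa: {dupes}")
    role_cols = [c for c in INDEX_COLUMNS[4:]]
    pieces.append(role_indices.set_index("taxon")[role_cols])
    matrix = pd.concat(pieces, axis=1, join="outer")
    return matrix.reindex(columns=list(INDEX_COLUMNS))


def pairwise_correlations(index_matrix: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Pearson r, two-sided p, and n for every index pair.

    Rows are pairwise-complete; pairs with fewer than ``min_n`` complete
    observations or a zero-variance column are skipped with a warning.
    The p-value is the Student-t tail of t = r√(n−2)/√(1−r²).
    """
    rows = []
    cols = list(index_matrix.columns)
    for a, b in itertools.combinations(cols, 2):
        pair = index_matrix[[a, b]].dropna()
        n = len(pair)
        if n < min_n:
            warnings.warn(f"pair ({a}, {b}): only {n} complete observations, skipped")
            continue
        x = pair[a].to_numpy(dtype=float)
        y = pair[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"pair ({a}, {b}): zero variance, skipped")
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"index_a": a, "index_b": b, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows, columns=["index_a", "index_b", "r", "p", "n"])


def r_squared_from_t(t: float, df: int) -> float:
    """Variance explained from a correlation t statistic: r² = t²/(t² + df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    return t * t / (t * t + df)


def build_correlation_network(correlations: pd.DataFrame, alpha: float = 0.05, nodes=INDEX_COLUMNS) -> nx.Graph:
    """Graph on the indices with an edge per significant correlation.

    Edge weight is r² (in (0, 1]); the sign of r is kept as an attribute.
    Non-significant pairs (p ≥ alpha) get no edge.
    """
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for rec in correlations.itertuples(index=False):
        if rec.p < alpha:
            graph.add_edge(
                rec.index_a,
                rec.index_b,
                weight=float(rec.r) ** 2,
                r=float(rec.r),
                sign=1 if rec.r >= 0 else -1,
                p=float(rec.p),
                n=int(rec.n),
            )
    return graph


def modularity_partition(network: nx.Graph) -> tuple[list[set], float]:
    """Greedy weighted-modularity partition (CNM agglomeration) and its Q.

    Isolated nodes form singleton modules; an edgeless network has Q = 0.
    """
    if network.number_of_edges() == 0:
        return [{node} for node in network.nodes], 0.0
    communities = nx.community.greedy_modularity_communities(network, weight="weight")
    partition = [set(c) for c in communities]
    q = nx.community.modularity(network, partition, weight="weight")
    return partition, float(q)


def integration_index(correlation_matrix, n_effective: int) -> tuple[float, float]:
    """Eigenvalue-variance integration of an N×N correlation matrix.

    raw = population variance of the N eigenvalues (equals
    (N−1) × mean off-diagonal r²).  The sample-size-corrected value
    subtracts the null expectation (N−1)/(n_effective − 1) — under no true
    correlation E[r²] ≈ 1/(n−1) — floored at 0.  NaN off-diagonal cells
    (index pairs never observed together) are imputed as 0 with a warning.
    """
    R = np.array(pd.DataFrame(correlation_matrix), dtype=float)
    if R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    nan_mask = np.isnan(R)
    if nan_mask.any():
        warnings.warn("imputing missing correlations as 0 for the integration index")
        R = np.where(nan_mask, 0.0, R)
    np.fill_diagonal(R, 1.0)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    eigenvalues = np.linalg.eigvalsh(R)
    raw = float(np.var(eigenvalues))
    if n_effective is None or n_effective <= 1:
        raise ValueError("n_effective must exceed 1")
    corrected = max(0.0, raw - (R.shape[0] - 1) / (n_effective - 1))
    return raw, corrected


def correlation_matrix_from_pairs(correlations: pd.DataFrame, nodes=INDEX_COLUMNS) -> pd.DataFrame:
    """Square symmetric r matrix from the pairwise table (NaN where absent)."""
    R = pd.DataFrame(np.nan, index=list(nodes), columns=list(nodes))
    np.fill_diagonal(R.values, 1.0)
    for rec in correlations.itertuples(index=False):
        R.loc[rec.index_a, rec.index_b] = rec.r
        R.loc[rec.index_b, rec.index_a] = rec.r
    return R


def cross_scale_correlation(
    local_index_matrix: pd.DataFrame,
    regional_index_matrix: pd.DataFrame,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per index: Pearson correlation of local vs regional values of shared taxa.

    Reports t, df = n − 2, two-sided p, and r² = t²/(t² + df); an index
    with fewer than ``min_n`` shared taxa is marked not computable.
    """
    shared = local_index_matrix.index.intersection(regional_index_matrix.index)
    rows = []
    for col in local_index_matrix.columns:
        pair = pd.DataFrame(
            {
                "local": local_index_matrix.loc[shared, col],
                "regional": regional_index_matrix.loc[shared, col],
            }
        ).dropna()
        n = len(pair)
        base = {"index": col, "n": n}
        if n < min_n or np.ptp(pair["local"]) == 0 or np.ptp(pair["regional"]) == 0:
            rows.append({**base, "t": np.nan, "df": np.nan, "p": np.nan, "r2": np.nan, "computable": False})
            continue
        r, p = stats.pearsonr(pair["local"], pair["regional"])
        df = n - 2
        if 1.0 - r * r <= 0:
            t = np.copysign(np.inf, r)  # perfect correlation
        else:
            t = r * np.sqrt(df / (1.0 - r * r))
        rows.append(
            {**base, "t": float(t), "df": df, "p": float(p), "r2": float(r * r), "computable": True}
        )
    return pd.DataFrame(rows, columns=["index", "t", "df", "p", "r2", "n", "computable"])


def abundance_correlation(
    total_interactions: pd.Series,
    index_matrix: pd.DataFrame,
    alpha: float = 0.05,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson r of each index with the taxon's total interaction count."""
    rows = []
    for col in index_matrix.columns:
        pair = pd.DataFrame({"total": total_interactions, "index": index_matrix[col]}).dropna()
        n = len(pair)
        if n < min_n:
            warnings.warn(f"index {col}: only {n} taxa with totals, skipped")
            continue
        if np.ptp(pair["index"]) == 0 or np.ptp(pair["total"]) == 0:
            warnings.warn(f"index {col}: zero variance, skipped")
            continue
        r, p = stats.pearsonr(pair["total"], pair["index"])
        rows.append(
            {"index": col, "r": float(r), "p": float(p), "n": n, "significant": bool(p < alpha)}
        )
    return pd.DataFrame(rows, columns=["index", "r", "p", "n", "significant"])


def network_to_dict(network: nx.Graph, partition: list[set], q: float, integration: tuple[float, float]) -> dict:
    """JSON-serializable summary of a correlation network."""
    module_of = {}
    for k, module in enumerate(partition):
        for node in module:
            module_of[node] = k
    return {
        "nodes": [{"id": n, "module": module_of.get(n)} for n in network.nodes],
        "edges": [
            {
                "source": u,
                "target": v,
                "weight": data["weight"],
                "r": data["r"],
                "sign": data["sign"],
                "p": data["p"],
                "n": data["n"],
            }
            for u, v, data in network.edges(data=True)
        ],
        "modularity": q,
        "integration_raw": integration[0],
        "integration_corrected": integration[1],
    }
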
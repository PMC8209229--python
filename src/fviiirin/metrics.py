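"""Per-residue centrality measures and their correlation structure.

Seven measures are always computed on the residue network: degree,
betweenness (unnormalised Brandes pair counts), closeness (within the
node's connected component, (n_comp - 1)/sum of distances), Burt's
constraint, PageRank (uniform teleport), k-core number and the HITS
authority score (power iteration from the uniform vector, max-normalised).
Several of them are strongly correlated on protein residue networks —
degree, betweenness and closeness alone already describe such networks
well — but all seven are reported and the reduction is left to callers.

Conventions on awkward graphs: isolated nodes get closeness 0 and an
undefined (NaN) Burt constraint; HITS is run on the full adjacency, so on
disconnected graphs the authority mass concentrates on the spectrally
dominant component.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CENTRALITY_MEASURES = [
    "degree", "betweenness", "closeness", "burt_constraint",
    "pagerank", "kcore", "authority",
]

PAGERANK_TOL = 1e-12
PAGERANK_MAX_ITER = 10_000
HITS_TOL = 1e-12
HITS_MAX_ITER = 10_000


def _authority_scores(g: nx.Graph) -> Dict[object, float]:
    """HITS authority by power iteration, uniform start, max-normalised.

    On an undirected graph authority equals the hub score and is the
    dominant eigenvector of A^2; iteration is deterministic.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
    x = np.full(n, 1.0 / n)
    for _ in range(HITS_MAX_ITER):
        y = a @ (a @ x)
        m = y.max()
        if m <= 0:  # edgeless graph
            x = np.zeros(n)
            break
        y /= m
        if np.abs(y - x).max() < HITS_TOL:
            x = y
            break
        x = y
    m = x.max()
    if m > 0:
        x = x / m
    return dict(zip(nodes, x.tolist()))


def compute_centralities(g: nx.Graph, damping: float = 0.85,
                         relative_exposure: Optional[Mapping] = None,
                         domain_map: Optional[Mapping] = None) -> pd.DataFrame:
    """Compute the seven centrality measures for every node of ``g``.

    Returns a DataFrame indexed by node with one column per measure, plus
    ``relative_exposure`` and ``domain`` columns when mappings are given.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not (0 < damping < 1):
        raise ValueError("damping must be in (0, 1)")
    nodes = list(g.nodes)

    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    # closeness within the component, (n_comp-1)/sum(d); isolated -> 0
    closeness = nx.closeness_centrality(g, wf_improved=False)
    constraint = nx.constraint(g)  # isolated nodes -> NaN
    pagerank = nx.pagerank(g, alpha=damping, tol=PAGERANK_TOL,
                           max_iter=PAGERANK_MAX_ITER)
    kcore = nx.core_number(g)
    authority = _authority_scores(g)

    df = pd.DataFrame({
        "degree": pd.Series({n: float(degree[n]) for n in nodes}),
        "betweenness": pd.Series(betweenness),
        "closeness": pd.Series(closeness),
        "burt_constraint": pd.Series({n: float(constraint[n]) for n in nodes}),
        "pagerank": pd.Series(pagerank),
        "kcore": pd.Series({n: float(kcore[n]) for n in nodes}),
        "authority": pd.Series(authority),
    })
    df = df.loc[nodes]
    if relative_exposure is not None:
        df["relative_exposure"] = pd.Series(
            {n: relative_exposure.get(n, np.nan) for n in nodes})
    if domain_map is not None:
        df["domain"] = pd.Series(
            {n: domain_map.get(n, "unassigned") for n in nodes})
    return df


def measure_correlations(t: pd.DataFrame,
                         measures: Optional[Sequence[str]] = None
                         ) -> pd.DataFrame:
    """Pearson correlation matrix among centrality measures.

    Zero-variance measures get NaN rows/columns (with a warning); the
    diagonal is exactly 1 for well-defined measures.
    """
    measures = list(measures) if measures is not None else [
        m for m in CENTRALITY_MEASURES if m in t.columns]
    if len(t) < 3:
        raise ValueError("need at least 3 rows to correlate measures")
    sub = t[measures].astype(float)
    out = pd.DataFrame(np.eye(len(measures)), index=measures, columns=measures)
    stds = sub.std(ddof=1)
    degenerate = [m for m in measures if not np.isfinite(stds[m]) or stds[m] == 0]
    for m in degenerate:
        warnings.warn(f"measure {m!r} has zero variance; correlations undefined")
    for i, mi in enumerate(measures):
        for j, mj in enumerate(measures):
            if i == j:
                if mi in degenerate:
                    out.iloc[i, j] = np.nan
                continue
            if mi in degenerate or mj in degenerate:
                out.iloc[i, j] = np.nan
            else:
                out.iloc[i, j] = float(np.corrcoef(sub[mi], sub[mj])[0, 1])
    return out
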
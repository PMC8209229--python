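"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — dense Floyd–Warshall with path
counting, all-pairs double loops, direct formula transcriptions, dense
eigendecompositions — and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# shortest-path measures (Floyd–Warshall with path counting)


def fw_distances_and_counts(adj: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """All-pairs distances and shortest-path counts on an unweighted graph."""
    n = len(adj)
    inf = math.inf
    dist = np.full((n, n), inf)
    count = np.zeros((n, n))
    for i in range(n):
        dist[i, i] = 0.0
        count[i, i] = 1.0
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                dist[i, j] = 1.0
                count[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
                    count[i, j] = count[i, k] * count[k, j]
                elif dist[i, k] + dist[k, j] == dist[i, j] and dist[i, j] < inf \
                        and k != i and k != j:
                    count[i, j] += count[i, k] * count[k, j]
    return dist, count


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Unnormalised betweenness: pair dependencies, each unordered pair once."""
    n = len(adj)
    dist, count = fw_distances_and_counts(adj)
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not math.isfinite(dist[s, t]) or count[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    out[v] += count[s, v] * count[v, t] / count[s, t]
    return out


def closeness_oracle(adj: np.ndarray) -> np.ndarray:
    """(n_comp - 1) / sum of within-component distances; isolated -> 0."""
    n = len(adj)
    dist, _ = fw_distances_and_counts(adj)
    out = np.zeros(n)
    for v in range(n):
        reach = [u for u in range(n) if u != v and math.isfinite(dist[v, u])]
        if reach:
            out[v] = len(reach) / sum(dist[v, u] for u in reach)
    return out


# ---------------------------------------------------------------------------
# Burt's constraint, k-core, PageRank, authority


def burt_constraint_oracle(adj: np.ndarray) -> np.ndarray:
    """Direct transcription of Burt's formula with p_ij = 1/degree(i)."""
    n = len(adj)
    deg = adj.sum(axis=1)
    out = np.full(n, np.nan)
    for i in range(n):
        if deg[i] == 0:
            continue
        total = 0.0
        neighbors = [j for j in range(n) if adj[i, j]]
        for j in neighbors:
            p_ij = 1.0 / deg[i]
            indirect = 0.0
            for q in neighbors:
                if q in (i, j) or not adj[q, j]:
                    continue
                indirect += (1.0 / deg[i]) * (1.0 / deg[q])
            total += (p_ij + indirect) ** 2
        out[i] = total
    return out


def kcore_oracle(adj: np.ndarray) -> np.ndarray:
    """Core numbers by repeated peeling."""
    n = len(adj)
    alive = set(range(n))
    core = np.zeros(n, dtype=int)
    k = 0
    while alive:
        while True:
            peel = [v for v in alive
                    if sum(1 for u in alive if adj[v, u]) < k + 1]
            if not peel:
                break
            for v in peel:
                core[v] = k
                alive.discard(v)
        if alive:
            k += 1
            for v in alive:
                core[v] = k
    return core


def pagerank_oracle(adj: np.ndarray, damping: float = 0.85,
                    tol: float = 1e-12, max_iter: int = 100_000) -> np.ndarray:
    """Dense power iteration with uniform teleport and dangling-node fix."""
    n = len(adj)
    deg = adj.sum(axis=1)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = np.full(n, (1.0 - damping) / n)
        dangling_mass = x[deg == 0].sum()
        new += damping * dangling_mass / n
        for j in range(n):
            if deg[j] > 0:
                new += damping * x[j] * adj[j] / deg[j]
        if np.abs(new - x).sum() < tol:
            return new
        x = new
    return x


def authority_oracle(adj: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of A^2 from a uniform start, max-normalised.

    Mirrors the HITS definition via dense eigendecomposition: project the
    uniform start onto the dominant eigenspace of A (largest |lambda|),
    square the spectrum's effect by construction, take magnitudes.
    """
    n = len(adj)
    w, v = np.linalg.eigh(adj.astype(float))
    lam2 = w ** 2
    top = np.isclose(lam2, lam2.max(), rtol=1e-12, atol=1e-12)
    start = np.full(n, 1.0 / n)
    # power iteration on A^2 converges to the projection of the start
    # vector onto the top eigenspace of A^2
    proj = v[:, top] @ (v[:, top].T @ start)
    x = np.abs(proj)
    if x.max() > 0:
        x = x / x.max()
    return x


# ---------------------------------------------------------------------------
# geometry / dominance / stats


def contacts_bruteforce(structure, cutoff: float,
                        exclude_covalent: bool = True) -> Dict[tuple, float]:
    """All-pairs double loop over heavy atoms; returns pair -> min distance."""
    keys = list(structure.residues)
    order = {k: i for i, k in enumerate(keys)}
    atoms = structure.heavy_atoms()
    # successor pairs per chain, in file order
    peptide = set()
    by_chain: Dict[str, list] = {}
    for k in keys:
        by_chain.setdefault(k.chain_id, []).append(k)
    for ks in by_chain.values():
        for a, b in zip(ks, ks[1:]):
            peptide.add((a, b))
    out: Dict[tuple, float] = {}
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ai, aj = atoms[i], atoms[j]
            ka, kb = ai.residue_key, aj.residue_key
            if ka == kb:
                continue
            if order[ka] > order[kb]:
                ka, kb, ai, aj = kb, ka, aj, ai
            d = math.dist(ai.coords, aj.coords)
            if d > cutoff:
                continue
            if exclude_covalent:
                if (ka, kb) in peptide and ai.name == "C" and aj.name == "N":
                    continue
                if ai.name == "SG" and aj.name == "SG" and d < 2.5 and \
                        ka.residue_type == "CYS" and kb.residue_type == "CYS":
                    continue
            key = (ka, kb)
            out[key] = min(out.get(key, math.inf), d)
    return out


def pareto_front_oracle(points: np.ndarray) -> Set[int]:
    """O(n^2) all-pairs dominance scan (maximisation, weak + one strict)."""
    n = len(points)
    front = set()
    for i in range(n):
        dominated = False
        for j in range(n):
            if j == i:
                continue
            if np.all(points[j] >= points[i]) and np.any(points[j] > points[i]):
                dominated = True
                break
        if not dominated:
            front.add(i)
    return front


def shrake_rupley_oracle(coords: np.ndarray, radii: np.ndarray,
                         probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Naive per-atom Shrake–Rupley with golden-spiral quadrature points."""
    idx = np.arange(n_points, dtype=float)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (idx + 0.5) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    sphere = np.column_stack((r * np.cos(golden * idx),
                              r * np.sin(golden * idx), z))
    expanded = radii + probe
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) > expanded[i] + expanded[j]:
                continue
            exposed &= np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
        areas[i] = exposed.mean() * 4.0 * math.pi * expanded[i] ** 2
    return areas


def exact_ranksum_pvalue(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by exhaustive enumeration (no ties)."""
    pooled = sorted(list(a) + list(b))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in a)
    n, m = len(a), len(b)
    mean = n * (len(pooled) + 1) / 2.0
    obs_dev = abs(obs - mean)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        total += 1
        if abs(sum(combo) - mean) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total


def kappa_oracle(tp: int, fn: int, fp: int, tn: int) -> float:
    """Cohen's Kappa from a 2x2 confusion table, direct formula."""
    n = tp + fn + fp + tn
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n ** 2
    return (po - pe) / (1 - pe)


def pearson_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Textbook covariance-over-sd formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def auc_rank_oracle(truth: Sequence[int], scores: Sequence[float]) -> float:
    """AUC as the Mann–Whitney rank statistic."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for p in pos:
        wins += (p > neg).sum() + 0.5 * (p == neg).sum()
    return wins / (len(pos) * len(neg))
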
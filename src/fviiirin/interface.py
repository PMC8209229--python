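"""Binding-site neighbourhoods and centrality comparisons.

Factor VIII binds FIXa, FX, thrombin, von Willebrand factor and the
platelet phospholipid membrane through surface loops.  Given curated
binding-site residue lists, this module extracts their first-shell network
neighbours and compares centrality distributions between the two groups
with the unpaired two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from scipy import stats

from .structure import ResidueKey

logger = logging.getLogger(__name__)

EXACT_MAX_N = 25  # exact rank-sum enumeration for both groups at or below this


@dataclass
class BindingSiteSet:
    """Residues reported to contact one binding partner."""

    partner: str
    residues: Set[ResidueKey] = field(default_factory=set)

    def restrict_to(self, nodes: Iterable) -> "BindingSiteSet":
        nodes = set(nodes)
        kept = {r for r in self.residues if r in nodes}
        dropped = self.residues - kept
        if dropped:
            logger.warning("binding site %s: %d residues not in network, "
                           "dropped", self.partner, len(dropped))
        return BindingSiteSet(self.partner, kept)


def read_binding_sites(path: str | Path,
                       resolve: Optional[Dict[Tuple[str, int], ResidueKey]] = None
                       ) -> List[BindingSiteSet]:
    """Read a binding-site TSV (partner, chain, position[, source]).

    When ``resolve`` maps (chain, position) to full residue keys, rows are
    resolved through it; otherwise bare (chain, position) tuples are kept
    and must be matched by the caller.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    sites: Dict[str, BindingSiteSet] = {}
    for _, row in df.iterrows():
        partner = str(row["partner"])
        key = (str(row["chain"]), int(row["position"]))
        if resolve is not None:
            if key not in resolve:
                logger.warning("binding site %s: %s not resolvable", partner, key)
                continue
            residue = resolve[key]
        else:
            residue = key
        sites.setdefault(partner, BindingSiteSet(partner)).residues.add(residue)
    return list(sites.values())


def neighborhood(g: nx.Graph, sites: Iterable[BindingSiteSet] | Set,
                 shell: int = 1) -> Set:
    """First-shell (or ``shell``-hop) network neighbours of the site union.

    Returns every node within ``shell`` steps of a site residue, minus the
    site residues themselves.  Site residues absent from the network are
    dropped with a warning; an empty intersection is an error.
    """
    if isinstance(sites, (set, frozenset)):
        site_residues = set(sites)
    else:
        site_residues = set().union(*(s.residues for s in sites))
    present = site_residues & set(g.nodes)
    missing = site_residues - present
    if missing:
        logger.warning("%d site residues not in network: %s", len(missing),
                       sorted(str(m) for m in missing)[:5])
    if not present:
        raise ValueError(
            f"no binding-site residues found in the network; unmatched: "
            f"{sorted(str(m) for m in site_residues)}")
    shell_nodes = set(present)
    frontier = set(present)
    for _ in range(shell):
        frontier = {u for v in frontier for u in g.neighbors(v)} - shell_nodes
        shell_nodes |= frontier
    return shell_nodes - present


def compare_centrality(t: pd.DataFrame, group_a: Set, group_b: Set,
                       measure: str) -> dict:
    """Unpaired two-sided Wilcoxon rank-sum comparison of one measure.

    Exact enumeration when both groups have at most 25 members and the
    pooled values are tie-free; normal approximation with tie correction
    otherwise.  Returns statistic, p-value, group sizes and medians.
    """
    if group_a & group_b:
        raise ValueError("groups overlap")
    a = t.loc[[i for i in t.index if i in group_a], measure].dropna().astype(float)
    b = t.loc[[i for i in t.index if i in group_b], measure].dropna().astype(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 members with the measure defined")
    pooled = pd.concat([a, b])
    no_ties = pooled.nunique() == len(pooled)
    method = "exact" if (len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N
                         and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "measure": measure, "n_a": len(a), "n_b": len(b),
        "median_a": float(a.median()), "median_b": float(b.median()),
        "statistic": float(res.statistic), "p_value": float(res.pvalue),
        "method": method, "test": "wilcoxon_rank_sum_two_sided",
    }


def comparison_report(t: pd.DataFrame, group_a: Set, group_b: Set,
                      measures: Sequence[str]) -> pd.DataFrame:
    """One :func:`compare_centrality` row per measure, CSV-ready."""
    return pd.DataFrame([compare_centrality(t, group_a, group_b, m)
                         for m in measures])
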
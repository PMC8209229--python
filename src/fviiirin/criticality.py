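"""Criticality grouping, Pareto-front super-critical residues, domain summaries.

Residues are partitioned by degree/betweenness quantile thresholds into
high-degree/high-betweenness (HDHB, inter-domain structural hubs),
low-degree/high-betweenness (LDHB, bridge residues often near binding
sites) and low-degree/low-betweenness (LDLB, loop support residues);
everything else is unassigned.  The "super-critical" residues are the
Pareto front — the non-dominated set — of degree, betweenness and
closeness jointly.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

GROUPS = ("HDHB", "LDHB", "LDLB", "unassigned")
DEFAULT_HIGH_QUANTILE = 0.90
DEFAULT_LOW_QUANTILE = 0.50
PARETO_MEASURES = ("degree", "betweenness", "closeness")


def assign_groups(t: pd.DataFrame,
                  degree_high: float = DEFAULT_HIGH_QUANTILE,
                  betweenness_high: float = DEFAULT_HIGH_QUANTILE,
                  degree_low: float = DEFAULT_LOW_QUANTILE,
                  betweenness_low: float = DEFAULT_LOW_QUANTILE) -> pd.Series:
    """Label each residue HDHB / LDHB / LDLB / unassigned.

    Thresholds are quantiles of the degree and betweenness columns
    (linear interpolation), so labels are invariant under rank-preserving
    rescaling of either measure.
    """
    for lo, hi in ((degree_low, degree_high), (betweenness_low, betweenness_high)):
        if not (0 <= lo < hi <= 1):
            raise ValueError(
                f"low quantile must be below high quantile in [0,1]; "
                f"got low={lo}, high={hi}")
    deg = t["degree"].astype(float)
    btw = t["betweenness"].astype(float)
    d_hi, d_lo = deg.quantile(degree_high), deg.quantile(degree_low)
    b_hi, b_lo = btw.quantile(betweenness_high), btw.quantile(betweenness_low)

    labels = pd.Series("unassigned", index=t.index, dtype=object)
    labels[(deg >= d_hi) & (btw >= b_hi)] = "HDHB"
    labels[(deg <= d_lo) & (btw >= b_hi)] = "LDHB"
    labels[(deg <= d_lo) & (btw <= b_lo)] = "LDLB"
    labels.name = "group"
    return labels


def pareto_front(t: pd.DataFrame,
                 measures: Sequence[str] = PARETO_MEASURES) -> Set:
    """Non-dominated set of nodes on the given measures (maximisation).

    A node is in the front iff no other node is >= on every measure and
    > on at least one.  Nodes with exact ties on all measures dominate
    nobody and are kept together.  Nodes with a missing measure are
    excluded with a warning.
    """
    import warnings

    sub = t[list(measures)].astype(float)
    missing = sub.index[sub.isna().any(axis=1)]
    if len(missing):
        warnings.warn(f"{len(missing)} nodes missing a measure; excluded "
                      f"from Pareto front")
        sub = sub.dropna()
    x = sub.to_numpy()
    n = len(x)
    front = np.ones(n, dtype=bool)
    for i in range(n):
        if not front[i]:
            continue
        ge = (x >= x[i]).all(axis=1)
        gt = (x > x[i]).any(axis=1)
        if (ge & gt).any():
            front[i] = False
    return set(sub.index[front])


def domain_closeness_summary(t: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of closeness per domain label.

    Quartiles use the linear-interpolation convention; unlabeled residues
    are grouped under "unassigned".  The convention is recorded in the
    output attrs.
    """
    if "domain" not in t.columns:
        raise KeyError("domain labels missing from centrality table")
    dom = t["domain"].fillna("unassigned").replace("", "unassigned")
    rows = []
    for name, grp in t.groupby(dom, sort=True):
        c = grp["closeness"].astype(float)
        rows.append({
            "domain": name, "n": len(c),
            "q1": c.quantile(0.25), "median": c.quantile(0.50),
            "q3": c.quantile(0.75),
        })
    out = pd.DataFrame(rows)
    out.attrs["quantile_convention"] = "linear interpolation"
    return out


def criticality_table(t: pd.DataFrame, **group_kwargs) -> pd.DataFrame:
    """Groups plus Pareto flag in one table (CSV/attribute-file ready)."""
    groups = assign_groups(t, **group_kwargs)
    front = pareto_front(t)
    out = pd.DataFrame({"group": groups})
    out["pareto_front"] = [idx in front for idx in t.index]
    return out


#: colour names for structure/graph viewers, keyed by criticality group
GROUP_COLORS = {"HDHB": "red", "LDHB": "orange", "LDLB": "steel blue",
                "unassigned": "gray"}


def write_attribute_file(crit: pd.DataFrame, path) -> None:
    """Write a viewer-ready attribute file mapping residues to group colours."""
    with open(path, "w") as fh:
        fh.write("residue\tgroup\tcolor\tpareto_front\n")
        for idx, row in crit.iterrows():
            label = idx.label() if hasattr(idx, "label") else str(idx)
            fh.write(f"{label}\t{row['group']}\t"
                     f"{GROUP_COLORS[row['group']]}\t{row['pareto_front']}\n")
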
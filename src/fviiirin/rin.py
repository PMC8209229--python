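"""Residue interaction network (RIN) construction.

Two residues are connected when at least one heavy-atom pair sits within a
distance cutoff (default 5.0 A) and that atom pair is not covalently bonded
(inter-residue peptide bonds C(i)-N(i+1) and disulfide SG-SG pairs are
excluded, as are intra-residue pairs).  Edges are untyped by weight but
annotated with the chain-part combinations observed among qualifying atom
pairs: main-chain/main-chain (mc_mc), main-chain/side-chain (mc_sc) and
side-chain/side-chain (sc_sc).  The graph is simple and undirected; nodes
with no contact are retained as isolated nodes so the node count equals the
residue count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomRecord, ResidueKey, Structure

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5.0
DISULFIDE_SG_CUTOFF = 2.5


@dataclass
class ContactEdge:
    residue_a: ResidueKey
    residue_b: ResidueKey
    interaction_classes: Set[str]
    min_distance: float


def _class_of(a: AtomRecord, b: AtomRecord) -> str:
    parts = sorted((a.chain_part, b.chain_part))
    if parts == ["main_chain", "main_chain"]:
        return "mc_mc"
    if parts == ["side_chain", "side_chain"]:
        return "sc_sc"
    return "mc_sc"


def _sequence_successors(s: Structure) -> Set[Tuple[ResidueKey, ResidueKey]]:
    """Unordered pairs of residues adjacent in chain order (peptide bonds)."""
    pairs: Set[Tuple[ResidueKey, ResidueKey]] = set()
    by_chain: Dict[str, List[ResidueKey]] = {}
    for key in s.residues:
        by_chain.setdefault(key.chain_id, []).append(key)
    for keys in by_chain.values():
        for a, b in zip(keys, keys[1:]):
            pairs.add((a, b))
    return pairs


def detect_contacts(s: Structure, cutoff: float = DEFAULT_CUTOFF,
                    exclude_covalent: bool = True) -> List[ContactEdge]:
    """Find all residue-residue contacts within ``cutoff`` A (heavy atoms).

    Returns one :class:`ContactEdge` per unordered residue pair with at
    least one qualifying atom pair; ``interaction_classes`` records every
    chain-part combination seen and ``min_distance`` the smallest
    qualifying distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    atoms = s.heavy_atoms()
    if not atoms:
        return []
    coords = np.array([a.coords for a in atoms], dtype=float)
    tree = cKDTree(coords)
    peptide_pairs = _sequence_successors(s) if exclude_covalent else set()

    edges: Dict[Tuple[ResidueKey, ResidueKey], ContactEdge] = {}
    key_order = {k: i for i, k in enumerate(s.residues)}
    for i, j in tree.query_pairs(cutoff):
        ai, aj = atoms[i], atoms[j]
        ka, kb = ai.residue_key, aj.residue_key
        if ka == kb:
            continue
        if key_order[ka] > key_order[kb]:
            ka, kb, ai, aj = kb, ka, aj, ai
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if exclude_covalent:
            # peptide bond: C of the earlier residue to N of its successor
            if (ka, kb) in peptide_pairs and ai.name == "C" and aj.name == "N":
                continue
            if ai.name == "SG" and aj.name == "SG" and \
                    ka.residue_type == "CYS" and kb.residue_type == "CYS" and \
                    d < DISULFIDE_SG_CUTOFF:
                continue
        cls = _class_of(ai, aj)
        edge = edges.get((ka, kb))
        if edge is None:
            edges[(ka, kb)] = ContactEdge(ka, kb, {cls}, d)
        else:
            edge.interaction_classes.add(cls)
            edge.min_distance = min(edge.min_distance, d)
    return list(edges.values())


def build_network(contacts: Iterable[ContactEdge],
                  residues: Sequence[ResidueKey],
                  provenance: Optional[dict] = None) -> nx.Graph:
    """Assemble a simple undirected residue network.

    Duplicate pairs are merged (union of interaction classes, minimum of
    distances), self-pairs are dropped with a warning, and residues without
    any contact are retained as isolated nodes (and logged).
    """
    g = nx.Graph()
    g.graph["provenance"] = dict(provenance or {})
    universe = set(residues)
    g.add_nodes_from(residues)
    for c in contacts:
        if c.residue_a == c.residue_b:
            logger.warning("self-contact on %s dropped", c.residue_a.label())
            continue
        if c.residue_a not in universe or c.residue_b not in universe:
            raise KeyError(
                f"contact references residue outside the universe: "
                f"{c.residue_a.label()}-{c.residue_b.label()}")
        if g.has_edge(c.residue_a, c.residue_b):
            data = g.edges[c.residue_a, c.residue_b]
            data["interaction_classes"] = sorted(
                set(data["interaction_classes"]) | set(c.interaction_classes))
            data["min_distance"] = min(data["min_distance"], c.min_distance)
        else:
            g.add_edge(c.residue_a, c.residue_b,
                       interaction_classes=sorted(c.interaction_classes),
                       min_distance=c.min_distance)
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    if isolated:
        logger.info("build_network: %d isolated residues retained", len(isolated))
    return g


def build_rin(s: Structure, cutoff: float = DEFAULT_CUTOFF,
              exclude_covalent: bool = True) -> nx.Graph:
    """Convenience: detect contacts and build the network in one call."""
    contacts = detect_contacts(s, cutoff=cutoff, exclude_covalent=exclude_covalent)
    return build_network(
        contacts, list(s.residues),
        provenance={"cutoff": cutoff, "exclude_covalent": exclude_covalent,
                    "structure_id": s.structure_id},
    )
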
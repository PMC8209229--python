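"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of a :class:`GeneratorSpec` seed:

* :func:`generate_structure` — toy protein structures (ideal alpha helix,
  extended chain, or two spatially separated helical domains) built from
  standard backbone internal coordinates, with a single pseudo side-chain
  atom per residue, emitted as valid PDB text;
* :func:`generate_activity_labels` — alanine-scan-style mutant activity
  tables whose Low/High labels depend monotonically on a chosen centrality
  through a logistic link, with the exact per-instance Bayes probabilities
  recorded as calibration ground truth;
* :func:`generate_clinical_table` — raw clinical mutation tables with a
  planted positional enrichment and a known census of messy activity
  strings for the sanitizer to handle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .classifier import MutantRecord
from .structure import AtomRecord, ResidueKey, Structure, classify_chain_part

# backbone internal coordinates (lengths A, angles deg)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
OMEGA = 180.0
PHI_PSI = {"helix": (-57.0, -47.0), "extended": (-120.0, 120.0)}
SIDECHAIN_LENGTH = 2.4  # pseudo side-chain atom along the outward direction

DEFAULT_TWO_DOMAIN_SEPARATION = 30.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic generators."""

    seed: int
    n_residues: int = 30
    fold: str = "helix"  # helix | extended | two_domain
    activity_beta: float = 4.0
    activity_feature: str = "closeness"
    clinical_enrichment: float = 3.0
    n_clinical: int = 500
    jitter: float = 0.0  # coordinate noise sd (A), seeded
    domain_separation: float = DEFAULT_TWO_DOMAIN_SEPARATION
    n_messy: int = 7

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("n_residues must be >= 3")
        if self.fold not in ("helix", "extended", "two_domain"):
            raise ValueError(f"unknown fold {self.fold!r}")


# ---------------------------------------------------------------------------
# geometry


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                r: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """Internal-coordinate atom placement (natural extension frame)."""
    theta, chi = math.radians(theta_deg), math.radians(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * math.cos(theta),
                  r * math.sin(theta) * math.cos(chi),
                  r * math.sin(theta) * math.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _backbone(n_res: int, phi: float, psi: float) -> List[Dict[str, np.ndarray]]:
    """N/CA/C/O coordinates for an ideal chain with fixed phi/psi."""
    res: List[Dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi)
        ca = _place_atom(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, OMEGA)
        c = _place_atom(prev["C"], n, ca, B_CA_C, A_N_CA_C, phi)
        res.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: anti to the next amide nitrogen
    for i, r in enumerate(res):
        chi = psi + 180.0
        r["O"] = _place_atom(r["N"], r["CA"], r["C"], B_C_O, A_CA_C_O, chi)
    return res


def _align_to_z(residues: List[Dict[str, np.ndarray]]) -> None:
    """Rotate/translate so the CA principal axis lies on z, centroid at origin."""
    cas = np.array([r["CA"] for r in residues])
    center = cas.mean(axis=0)
    u, s, vt = np.linalg.svd(cas - center)
    axis = vt[0]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    for r in residues:
        for k in r:
            r[k] = rot @ (r[k] - center)


def _add_sidechains(residues: List[Dict[str, np.ndarray]], fold: str,
                    types: Sequence[str]) -> None:
    """One pseudo side-chain atom per non-glycine residue.

    Helical folds place it radially outward from the helix axis (z, after
    alignment); the extended fold uses the tetrahedral bisector direction.
    """
    for r, rtype in zip(residues, types):
        if rtype == "GLY":
            continue
        ca = r["CA"]
        if fold in ("helix", "two_domain"):
            radial = np.array([ca[0], ca[1], 0.0])
            nrm = np.linalg.norm(radial)
            direction = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        else:
            u = r["N"] - ca
            v = r["C"] - ca
            direction = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
            direction /= np.linalg.norm(direction)
        r["CB"] = ca + SIDECHAIN_LENGTH * direction


def _pdb_lines(chains: List[Tuple[str, int, str, Dict[str, np.ndarray]]]
               ) -> List[str]:
    lines = []
    serial = 1
    for chain_id, seq, rtype, atoms in chains:
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in atoms:
                continue
            x, y, z = atoms[name]
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{rtype:>4s} {chain_id}"
                f"{seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}")
            serial += 1
    lines.append("END")
    return lines


def generate_structure(spec: GeneratorSpec,
                       path: Optional[str | Path] = None,
                       residue_types: Optional[Sequence[str]] = None
                       ) -> Tuple[Structure, str]:
    """Build a synthetic structure; returns (Structure, PDB text).

    Same spec -> byte-identical PDB.  ``residue_types`` overrides the
    default all-alanine sequence (3-letter codes, length n_residues).
    """
    n = spec.n_residues
    types = list(residue_types) if residue_types else ["ALA"] * n
    if len(types) != n:
        raise ValueError("residue_types length must equal n_residues")

    chains: List[Tuple[str, int, str, Dict[str, np.ndarray]]] = []
    if spec.fold in ("helix", "extended"):
        phi, psi = PHI_PSI["helix" if spec.fold == "helix" else "extended"]
        residues = _backbone(n, phi, psi)
        if spec.fold == "helix":
            _align_to_z(residues)
        _add_sidechains(residues, spec.fold, types)
        for i, r in enumerate(residues):
            chains.append(("A", i + 1, types[i], r))
    else:  # two_domain: two aligned helices, axes offset along x
        n_a = n // 2
        phi, psi = PHI_PSI["helix"]
        for d, (chain_id, n_dom, offset) in enumerate(
                [("A", n_a, 0.0), ("B", n - n_a, spec.domain_separation)]):
            residues = _backbone(n_dom, phi, psi)
            _align_to_z(residues)
            for r in residues:
                for k in r:
                    r[k] = r[k] + np.array([offset, 0.0, 0.0])
            dom_types = types[:n_dom] if d == 0 else types[n_a:]
            _add_sidechains_offset(residues, dom_types, offset)
            start = 1 if d == 0 else n_a + 1
            for i, r in enumerate(residues):
                chains.append((chain_id, start + i, dom_types[i], r))

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        for _, _, _, atoms in chains:
            for k in atoms:
                atoms[k] = atoms[k] + rng.normal(0.0, spec.jitter, size=3)

    pdb_text = "\n".join(_pdb_lines(chains)) + "\n"
    if path is not None:
        Path(path).write_text(pdb_text)

    residues_map: Dict[ResidueKey, List[AtomRecord]] = {}
    for chain_id, seq, rtype, atoms in chains:
        key = ResidueKey(chain_id, seq, "", rtype)
        recs = []
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in atoms:
                continue
            recs.append(AtomRecord(
                name=name, element=name[0], residue_key=key,
                coords=tuple(round(float(v), 3) for v in atoms[name]),
                chain_part=classify_chain_part(name, name[0])))
        residues_map[key] = recs
    return Structure(structure_id=f"synthetic_{spec.fold}",
                     residues=residues_map), pdb_text


def _add_sidechains_offset(residues, types, offset: float) -> None:
    """Radial side chains for a helix whose axis was shifted to x=offset."""
    for r, rtype in zip(residues, types):
        if rtype == "GLY":
            continue
        ca = r["CA"]
        radial = np.array([ca[0] - offset, ca[1], 0.0])
        nrm = np.linalg.norm(radial)
        direction = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        r["CB"] = ca + SIDECHAIN_LENGTH * direction


# ---------------------------------------------------------------------------
# activity labels


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_activity_labels(t: pd.DataFrame, spec: GeneratorSpec
                             ) -> Tuple[List[MutantRecord], pd.DataFrame]:
    """Alanine-scan mutant table with planted centrality dependence.

    P(Low) = logistic(activity_beta * z), z the z-scored activity feature.
    Chromogenic percentages are drawn from triangular distributions
    conditioned on the drawn class (modes 10 and 90), so the 50% rule is
    exercised with realistic spread.  Returns the mutant records and a
    ground-truth frame (z, p_low, drawn label, Bayes-optimal label).
    """
    feat = t[spec.activity_feature].astype(float)
    sd = feat.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"feature {spec.activity_feature!r} has zero variance")
    z = (feat - feat.mean()) / sd
    p_low = _logistic(spec.activity_beta * z.to_numpy())
    rng = np.random.default_rng(spec.seed)
    low = rng.random(len(t)) < p_low
    pct = np.where(low, rng.triangular(0.0, 10.0, 50.0, size=len(t)),
                   rng.triangular(50.0, 90.0, 100.0, size=len(t)))
    secretion = np.where(low, rng.triangular(0.0, 15.0, 60.0, size=len(t)),
                         rng.triangular(40.0, 85.0, 100.0, size=len(t)))
    mutants = [
        MutantRecord(residue_key=key, substitution="ALA",
                     chromogenic_pct=float(c), secretion_pct=float(s))
        for key, c, s in zip(t.index, pct, secretion)
    ]
    truth = pd.DataFrame({
        "z": z, "p_low": p_low, "drawn_low": low,
        "bayes_label_low": p_low > 0.5,
        "bayes_correct_prob": np.maximum(p_low, 1.0 - p_low),
    }, index=t.index)
    return mutants, truth


def mutants_to_frame(mutants: Sequence[MutantRecord]) -> pd.DataFrame:
    """Mutant CSV-ready frame (chain, position, wt_aa, mut_aa, activities)."""
    return pd.DataFrame([{
        "chain": m.residue_key.chain_id, "position": m.residue_key.seq_number,
        "wt_aa": m.residue_key.residue_type, "mut_aa": m.substitution,
        "chromogenic_pct": m.chromogenic_pct, "secretion_pct": m.secretion_pct,
    } for m in mutants])


# ---------------------------------------------------------------------------
# clinical tables

#: the messy activity forms planted in every generated clinical table,
#: with the sanitizer action each must trigger
MESSY_FORMS = [
    {"fviii_c_raw": "10 to 24", "expect": "range_average"},
    {"fviii_c_raw": "< 1", "expect": "bound_substitution"},
    {"severity": "mild/moderate", "expect": "ambiguous_severity"},
    {"protein_change": "Arg336Ter", "expect": "stop_codon"},
    {"fviii_c_raw": "150", "expect": "activity_above_100"},
    {"fviii_c_raw": "0 to 2", "expect": "ambiguous_range"},
    {"fviii_c_raw": "normal", "expect": "non_numeric_activity"},
]


def _severity_for(value: float) -> str:
    if value < 1.0:
        return "severe"
    if value <= 5.0:
        return "moderate"
    return "mild"


def generate_clinical_table(positions: Sequence[int], spec: GeneratorSpec,
                            harmful: Optional[Set[int]] = None
                            ) -> Tuple[pd.DataFrame, dict]:
    """Raw clinical mutation table with planted positional enrichment.

    Record positions are sampled with odds multiplied by
    ``clinical_enrichment`` inside the designated harmful set (default:
    the first half of ``positions``).  The first ``n_messy`` records cycle
    through :data:`MESSY_FORMS` in known counts.  Returns the raw table
    and a ground-truth dict (harmful set, messy record ids and the rule
    each must trigger).
    """
    positions = sorted(set(int(p) for p in positions))
    if not positions:
        raise ValueError("empty position set")
    if spec.n_clinical < 10:
        raise ValueError("n_clinical must be >= 10")
    if harmful is None:
        harmful = set(positions[: len(positions) // 2])
    rng = np.random.default_rng(spec.seed)
    weights = np.array([spec.clinical_enrichment if p in harmful else 1.0
                        for p in positions], dtype=float)
    weights /= weights.sum()
    sampled = rng.choice(positions, size=spec.n_clinical, p=weights)

    rows = []
    messy_truth = []
    for i, pos in enumerate(sampled):
        value = round(float(rng.uniform(0.0, 40.0)), 1)
        row = {
            "mutation_type": "Point", "variant_effect": "Missense",
            "position_legacy": int(pos), "fviii_c_raw": f"{value}",
            "fviii_c_1st": "", "fviii_c_2st": "", "protein_change": "",
            "severity_reported": _severity_for(value),
        }
        if i < spec.n_messy:
            form = MESSY_FORMS[i % len(MESSY_FORMS)]
            if "fviii_c_raw" in form:
                row["fviii_c_raw"] = form["fviii_c_raw"]
                if form["expect"] == "range_average":
                    row["severity_reported"] = "mild"
            if "severity" in form:
                row["severity_reported"] = form["severity"]
            if "protein_change" in form:
                row["protein_change"] = form["protein_change"]
            messy_truth.append({"record_id": i, "expect": form["expect"]})
        rows.append(row)
    raw = pd.DataFrame(rows)
    truth = {
        "harmful_positions": sorted(harmful),
        "enrichment": spec.clinical_enrichment,
        "n_messy": spec.n_messy,
        "messy_records": messy_truth,
    }
    return raw, truth
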
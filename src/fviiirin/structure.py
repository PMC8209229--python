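"""Protein structure model: PDB parsing, atom classification and surface areas.

A :class:`Structure` is an ordered collection of standard amino-acid residues,
each holding its heavy atoms (and any hydrogens present in the file) with
3-D coordinates in Angstrom.  Atoms are classified as main-chain (backbone
N, CA, C, O, OXT, plus their hydrogens) or side-chain; that classification
drives the interaction typing of the residue network downstream.

Per-residue solvent-accessible surface area is computed with the
Shrake-Rupley quadrature (probe sphere rolled over van der Waals spheres,
default probe 1.4 A, 960 points per atom) and normalised to a relative
exposure by dividing by the reference area of the same residue type in an
extended Gly-X-Gly tripeptide.  The reference table ships as a versioned
CSV and can be swapped for an alternative scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# constants

MAIN_CHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}
# backbone hydrogens follow their parent heavy atom
MAIN_CHAIN_HYDROGENS = {"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT", "HN"}

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: van der Waals radii (A) used for surface quadrature, by element.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960


class StructureError(ValueError):
    """Raised for unparseable files, empty selections or invalid residues."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue: chain, author sequence number, icode, type.

    Author numbering is taken verbatim from the PDB file; for the factor
    VIII structure 2R7E it coincides with legacy mature-protein numbering.
    """

    chain_id: str
    seq_number: int
    insertion_code: str
    residue_type: str

    def label(self) -> str:
        ic = self.insertion_code.strip()
        return f"{self.chain_id}:{self.residue_type}{self.seq_number}{ic}"


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    residue_key: ResidueKey
    coords: Tuple[float, float, float]
    chain_part: str  # "main_chain" | "side_chain"
    altloc: str = ""
    occupancy: float = 1.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Structure:
    """Ordered residues of a single-model protein structure."""

    structure_id: str
    residues: "Dict[ResidueKey, List[AtomRecord]]" = field(default_factory=dict)
    domain_map: Optional[Dict[ResidueKey, str]] = None

    def __len__(self) -> int:
        return len(self.residues)

    def keys(self) -> List[ResidueKey]:
        return list(self.residues.keys())

    def heavy_atoms(self) -> List[AtomRecord]:
        return [a for atoms in self.residues.values() for a in atoms
                if not a.is_hydrogen]

    def coords_of(self, key: ResidueKey, heavy_only: bool = True) -> np.ndarray:
        atoms = self.residues[key]
        if heavy_only:
            atoms = [a for a in atoms if not a.is_hydrogen]
        return np.array([a.coords for a in atoms], dtype=float)


def classify_chain_part(atom_name: str, element: str) -> str:
    """Main-chain vs side-chain assignment for one atom name."""
    name = atom_name.strip().upper()
    if element == "H":
        return "main_chain" if name in MAIN_CHAIN_HYDROGENS else "side_chain"
    return "main_chain" if name in MAIN_CHAIN_ATOMS else "side_chain"


# ---------------------------------------------------------------------------
# loading


def load_structure(path: str | Path, chains: Optional[Sequence[str]] = None,
                   structure_id: Optional[str] = None) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Only standard amino-acid residues of the selected chains are kept; for
    multi-model files the first model is used.  Waters, glycans and other
    hetero groups are dropped (and counted in the log).  When a residue has
    alternate locations, the highest-occupancy conformer wins, ties broken
    by altloc letter order.

    Parameters
    ----------
    path:
        PDB file path.
    chains:
        Optional list of chain identifiers to keep; default all chains.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        model = next(parser.get_structure(structure_id or path.stem, str(path)).get_models())
    except StopIteration:
        raise StructureError(f"{path}: no models found")
    except Exception as exc:  # biopython names the offending line in its message
        raise StructureError(f"{path}: PDB parse error: {exc}") from exc

    wanted = set(chains) if chains else None
    residues: Dict[ResidueKey, List[AtomRecord]] = {}
    n_dropped_hetero = 0
    n_dropped_nonstd = 0

    for chain in model:
        if wanted is not None and chain.id not in wanted:
            continue
        for res in chain:
            hetflag, seq, icode = res.id
            resname = res.get_resname().strip().upper()
            if hetflag.strip():
                n_dropped_hetero += 1
                continue
            if resname not in STANDARD_AA3:
                n_dropped_nonstd += 1
                continue
            key = ResidueKey(chain.id, int(seq), icode.strip(), resname)
            if key in residues:
                raise StructureError(f"duplicate residue key {key.label()}")
            atoms: List[AtomRecord] = []
            for atom in res:
                if atom.is_disordered():
                    # deterministic altloc choice: occupancy desc, letter asc
                    children = sorted(
                        atom.child_dict.values(),
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                    )
                    atom = children[0]
                element = (atom.element or "").strip().upper()
                atoms.append(AtomRecord(
                    name=atom.get_name().strip(),
                    element=element,
                    residue_key=key,
                    coords=tuple(float(x) for x in atom.coord),
                    chain_part=classify_chain_part(atom.get_name(), element),
                    altloc=(atom.get_altloc() or "").strip(),
                    occupancy=float(atom.get_occupancy() or 1.0),
                ))
            if not any(a.chain_part == "main_chain" and not a.is_hydrogen
                       for a in atoms):
                raise StructureError(
                    f"residue {key.label()} has no main-chain heavy atom")
            residues[key] = atoms

    if n_dropped_hetero or n_dropped_nonstd:
        logger.info("load_structure(%s): dropped %d hetero/water and %d "
                    "non-standard residues", path.name, n_dropped_hetero,
                    n_dropped_nonstd)
    if not residues:
        raise StructureError(f"{path}: no protein residues in selection")
    logger.info("load_structure(%s): %d residues kept", path.name, len(residues))
    return Structure(structure_id=structure_id or path.stem, residues=residues)


# ---------------------------------------------------------------------------
# surface area (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Unit sphere quadrature points via the golden-section spiral."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * i
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def atom_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def compute_surface_area(s: Structure,
                         probe_radius: float = DEFAULT_PROBE_RADIUS,
                         sphere_points: int = DEFAULT_SPHERE_POINTS,
                         ) -> Dict[ResidueKey, float]:
    """Per-residue solvent-accessible surface area (A^2), Shrake-Rupley.

    Heavy atoms only (hydrogens excluded by convention).  Each atom's
    accessible area is the fraction of quadrature points on its expanded
    sphere (vdW + probe) not occluded by any neighbouring expanded sphere,
    times the sphere area; residue areas are sums over the residue's atoms,
    so per-residue areas are additive to the whole-structure total.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    atoms = s.heavy_atoms()
    for key, recs in s.residues.items():
        if not any(not a.is_hydrogen for a in recs):
            raise StructureError(f"residue {key.label()} has no heavy atoms")
    coords = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array([atom_radius(a.element) + probe_radius for a in atoms])
    pts = _sphere_points(sphere_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas: Dict[ResidueKey, float] = {k: 0.0 for k in s.residues}
    for i in range(len(atoms)):
        ri = radii[i]
        neigh = [j for j in tree.query_ball_point(coords[i], ri + max_r)
                 if j != i]
        test = coords[i] + ri * pts
        accessible = np.ones(len(pts), dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", test - coords[j], test - coords[j])
            accessible &= d2 >= radii[j] ** 2
        frac = accessible.sum() / len(pts)
        areas[atoms[i].residue_key] += frac * 4.0 * math.pi * ri * ri
    return areas


# ---------------------------------------------------------------------------
# relative exposure


def load_reference_areas(path: Optional[str | Path] = None) -> Dict[str, float]:
    """Load the Gly-X-Gly reference area table (3-letter code -> A^2)."""
    if path is None:
        ref = resources.files("fviiirin") / "data" / "reference_areas_gxg.csv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table: Dict[str, float] = {}
    for line in text.strip().splitlines()[1:]:
        restype, area = line.split(",")
        table[restype.strip().upper()] = float(area)
    if len(table) != 20 or any(v <= 0 for v in table.values()):
        raise ValueError("reference area table must have 20 positive entries")
    return table


def relative_exposure(areas: Mapping[ResidueKey, float],
                      ref: Mapping[str, float]) -> Dict[ResidueKey, float]:
    """Area divided by the same residue type's reference area (not clamped)."""
    out: Dict[ResidueKey, float] = {}
    for key, area in areas.items():
        if key.residue_type not in ref:
            raise KeyError(
                f"no reference area for residue type {key.residue_type!r}")
        out[key] = area / ref[key.residue_type]
    return out


def surface_table(s: Structure, areas: Mapping[ResidueKey, float],
                  rel: Mapping[ResidueKey, float]):
    """Per-residue surface CSV-ready table (pandas DataFrame)."""
    import pandas as pd

    rows = [{
        "chain": k.chain_id, "seq_number": k.seq_number,
        "icode": k.insertion_code, "restype": k.residue_type,
        "area": areas[k], "relative_exposure": rel[k],
    } for k in s.residues]
    return pd.DataFrame(rows)
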
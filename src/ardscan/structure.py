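"""Structure reading and solvent-accessible surface area (SASA).

Structures (PDB or mmCIF) are read with gemmi into flat heavy-atom records.
Per-atom SASA is computed with the Shrake–Rupley rolling-probe method on a
deterministic golden-spiral point set, so identical inputs always give
identical areas — no random sphere sampling.  Per-residue absolute SASA is
the sum over the residue's atoms; *fractional* SASA (relative solvent
accessibility) divides by a theoretical per-residue maximum (Tien et al.
2013), so ~0 means buried and values may slightly exceed 1 for highly
exposed residues in extended conformations.

Burial is context dependent: for oligomeric channels the default is to
compute SASA in the context of all chains present (e.g. the TRPV1
tetramer) and then report the chain of interest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    StructureReadError,
    UnknownResidueError,
)

logger = logging.getLogger(__name__)

#: van der Waals radii per element, Å (Bondi-style values).
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.8

#: theoretical maximum ASA per residue type, Å² (Tien et al. 2013).
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: amino-acid side-chain volumes, ml/mole (Zamyatnin). The ordering
#: Val < Met < Ile is what makes valine the "safe" missense substitution
#: for a buried methionine.
SIDE_CHAIN_VOLUME = {
    "A": 60.4, "R": 127.3, "N": 78.0, "D": 73.8, "C": 67.7,
    "Q": 93.9, "E": 85.9, "G": 43.2, "H": 98.8, "I": 107.5,
    "L": 107.5, "K": 108.5, "M": 105.1, "F": 121.2, "P": 81.0,
    "S": 60.3, "T": 76.8, "W": 143.9, "Y": 123.1, "V": 91.3,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent
    "MSE": "M", "SEC": "C",
}

DEFAULT_PROBE_RADIUS = 1.4  # Å, water
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom as deposited (author numbering)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    x: float
    y: float
    z: float
    element: str
    occupancy: float = 1.0


@dataclass(frozen=True)
class ResidueSASA:
    """Absolute (Å²) and fractional solvent accessibility of one residue."""

    chain_id: str
    residue_number: int
    residue_type: str  # one-letter
    absolute_sasa: float
    fractional_sasa: float


def read_structure(
    path,
    chains: list[str] | None = None,
    residue_range: tuple[int, int] | None = None,
) -> list[AtomRecord]:
    """Read heavy protein atoms from a PDB or mmCIF file.

    Hydrogens, waters and hetero compounds are dropped.  For alternate
    locations only the highest-occupancy conformer of each atom is kept.
    Records come back sorted by (chain, residue number).
    """
    import gemmi

    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureReadError(f"cannot read {path}: {exc}") from exc
    structure.setup_entities()
    if len(structure) == 0:
        raise StructureReadError(f"{path}: no models")
    model = structure[0]

    records: list[AtomRecord] = []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            if residue.name not in THREE_TO_ONE:
                continue  # hetero/water/non-standard
            if residue_range is not None:
                num = residue.seqid.num
                if not (residue_range[0] <= num <= residue_range[1]):
                    continue
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                records.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                        element=atom.element.name.upper(),
                        occupancy=atom.occ,
                    )
                )
    if not records:
        raise EmptySelectionError(
            f"{path}: no atoms match chains={chains} range={residue_range}"
        )
    records.sort(key=lambda a: (a.chain_id, a.residue_number))
    return records


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points via the golden-angle spiral.

    Deterministic by construction: no random state anywhere.
    """
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def atom_radii(atoms: list[AtomRecord]) -> np.ndarray:
    """Per-atom van der Waals radii; unknown elements default with a warning."""
    radii = np.empty(len(atoms))
    unknown: set[str] = set()
    for i, a in enumerate(atoms):
        r = VDW_RADII.get(a.element)
        if r is None:
            unknown.add(a.element)
            r = DEFAULT_VDW_RADIUS
        radii[i] = r
    if unknown:
        logger.warning(
            "unknown elements %s: using %.1f Å", sorted(unknown), DEFAULT_VDW_RADIUS
        )
    return radii


def shrake_rupley(
    atoms: list[AtomRecord],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å².

    Each atom's solvent-expanded sphere of radius ``r_i + probe`` is
    covered with ``n_points`` golden-spiral test points; a point counts as
    accessible if it lies outside every neighbor's expanded sphere, and

        SASA_i = 4π (r_i + probe)² × accessible_i / n_points.
    """
    if n_points < 96:
        raise ValueError(f"n_points {n_points} < 96")
    if probe_radius <= 0:
        raise ValueError(f"probe_radius {probe_radius} must be > 0")
    coords = np.array([(a.x, a.y, a.z) for a in atoms], dtype=float)
    if not np.isfinite(coords).all():
        raise DegenerateGeometryError("non-finite coordinates")
    radii = atom_radii(atoms) + probe_radius
    n = len(atoms)

    tree = cKDTree(coords)
    # neighbor pairs whose expanded spheres can intersect
    pairs = tree.query_pairs(2.0 * radii.max(), output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        if np.any(d == 0.0):
            i, j = pairs[np.nonzero(d == 0.0)[0][0]]
            raise DegenerateGeometryError(
                f"atoms {i} and {j} share coordinates {tuple(coords[i])}"
            )
        keep = d < radii[pairs[:, 0]] + radii[pairs[:, 1]]
        pairs = pairs[keep]

    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        neighbors[i].append(j)
        neighbors[j].append(i)

    unit = golden_spiral_points(n_points)
    sasa = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors[i]:
            if not accessible.any():
                break
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        sasa[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.sum() / n_points
    return sasa


def residue_sasa(
    per_atom_sasa: np.ndarray,
    atoms: list[AtomRecord],
    report_chain: str | None = None,
    max_asa: dict[str, float] = MAX_ASA,
) -> list[ResidueSASA]:
    """Sum atom SASA per residue and normalize by the reference maximum.

    ``report_chain`` restricts the report while the areas themselves keep
    the full-assembly context used in :func:`shrake_rupley`.  Fractional
    values above 1.2 are reported as-is with a warning.
    """
    if len(per_atom_sasa) != len(atoms):
        raise ValueError("per-atom SASA not aligned with atom list")
    totals: dict[tuple[str, int], float] = {}
    names: dict[tuple[str, int], str] = {}
    for area, atom in zip(per_atom_sasa, atoms):
        key = (atom.chain_id, atom.residue_number)
        totals[key] = totals.get(key, 0.0) + float(area)
        names.setdefault(key, atom.residue_name)

    out: list[ResidueSASA] = []
    for (chain, num), absolute in sorted(totals.items()):
        if report_chain is not None and chain != report_chain:
            continue
        resname = names[(chain, num)]
        one = THREE_TO_ONE.get(resname)
        if one is None or one not in max_asa:
            raise UnknownResidueError(f"{resname} at {chain}{num} not in reference table")
        frac = absolute / max_asa[one]
        if frac > 1.2:
            logger.warning(
                "fractional SASA %.2f > 1.2 at %s%d (%s)", frac, chain, num, resname
            )
        out.append(ResidueSASA(chain, num, one, absolute, frac))
    if not out:
        raise EmptySelectionError(f"report chain {report_chain!r} matched no residues")
    return out


def residue_sasa_frame(residues: list[ResidueSASA]):
    """Residue SASA as a DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            (r.chain_id, r.residue_number, r.residue_type,
             r.absolute_sasa, r.fractional_sasa)
            for r in residues
        ],
        columns=["chain", "resnum", "restype", "abs_sasa_A2", "frac_sasa"],
    )
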
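"""Structural models: PDB reading, distances, and solvent accessibility.

The container is deliberately small: an atom table (chain, residue number,
residue name, atom name, element, xyz) with numpy-backed coordinate queries.
Solvent-accessible surface area (SASA) is computed with the Shrake-Rupley
sphere-point algorithm; per-residue relative accessibility is obtained by
normalising against a bundled theoretical Gly-X-Gly maximum-area table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "StructureModel",
    "AccessibilityRecord",
    "read_structure",
    "interatomic_distance",
    "effective_distance",
    "shrake_rupley_sasa",
    "residue_sasa",
    "relative_accessibility",
    "accessibility_table",
    "VDW_RADII",
    "MAX_SASA_GLY_X_GLY",
]

# van der Waals radii (Angstrom), Bondi-style set; overridable per call.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

# Theoretical maximum SASA of residue X in an extended Gly-X-Gly tripeptide
# (Tien et al. 2013, theoretical column), Angstrom^2.
MAX_SASA_GLY_X_GLY: dict[str, float] = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}


class SelectorError(ValueError):
    """An atom selector matched zero or more than one atom."""


class RadiusError(KeyError):
    """No van der Waals radius is defined for an element."""


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]


@dataclass(frozen=True)
class AccessibilityRecord:
    chain: str
    residue_number: int
    residue_name: str
    sasa: float
    relative_sasa: float


@dataclass
class StructureModel:
    """A set of atoms with coordinate queries.

    (chain, residue_number, atom_name) is unique within a model; all
    positions must be finite.
    """

    model_id: str
    atoms: list[Atom]
    _coords: np.ndarray = field(init=False, repr=False)
    _index: dict[tuple[str, int, str], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        coords = np.array([a.position for a in self.atoms], dtype=float)
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("non-finite atom coordinates")
        self._coords = coords.reshape(-1, 3)
        self._index = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.residue_number, a.atom_name)
            if key in self._index:
                raise ValueError(f"duplicate atom {key} in model {self.model_id!r}")
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    def atom_index(self, chain: str, residue_number: int, atom_name: str) -> int:
        key = (chain, residue_number, atom_name)
        try:
            return self._index[key]
        except KeyError:
            raise SelectorError(f"no atom {key} in model {self.model_id!r}") from None

    def position(self, chain: str, residue_number: int, atom_name: str) -> np.ndarray:
        return self._coords[self.atom_index(chain, residue_number, atom_name)]

    def select(
        self,
        chain: str | None = None,
        residue_number: int | None = None,
        atom_name: str | None = None,
    ) -> list[int]:
        """Indices of atoms matching all provided criteria."""
        out = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain != chain:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if atom_name is not None and a.atom_name != atom_name:
                continue
            out.append(i)
        return out

    def residue_atoms(self, chain: str, residue_number: int) -> list[int]:
        return self.select(chain=chain, residue_number=residue_number)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def residues(self) -> list[tuple[str, int, str]]:
        """(chain, residue_number, residue_name) in order of first appearance."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.residue_number), a.residue_name)
        return [(c, n, r) for (c, n), r in seen.items()]


def write_pdb(models: StructureModel | Sequence[StructureModel], path: str | Path) -> None:
    """Write one or several models as a (multi-MODEL) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    lines: list[str] = []
    multi = len(models) > 1
    for k, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        for i, a in enumerate(model.atoms, start=1):
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            x, y, z = a.position
            lines.append(
                f"ATOM  {i:5d} {name:<4s} {a.residue_name:<3s} {a.chain[:1]}"
                f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"  1.00  0.00          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure(path: str | Path, model_index: int = 1) -> StructureModel:
    """Read one model of a PDB file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer;
    coordinates are taken verbatim (Angstrom, author chain IDs, original
    residue numbering).  ``model_index`` is the 1-based PDB MODEL number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    model = None
    for m in st:
        if m.num == model_index:
            model = m
            break
    if model is None:
        raise LookupError(f"model index {model_index} not present in {path}")
    # resolve altlocs to the highest-occupancy conformer
    best: dict[tuple[str, int, str], tuple[float, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        for res in chain:
            for at in res:
                key = (chain.name, res.seqid.num, at.name)
                atom = Atom(
                    chain=chain.name,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    atom_name=at.name,
                    element=at.element.name.upper(),
                    position=(at.pos.x, at.pos.y, at.pos.z),
                )
                if key not in best:
                    order.append(key)
                    best[key] = (at.occ, atom)
                elif at.occ > best[key][0]:
                    best[key] = (at.occ, atom)
    atoms = [best[key][1] for key in order]
    return StructureModel(model_id=f"{path.stem}#{model_index}", atoms=atoms)


def interatomic_distance(
    model: StructureModel,
    atom_a: tuple[str, int, str],
    atom_b: tuple[str, int, str],
) -> float:
    """Euclidean distance (Angstrom) between two uniquely selected atoms."""
    pa = model.position(*atom_a)
    pb = model.position(*atom_b)
    return float(np.linalg.norm(pa - pb))


def effective_distance(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> float:
    """r^-6 summed effective distance between two atom groups.

    Returns (sum over all cross pairs of d^-6)^(-1/6), the ambiguous-restraint
    distance convention: dominated by the closest pair, always <= the minimum
    pairwise distance.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        raise ValueError("effective_distance requires non-empty groups")
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    if np.any(d2 <= 0.0):
        return 0.0
    return float(np.sum(d2 ** -3.0) ** (-1.0 / 6.0))


def group_effective_distance(
    model: StructureModel,
    group_a: Sequence[int],
    group_b: Sequence[int],
) -> float:
    """:func:`effective_distance` on two index groups of one model."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("empty atom group")
    return effective_distance(model.coords[list(group_a)], model.coords[list(group_b)])


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
    include_hydrogens: bool = False,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by Shrake-Rupley sampling.

    Each atom is expanded by the probe radius and covered with ``n_points``
    quasi-uniform sphere points; the accessible fraction is the fraction of
    points outside every neighbouring expanded sphere.  Hydrogens are
    excluded by default (both as surface atoms and as occluders), following
    the heavy-atom convention of standard accessibility programs.

    Returns an array of length ``len(model)``; hydrogen entries are 0.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    radii = dict(VDW_RADII if radii is None else radii)

    mask = np.ones(len(model), dtype=bool)
    if not include_hydrogens:
        mask = np.array([a.element != "H" for a in model.atoms], dtype=bool)

    idx = np.where(mask)[0]
    out = np.zeros(len(model))
    if idx.size == 0:
        return out
    try:
        r = np.array([radii[model.atoms[i].element] for i in idx])
    except KeyError as exc:
        raise RadiusError(
            f"no van der Waals radius defined for element {exc.args[0]!r}"
        ) from None
    xyz = model.coords[idx]
    r_ext = r + probe_radius
    sphere = _fibonacci_sphere(n_points)

    # Neighbour lists via pairwise distances (desk-scale models).
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    for k in range(idx.size):
        pts = xyz[k] + r_ext[k] * sphere
        neigh = np.where((d[k] < r_ext[k] + r_ext) & (np.arange(idx.size) != k))[0]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            dj = np.linalg.norm(pts - xyz[j], axis=1)
            accessible &= dj > r_ext[j]
            if not accessible.any():
                break
        out[idx[k]] = 4.0 * math.pi * r_ext[k] ** 2 * accessible.mean()
    return out


def residue_sasa(
    model: StructureModel, atom_sasa: np.ndarray
) -> dict[tuple[str, int], float]:
    """Sum per-atom SASA into per-residue totals keyed by (chain, resnum)."""
    totals: dict[tuple[str, int], float] = {}
    for a, s in zip(model.atoms, atom_sasa):
        key = (a.chain, a.residue_number)
        totals[key] = totals.get(key, 0.0) + float(s)
    return totals


def relative_accessibility(
    sasa: float, residue_name: str, reference: Mapping[str, float] | None = None
) -> float:
    """Residue SASA divided by its theoretical Gly-X-Gly maximum."""
    table = MAX_SASA_GLY_X_GLY if reference is None else reference
    try:
        ref = table[residue_name.upper()]
    except KeyError:
        raise KeyError(
            f"no reference maximum SASA for residue type {residue_name!r}"
        ) from None
    return float(sasa) / float(ref)


def accessibility_table(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    reference: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-residue SASA and relative accessibility as a DataFrame.

    Columns: chain, resnum, resname, sasa, rel_sasa.  Residue types absent
    from the reference table get rel_sasa = NaN.
    """
    atom_areas = shrake_rupley_sasa(model, probe_radius, n_points)
    totals = residue_sasa(model, atom_areas)
    rows = []
    for chain, resnum, resname in model.residues():
        s = totals.get((chain, resnum), 0.0)
        try:
            rel = relative_accessibility(s, resname, reference)
        except KeyError:
            rel = float("nan")
        rows.append(
            {"chain": chain, "resnum": resnum, "resname": resname,
             "sasa": s, "rel_sasa": rel}
        )
    return pd.DataFrame(rows)
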
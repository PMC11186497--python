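"""Chemical-shift perturbation mapping and ambiguous interaction restraints.

The per-residue CSP is the weighted quadratic combination

    CSP = sqrt( (d_H)^2 + (0.15 * d_N)^2 )

of the 1H and 15N chemical-shift differences between free and bound
spectra.  Interface residues are classified against the mean and standard
deviation of the scored CSPs: *active* residues perturb by at least 1.5 SD
above the mean and are solvent exposed (relative accessibility above 15%);
*passive* residues perturb by at least 1 SD, or lose intensity on binding
while sitting next to an active residue.  Active residues must form a
contiguous patch: an active with no classified neighbour within the
contiguity radius is demoted to passive.

Each active residue of one molecule then defines one ambiguous interaction
restraint (AIR) to every atom of the active+passive set of the partner,
with an r^-6 effective-distance ceiling (2.0 Angstrom by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structure import StructureModel, group_effective_distance

__all__ = [
    "CSPRecord",
    "AmbiguousInteractionRestraint",
    "csp",
    "read_shift_table",
    "csp_records_from_tables",
    "classify_residues",
    "build_airs",
    "air_violation",
    "write_air_tbl",
]

DEFAULT_NITROGEN_WEIGHT = 0.15
DEFAULT_SASA_THRESHOLD = 0.15
DEFAULT_CONTIGUITY_RADIUS = 8.0
DEFAULT_AIR_DISTANCE = 2.0
ACTIVE_SD = 1.5
PASSIVE_SD = 1.0


@dataclass
class CSPRecord:
    """Per-residue shift perturbation and classification state."""

    chain: str
    residue_number: int
    delta_h: float = float("nan")
    delta_n: float = float("nan")
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT
    csp: float = float("nan")
    rel_sasa: float = float("nan")
    classification: str = "none"
    intensity_loss_flag: bool = False
    residue_name: str = ""


@dataclass(frozen=True)
class AmbiguousInteractionRestraint:
    """One active residue restrained to the partner's active+passive set."""

    active_residue: tuple[str, int]
    target_residues: frozenset[tuple[str, int]]
    max_effective_distance: float = DEFAULT_AIR_DISTANCE

    def __post_init__(self) -> None:
        if not self.target_residues:
            raise ValueError("AIR target set must be non-empty")
        if self.max_effective_distance <= 0:
            raise ValueError("AIR distance must be > 0")


def csp(delta_h: float, delta_n: float, weight: float = DEFAULT_NITROGEN_WEIGHT) -> float:
    """Weighted combined shift perturbation in ppm."""
    if weight <= 0:
        raise ValueError("nitrogen weight must be > 0")
    return math.sqrt(delta_h**2 + (weight * delta_n) ** 2)


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Read a shift table CSV: chain, resnum, delta_h_ppm, delta_n_ppm[, intensity_loss]."""
    df = pd.read_csv(path)
    required = ["chain", "resnum", "delta_h_ppm", "delta_n_ppm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"shift table {path} missing columns: {missing}")
    if "intensity_loss" not in df.columns:
        df["intensity_loss"] = 0
    return df


def csp_records_from_tables(
    free: pd.DataFrame | None,
    bound: pd.DataFrame,
    weight: float = DEFAULT_NITROGEN_WEIGHT,
) -> list[CSPRecord]:
    """Build CSP records from shift-difference tables.

    If ``free`` is given, delta columns are ``bound - free`` matched on
    (chain, resnum); otherwise ``bound`` is taken to already hold the
    differences.
    """
    if free is not None:
        merged = bound.merge(free, on=["chain", "resnum"], suffixes=("", "_free"))
        merged["delta_h_ppm"] = merged["delta_h_ppm"] - merged["delta_h_ppm_free"]
        merged["delta_n_ppm"] = merged["delta_n_ppm"] - merged["delta_n_ppm_free"]
    else:
        merged = bound
    records = []
    for _, row in merged.iterrows():
        dh, dn = float(row["delta_h_ppm"]), float(row["delta_n_ppm"])
        rec = CSPRecord(
            chain=str(row["chain"]),
            residue_number=int(row["resnum"]),
            delta_h=dh,
            delta_n=dn,
            nitrogen_weight=weight,
            intensity_loss_flag=bool(row.get("intensity_loss", 0)),
        )
        if np.isfinite(dh) and np.isfinite(dn):
            rec.csp = csp(dh, dn, weight)
        records.append(rec)
    return records


def _min_residue_distance(
    model: StructureModel, res_a: tuple[str, int], res_b: tuple[str, int]
) -> float:
    ia = model.residue_atoms(*res_a)
    ib = model.residue_atoms(*res_b)
    if not ia or not ib:
        return float("inf")
    d = np.linalg.norm(
        model.coords[ia][:, None, :] - model.coords[ib][None, :, :], axis=-1
    )
    return float(d.min())


def classify_residues(
    records: Sequence[CSPRecord],
    sasa_threshold: float = DEFAULT_SASA_THRESHOLD,
    contiguity_radius: float = DEFAULT_CONTIGUITY_RADIUS,
    model: StructureModel | None = None,
    active_sd: float = ACTIVE_SD,
    passive_sd: float = PASSIVE_SD,
) -> list[CSPRecord]:
    """Annotate records with active/passive/none classifications (in place).

    Statistics (mean, SD with n-1) are computed over residues with a finite
    CSP — unassigned residues and prolines simply carry no CSP and are
    excluded, never imputed.  Rules:

    * active: csp >= mean + active_sd * SD and rel_sasa > sasa_threshold
    * passive: csp >= mean + passive_sd * SD (and not active), or
      intensity-loss flag set with a classified active neighbour within
      ``contiguity_radius`` (requires ``model``)
    * actives with no active/passive neighbour within the radius are
      demoted to passive (contiguous-surface rule; requires ``model``)

    A zero SD (all scored CSPs identical) is degenerate: nothing is
    classified.  Needs at least 5 scored residues.
    """
    scored = [r for r in records if np.isfinite(r.csp)]
    if len(scored) < 5:
        raise ValueError("need >= 5 scored residues for classification")
    values = np.array([r.csp for r in scored])
    mean = float(values.mean())
    sd = float(values.std(ddof=1))

    for r in records:
        r.classification = "none"
    if sd == 0.0:
        return list(records)

    for r in scored:
        if r.csp >= mean + active_sd * sd and (
            np.isfinite(r.rel_sasa) and r.rel_sasa > sasa_threshold
        ):
            r.classification = "active"
        elif r.csp >= mean + passive_sd * sd:
            r.classification = "passive"

    if model is not None:
        actives = [r for r in records if r.classification == "active"]
        # intensity-loss residues near an active become passive
        for r in records:
            if r.classification == "none" and r.intensity_loss_flag:
                near = any(
                    _min_residue_distance(
                        model, (r.chain, r.residue_number), (a.chain, a.residue_number)
                    )
                    <= contiguity_radius
                    for a in actives
                )
                if near:
                    r.classification = "passive"
        # contiguous-surface rule: isolated actives demoted
        classified = [r for r in records if r.classification in ("active", "passive")]
        for r in actives:
            neighbours = [
                o for o in classified
                if (o.chain, o.residue_number) != (r.chain, r.residue_number)
            ]
            near = any(
                _min_residue_distance(
                    model, (r.chain, r.residue_number), (o.chain, o.residue_number)
                )
                <= contiguity_radius
                for o in neighbours
            )
            if not near:
                r.classification = "passive"
    return list(records)


def build_airs(
    active_a: Iterable[tuple[str, int]],
    passive_a: Iterable[tuple[str, int]],
    active_b: Iterable[tuple[str, int]],
    passive_b: Iterable[tuple[str, int]],
    max_dist: float = DEFAULT_AIR_DISTANCE,
) -> list[AmbiguousInteractionRestraint]:
    """Generate AIRs: one per active residue, targeting the partner's
    active + passive set.  The total count is |active_a| + |active_b|."""
    aa, pa = set(active_a), set(passive_a)
    ab, pb = set(active_b), set(passive_b)
    if not aa or not ab:
        raise ValueError("need >= 1 active residue on each molecule")
    airs = [
        AmbiguousInteractionRestraint(res, frozenset(ab | pb), max_dist)
        for res in sorted(aa)
    ]
    airs += [
        AmbiguousInteractionRestraint(res, frozenset(aa | pa), max_dist)
        for res in sorted(ab)
    ]
    return airs


def air_violation(
    restraint: AmbiguousInteractionRestraint, model: StructureModel
) -> float:
    """Violation (Angstrom) of one AIR in a model: max(0, d_eff - d_max)."""
    ia = model.residue_atoms(*restraint.active_residue)
    ib: list[int] = []
    for res in restraint.target_residues:
        ib.extend(model.residue_atoms(*res))
    if not ia or not ib:
        raise KeyError(f"AIR residues missing from model: {restraint.active_residue}")
    d = group_effective_distance(model, ia, ib)
    return max(0.0, d - restraint.max_effective_distance)


def write_air_tbl(
    airs: Sequence[AmbiguousInteractionRestraint], path: str | Path
) -> None:
    """Write AIRs as docking-style ambiguous assign statements.

    Encoding: ``assign (active) (target1 or target2 or ...) d d 0.0`` with
    d the maximum effective distance (upper-bound-only, lower bound 0).
    """
    lines = ["! ambiguous interaction restraints"]
    for air in airs:
        chain, resnum = air.active_residue
        sel_a = f"(segid {chain} and resid {resnum})"
        targets = " or ".join(
            f"(segid {c} and resid {n})" for c, n in sorted(air.target_residues)
        )
        d = air.max_effective_distance
        lines.append(f"assign {sel_a} ({targets}) {d:.1f} {d:.1f} 0.0")
    Path(path).write_text("\n".join(lines) + "\n")
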
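"""Build, filter, validate and serialize PRE-derived docking restraints.

PRE rates are converted to electron-nucleus distances with the simplified
SBMF rate law and written as upper-bound-only restraints between proxy
atoms: the amide nitrogen (or methyl carbon) of the probe and the C-beta of
the spin-label attachment residue.  Only intensity ratios below a cutoff
(default 0.8) carry usable distance information; an empirical padding
(default 6 Angstrom) is added to the derived distance to absorb tag-length
and quantification errors, and no lower bound is applied because partial
saturation can only lengthen the apparent distance.

To avoid contamination by a transient encounter complex, restraints that
are already satisfiable in any member of an encounter-complex ensemble are
eliminated before docking.  Connectivity restraints (inter-domain linker,
phosphopantetheine-arm unfurling and active-site reach) are emitted with
fixed bounds.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pre_extraction import PREMeasurement, STATUS_QUANTIFIED, STATUS_BLEACHED
from .sbmf import SBMFParameters, distance_from_gamma2
from .structure import StructureModel, interatomic_distance

__all__ = [
    "DistanceRestraint",
    "ProxyMapping",
    "build_pre_restraints",
    "filter_encounter_satisfiable",
    "add_connectivity_restraints",
    "check_violations",
    "write_restraints",
    "read_restraints_tbl",
    "DEFAULT_RATIO_CUTOFF",
    "DEFAULT_PADDING",
    "LINKER_MAX",
    "PPANT_UNFURL_BOUNDS",
    "PPANT_ACTIVE_SITE_MAX",
]

logger = logging.getLogger(__name__)

DEFAULT_RATIO_CUTOFF = 0.8
DEFAULT_PADDING = 6.0

# Connectivity restraint bounds (Angstrom):
LINKER_MAX = 59.5             # Calpha(C-term of N domain) - Calpha(N-term of partner domain)
PPANT_UNFURL_BOUNDS = (14.0, 16.5)   # ppant thiol S - phosphate P
PPANT_ACTIVE_SITE_MAX = 8.0   # ppant thiol S - catalytic His CE1

STATUS_RETAINED = "retained"
STATUS_ELIMINATED = "eliminated_encounter"
STATUS_FILTERED = "filtered_ratio"


@dataclass
class DistanceRestraint:
    """An atom-pair distance restraint with provenance."""

    atom_a: tuple[str, int, str]
    atom_b: tuple[str, int, str]
    upper_bound: float
    lower_bound: float = 0.0
    derived_distance: float = float("nan")
    padding: float = 0.0
    source: str = "pre"
    tag_site: str = ""
    status: str = STATUS_RETAINED

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError("lower_bound must be <= upper_bound")


@dataclass(frozen=True)
class ProxyMapping:
    """Maps PRE probes and tag sites onto restraint proxy atoms.

    ``tag_attachments`` maps a tag-site label (e.g. "A36C") to the
    (chain, residue_number) of the engineered cysteine; its C-beta is the
    paramagnetic-centre proxy.  Probe atoms map to the amide nitrogen for
    amide probes and to the methyl carbon for methyl probes; additional
    explicit entries can be supplied in ``probe_atoms``.
    """

    tag_attachments: Mapping[str, tuple[str, int]]
    probe_atoms: Mapping[str, str] = field(default_factory=dict)

    _AMIDE = {"N", "H", "HN"}

    def tag_atom(self, tag_site: str) -> tuple[str, int, str]:
        try:
            chain, resnum = self.tag_attachments[tag_site]
        except KeyError:
            raise KeyError(f"unknown tag site {tag_site!r}") from None
        return (chain, resnum, "CB")

    def probe_atom(self, probe_id: tuple[str, int, str]) -> tuple[str, int, str]:
        chain, resnum, name = probe_id
        if name in self.probe_atoms:
            return (chain, resnum, self.probe_atoms[name])
        if name.upper() in self._AMIDE:
            return (chain, resnum, "N")
        if name.upper().startswith("C"):
            return (chain, resnum, name.upper())
        raise KeyError(f"cannot map probe atom {name!r} of {probe_id}")


def build_pre_restraints(
    measurements: Sequence[PREMeasurement],
    params: SBMFParameters,
    mapping: ProxyMapping,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
    padding: float = DEFAULT_PADDING,
) -> tuple[list[DistanceRestraint], int]:
    """Convert quantified PREs into upper-bound distance restraints.

    Measurements with intensity ratio >= ``ratio_cutoff`` are kept in the
    output with status ``filtered_ratio`` (no usable distance); bleached
    measurements are excluded entirely and counted.  Returns (restraints,
    n_bleached).
    """
    logger.info(
        "building PRE restraints: ratio_cutoff=%.3g padding=%.3g A", ratio_cutoff, padding
    )
    out: list[DistanceRestraint] = []
    n_bleached = 0
    for m in measurements:
        if m.status == STATUS_BLEACHED:
            n_bleached += 1
            continue
        ratio = m.intensity_ratio if np.isfinite(m.i_para) else m.volume_ratio
        atom_a = mapping.probe_atom(m.probe_id)
        atom_b = mapping.tag_atom(m.tag_site)
        if not (ratio < ratio_cutoff) or not (m.gamma2_h > 0):
            out.append(
                DistanceRestraint(
                    atom_a=atom_a, atom_b=atom_b,
                    upper_bound=float("inf"), lower_bound=0.0,
                    padding=padding, source="pre", tag_site=m.tag_site,
                    status=STATUS_FILTERED,
                )
            )
            continue
        r = distance_from_gamma2(m.gamma2_h, params)
        out.append(
            DistanceRestraint(
                atom_a=atom_a, atom_b=atom_b,
                upper_bound=r + padding, lower_bound=0.0,
                derived_distance=r, padding=padding,
                source="pre", tag_site=m.tag_site, status=STATUS_RETAINED,
            )
        )
    if n_bleached:
        logger.info("excluded %d bleached measurements", n_bleached)
    return out, n_bleached


def filter_encounter_satisfiable(
    restraints: Sequence[DistanceRestraint],
    encounter_ensemble: Sequence[StructureModel],
) -> tuple[list[DistanceRestraint], list[DistanceRestraint]]:
    """Eliminate restraints satisfiable in the encounter-complex ensemble.

    A restraint is eliminated iff its atom-pair distance is <= its upper
    bound in ANY ensemble member (a restraint an encounter pose can already
    satisfy carries no information about the final complex).  Returns
    (retained, eliminated); statuses are updated in place and
    len(retained) + len(eliminated) equals the number of retained-status
    inputs.
    """
    if len(encounter_ensemble) == 0:
        raise ValueError("encounter ensemble must be non-empty")
    retained: list[DistanceRestraint] = []
    eliminated: list[DistanceRestraint] = []
    for r in restraints:
        if r.status != STATUS_RETAINED:
            continue
        satisfiable = False
        for model in encounter_ensemble:
            d = interatomic_distance(model, r.atom_a, r.atom_b)
            if d <= r.upper_bound:
                satisfiable = True
                break
        if satisfiable:
            r.status = STATUS_ELIMINATED
            eliminated.append(r)
        else:
            retained.append(r)
    logger.info(
        "encounter filter: %d of %d eliminated, %d retained",
        len(eliminated), len(eliminated) + len(retained), len(retained),
    )
    return retained, eliminated


def add_connectivity_restraints(
    linker_ca_a: tuple[str, int, str],
    linker_ca_b: tuple[str, int, str],
    thiol_s: tuple[str, int, str],
    phosphate_p: tuple[str, int, str],
    his_ce1: tuple[str, int, str],
    model: StructureModel | None = None,
) -> list[DistanceRestraint]:
    """Emit the three fixed connectivity restraints.

    * inter-domain linker: Calpha-Calpha upper bound 59.5 A (no lower bound)
    * ppant-arm unfurling: thiol S to phosphate P bounded to 14.0-16.5 A
    * active-site reach: thiol S to the catalytic His CE1, upper bound 8.0 A

    If ``model`` is given, all named atoms are checked to exist.
    """
    if model is not None:
        for atom in (linker_ca_a, linker_ca_b, thiol_s, phosphate_p, his_ce1):
            model.atom_index(*atom)  # raises SelectorError if absent
    return [
        DistanceRestraint(
            atom_a=linker_ca_a, atom_b=linker_ca_b,
            upper_bound=LINKER_MAX, lower_bound=0.0, source="linker",
        ),
        DistanceRestraint(
            atom_a=thiol_s, atom_b=phosphate_p,
            upper_bound=PPANT_UNFURL_BOUNDS[1], lower_bound=PPANT_UNFURL_BOUNDS[0],
            source="ppant_unfurl",
        ),
        DistanceRestraint(
            atom_a=thiol_s, atom_b=his_ce1,
            upper_bound=PPANT_ACTIVE_SITE_MAX, lower_bound=0.0,
            source="ppant_active_site",
        ),
    ]


def check_violations(
    restraints: Sequence[DistanceRestraint], model: StructureModel
) -> pd.DataFrame:
    """Evaluate each restraint against a model.

    Returns a DataFrame with the model distance and the violation
    ``max(0, d - upper, lower - d)`` per restraint; atoms missing from the
    model leave NaN entries and a warning.
    """
    rows = []
    for r in restraints:
        try:
            d = interatomic_distance(model, r.atom_a, r.atom_b)
            viol = max(0.0, d - r.upper_bound, r.lower_bound - d)
        except Exception:
            logger.warning("restraint atoms unresolvable in %s: %s %s",
                           model.model_id, r.atom_a, r.atom_b)
            d, viol = float("nan"), float("nan")
        rows.append(
            {
                "atom_a": "/".join(map(str, r.atom_a)),
                "atom_b": "/".join(map(str, r.atom_b)),
                "source": r.source,
                "lower": r.lower_bound,
                "upper": r.upper_bound,
                "distance": d,
                "violation": viol,
            }
        )
    return pd.DataFrame(rows)


def _tbl_selection(atom: tuple[str, int, str]) -> str:
    chain, resnum, name = atom
    return f"(segid {chain} and resid {resnum} and name {name})"


def write_restraints(
    restraints: Sequence[DistanceRestraint],
    path: str | Path,
    dialect: str = "cns_tbl",
) -> None:
    """Serialize restraints.

    ``cns_tbl`` writes one assign statement per restraint as
    ``assign (sel_a) (sel_b) d dminus dplus`` with d = upper bound,
    dminus = upper - lower and dplus = 0: an exact, reversible encoding of
    upper-bound-only (and two-sided) restraints.  ``json`` keeps full
    provenance.  Restraints without a finite upper bound (ratio-filtered)
    are skipped.
    """
    path = Path(path)
    usable = [r for r in restraints if np.isfinite(r.upper_bound)]
    if dialect == "cns_tbl":
        lines = [
            "! distance restraints: assign (a) (b) d dminus dplus",
            "! convention: d = upper bound, dminus = d - lower bound, dplus = 0",
        ]
        for r in usable:
            lines.append(
                f"assign {_tbl_selection(r.atom_a)} {_tbl_selection(r.atom_b)} "
                f"{r.upper_bound:.3f} {r.upper_bound - r.lower_bound:.3f} 0.000"
            )
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "json":
        payload = [asdict(r) for r in usable]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown restraint dialect {dialect!r}")


_ASSIGN_RE = re.compile(
    r"assign\s+\(segid\s+(\S+)\s+and\s+resid\s+(\d+)\s+and\s+name\s+(\S+)\)\s+"
    r"\(segid\s+(\S+)\s+and\s+resid\s+(\d+)\s+and\s+name\s+(\S+)\)\s+"
    r"([\d.eE+-]+)\s+([\d.eE+-]+)\s+([\d.eE+-]+)"
)


def read_restraints_tbl(path: str | Path) -> list[DistanceRestraint]:
    """Read back restraints written by :func:`write_restraints` (cns_tbl)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        m = _ASSIGN_RE.match(line)
        if not m:
            raise ValueError(f"unparseable assign statement: {line!r}")
        c1, n1, a1, c2, n2, a2, d, dminus, dplus = m.groups()
        d, dminus, dplus = float(d), float(dminus), float(dplus)
        out.append(
            DistanceRestraint(
                atom_a=(c1, int(n1), a1),
                atom_b=(c2, int(n2), a2),
                upper_bound=d + dplus,
                lower_bound=d - dminus,
                source="pre",
            )
        )
    return out
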
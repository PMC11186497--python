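"""Small planning calculators: NUS effective sparsity and formula masses.

*NUS sparsity.*  When the indirect spectral widths are oversampled by a
factor k per dimension, the underlying Nyquist grid holds k^n times more
hypercomplex points than the non-oversampled grid with the same maximum
evolution times, so the nominal sparsity understates the effective sampling
density by that factor: effective = nominal * k^n, and the per-dimension
sampling fraction is effective^(1/n).

*Masses.*  Nominal (integer, most-abundant-isotope) and monoisotopic masses
of small-molecule formulas, with an amide-condensation helper (element-wise
sum minus lost waters) for checking reaction products in MS data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "NUSPlan",
    "MolecularFormula",
    "effective_nus_sparsity",
    "parse_formula",
    "formula_mass",
    "condensation_product_formula",
    "WATER",
]

# (nominal integer mass, monoisotopic mass in Da) of the most abundant isotope
ISOTOPE_TABLE: dict[str, tuple[int, float]] = {
    "H": (1, 1.0078250319),
    "C": (12, 12.0),
    "N": (14, 14.0030740052),
    "O": (16, 15.9949146221),
    "P": (31, 30.97376151),
    "S": (32, 31.97207069),
    "F": (19, 18.9984032),
    "CL": (35, 34.96885271),
    "BR": (79, 78.9183376),
    "I": (127, 126.904468),
    "NA": (23, 22.98976928),
    "K": (39, 38.9637064),
}


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class NUSPlan:
    """Nonuniform-sampling plan with oversampling-corrected sparsity."""

    nominal_sparsity: float
    n_indirect_dims: int
    oversampling_factor: int
    effective_sparsity: float
    per_dimension_fraction: float

    @property
    def effective_percent(self) -> float:
        """Effective sparsity in percent, rounded to 2 significant figures."""
        return _round_sig(self.effective_sparsity * 100.0, 2)

    @property
    def per_dimension_percent(self) -> int:
        """Per-dimension sampling fraction as an integer percent."""
        return round(self.per_dimension_fraction * 100.0)


def effective_nus_sparsity(
    nominal: float, n_dims: int, oversampling: int = 2
) -> NUSPlan:
    """Effective NUS sparsity after per-dimension oversampling.

    ``nominal`` is the fraction of the oversampled Nyquist grid actually
    acquired; the effective sparsity relative to the non-oversampled grid is
    nominal * oversampling^n_dims, e.g. 0.55% * 2^3 = 4.4% (35% per
    indirect dimension).
    """
    if not (0.0 < nominal <= 1.0):
        raise ValueError("nominal sparsity must lie in (0, 1]")
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    effective = nominal * oversampling**n_dims
    if effective > 1.0:
        raise ValueError("effective sparsity exceeds 1; check the inputs")
    return NUSPlan(
        nominal_sparsity=nominal,
        n_indirect_dims=n_dims,
        oversampling_factor=oversampling,
        effective_sparsity=effective,
        per_dimension_fraction=effective ** (1.0 / n_dims),
    )


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts with nominal and monoisotopic masses."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative element count for {el}")
            if el.upper() not in ISOTOPE_TABLE:
                raise KeyError(f"unknown element {el!r} in formula")

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __str__(self) -> str:
        order = ["C", "H"] + sorted(k for k in self.counts if k not in ("C", "H"))
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
            for el in order
            if self.counts.get(el, 0) > 0
        )

    @property
    def nominal_mass(self) -> int:
        return sum(ISOTOPE_TABLE[el.upper()][0] * n for el, n in self.counts.items())

    @property
    def monoisotopic_mass(self) -> float:
        return sum(ISOTOPE_TABLE[el.upper()][1] * n for el, n in self.counts.items())


WATER = MolecularFormula({"H": 2, "O": 1})

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string like ``C13H12N2O2``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text) or not counts:
        raise ValueError(f"cannot parse formula {text!r}")
    return MolecularFormula(counts)


def formula_mass(
    formula: MolecularFormula | str, protonated: bool = False
) -> tuple[int, float]:
    """(nominal, monoisotopic) mass in Da; ``protonated`` adds one hydrogen
    (the M+H / M+ channel seen in positive-mode LC-MS)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if protonated:
        formula = formula + MolecularFormula({"H": 1})
    return formula.nominal_mass, formula.monoisotopic_mass


def condensation_product_formula(
    a: MolecularFormula | str, b: MolecularFormula | str, waters_lost: int = 2
) -> MolecularFormula:
    """Formula of a condensation product: a + b minus ``waters_lost`` waters.

    An amide condensation releases one water; a subsequent intramolecular
    ring closure releases a second.
    """
    if isinstance(a, str):
        a = parse_formula(a)
    if isinstance(b, str):
        b = parse_formula(b)
    total = dict((a + b).counts)
    for el, n in WATER.counts.items():
        total[el] = total.get(el, 0) - n * waters_lost
        if total[el] < 0:
            raise ValueError(
                f"condensation would leave a negative {el} count"
            )
    return MolecularFormula({el: n for el, n in total.items() if n > 0})
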
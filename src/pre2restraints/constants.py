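"""Physical constants for paramagnetic relaxation enhancement calculations.

The central quantity is the dipolar PRE prefactor

    kappa_H = (gamma_H * g_e * beta)^2 * (mu0/4pi)^2 * S(S+1)/15

which converts an electron-nucleus distance r (in the r^-6 sense) into a
transverse PRE rate.  The PRE restraint literature conventionally evaluates
this prefactor with the spin-only electron g-factor g = 2 (giving the classic
1.23e-32 cm^6 s^-2 = 1.2311e16 A^6 s^-2 for 1H and a nitroxide S = 1/2);
that convention is the default here.  A CODATA-2018 constant set (with the
free-electron g-factor 2.00231930436256, ~0.23% larger in kappa) is available
through :meth:`PhysicalConstants.codata2018` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

# CODATA 2018 values
GAMMA_H = 2.6752218744e8
"""1H gyromagnetic ratio, rad s^-1 T^-1."""

GAMMA_C = 6.728284e7
"""13C gyromagnetic ratio, rad s^-1 T^-1."""

G_E_CODATA = 2.00231930436256
"""Free-electron g-factor magnitude (CODATA 2018)."""

G_E_SPIN_ONLY = 2.0
"""Spin-only electron g-factor, the conventional choice for PRE prefactors."""

BOHR_MAGNETON = 9.2740100783e-24
"""Bohr magneton, J T^-1."""

MU0_OVER_4PI = 1e-7
"""mu0 / 4pi, T^2 m^3 J^-1."""

M6_TO_A6 = 1e60
"""Conversion factor m^6 -> Angstrom^6."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of physical constants entering the PRE equations.

    kappa_H is always derived from these fields (see :meth:`kappa_h`),
    never stored independently.
    """

    gamma_h: float = GAMMA_H
    gamma_c: float = GAMMA_C
    g_e: float = G_E_SPIN_ONLY
    beta: float = BOHR_MAGNETON
    mu0_over_4pi: float = MU0_OVER_4PI
    spin_s: float = 0.5

    @classmethod
    def codata2018(cls) -> "PhysicalConstants":
        """Constant set using the CODATA free-electron g-factor."""
        return cls(g_e=G_E_CODATA)

    def with_gamma(self, gamma: float) -> "PhysicalConstants":
        """Same constants but with the nuclear gyromagnetic ratio replaced."""
        return replace(self, gamma_h=gamma)

    def kappa_h(self, in_si: bool = False) -> float:
        """Dipolar PRE prefactor kappa_H.

        Parameters
        ----------
        in_si:
            If True return m^6 s^-2; otherwise Angstrom^6 s^-2 (default).
        """
        s = self.spin_s
        kappa_si = (
            (self.gamma_h * self.g_e * self.beta) ** 2
            * self.mu0_over_4pi**2
            * s * (s + 1.0) / 15.0
        )
        return kappa_si if in_si else kappa_si * M6_TO_A6

    def mq_pre_factor(self) -> float:
        """Multiple-quantum PRE scaling factor 1 + (gamma_C/gamma_H)^2.

        The 1H/13C multiple-quantum coherence present during the indirect
        evolution of a methyl HMQC relaxes with the summed proton and carbon
        PREs; under the assumption of identical electron-nucleus geometry
        and dominance of the zero-frequency spectral density this reduces to
        Gamma2(MQ) = [1 + (gamma_C/gamma_H)^2] * Gamma2(H) ~= 1.063 Gamma2(H).
        """
        return 1.0 + (self.gamma_c / self.gamma_h) ** 2


def kappa_h(constants: PhysicalConstants | None = None, in_si: bool = False) -> float:
    """Module-level convenience wrapper for :meth:`PhysicalConstants.kappa_h`."""
    return (constants or PhysicalConstants()).kappa_h(in_si=in_si)


def mq_pre_factor(constants: PhysicalConstants | None = None) -> float:
    """Module-level convenience wrapper for :meth:`PhysicalConstants.mq_pre_factor`."""
    return (constants or PhysicalConstants()).mq_pre_factor()
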
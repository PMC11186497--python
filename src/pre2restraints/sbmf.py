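"""Solomon-Bloembergen model-free (SBMF) machinery.

Connects transverse 1H PREs to electron-nucleus distances through

    Gamma2_H = kappa_H / r^6 * [4 J(0) + 3 J(omega_H)]

with the model-free spectral density

    J(omega) = S^2 tau1 / (1 + omega^2 tau1^2)
             + (1 - S^2) taut / (1 + omega^2 taut^2)

where tau1 combines global tumbling and longitudinal electron relaxation
(1/tau1 = 1/tau_m + 1/T1e) and taut additionally folds in the internal
motion of the electron-nucleus vector (1/taut = 1/tau1 + 1/tau_i).  When
internal motion is fast and S^2 is not too small the second term is
negligible, leaving the simplified form used for restraint generation:

    Gamma2_H = kappa_H / r^6 * S^2 tau1 * (4 + 3 / (1 + omega_H^2 tau1^2))

Back-calculation from a structure averages r^-6 over a nitroxide-tag
conformer ensemble, and the electron-nucleus correlation time can be fitted
to measured PREs by bounded 1-D weighted least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import PhysicalConstants
from .pre_extraction import PREMeasurement, STATUS_QUANTIFIED
from .structure import StructureModel

__all__ = [
    "SBMFParameters",
    "TagSite",
    "j_sbmf",
    "gamma2_from_distance",
    "distance_from_gamma2",
    "ensemble_r6_distance",
    "back_calculate_pre_profile",
    "fit_correlation_time",
    "default_tag_conformers",
]


@dataclass(frozen=True)
class SBMFParameters:
    """Spectral-density parameters of the SBMF model.

    tau1 is the electron-nucleus correlation time (s) combining global
    rotational diffusion and electronic T1 relaxation; tau_i the internal
    tag-motion correlation time; s2 the squared order parameter of that
    motion.  The restraint-generation defaults are S^2 = 1 and
    tau1 = 20 ns at an 850 MHz 1H frequency.
    """

    tau_1: float = 20e-9
    tau_i: float = float("inf")
    s2: float = 1.0
    field_mhz: float = 850.0
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        if self.tau_1 <= 0 or self.tau_i <= 0:
            raise ValueError("correlation times must be > 0")
        if not (0.0 <= self.s2 <= 1.0):
            raise ValueError("s2 must lie in [0, 1]")

    @classmethod
    def from_tumbling(
        cls, tau_m: float, t1e: float = float("inf"), **kw
    ) -> "SBMFParameters":
        """Build tau1 from the tumbling time and electronic T1."""
        tau_1 = 1.0 / (1.0 / tau_m + (0.0 if math.isinf(t1e) else 1.0 / t1e))
        return cls(tau_1=tau_1, **kw)

    @property
    def tau_t(self) -> float:
        """Combined internal correlation time: 1/taut = 1/tau1 + 1/tau_i."""
        if math.isinf(self.tau_i):
            return self.tau_1
        return 1.0 / (1.0 / self.tau_1 + 1.0 / self.tau_i)

    @property
    def omega_h(self) -> float:
        return 2.0 * math.pi * self.field_mhz * 1e6

    def with_tau1(self, tau_1: float) -> "SBMFParameters":
        return replace(self, tau_1=tau_1)


@dataclass(frozen=True)
class TagSite:
    """A nitroxide spin-label site: attachment atom plus conformer cloud."""

    site_id: str
    attachment: tuple[str, int, str]
    conformers: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.conformers) < 1:
            raise ValueError("a tag site needs >= 1 conformer")

    @property
    def positions(self) -> np.ndarray:
        return np.asarray(self.conformers, dtype=float).reshape(-1, 3)


def j_sbmf(omega: float, params: SBMFParameters) -> float:
    """Model-free spectral density J(omega), in seconds."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    t1, tt, s2 = params.tau_1, params.tau_t, params.s2
    return s2 * t1 / (1.0 + omega**2 * t1**2) + (1.0 - s2) * tt / (
        1.0 + omega**2 * tt**2
    )


def _rate_factor(params: SBMFParameters) -> float:
    """S^2 tau1 (4 + 3/(1 + omega^2 tau1^2)) of the simplified rate law."""
    wt = params.omega_h * params.tau_1
    return params.s2 * params.tau_1 * (4.0 + 3.0 / (1.0 + wt * wt))


def gamma2_from_distance(
    r_en: float, params: SBMFParameters, kappa: float | None = None
) -> float:
    """Transverse 1H PRE (s^-1) at electron-nucleus distance r_en (Angstrom)."""
    if r_en <= 0:
        raise ValueError("r_en must be > 0")
    k = params.constants.kappa_h() if kappa is None else kappa
    return k / r_en**6 * _rate_factor(params)


def distance_from_gamma2(
    gamma2: float, params: SBMFParameters, kappa: float | None = None
) -> float:
    """Electron-nucleus distance (Angstrom) for a transverse PRE (s^-1)."""
    if gamma2 <= 0:
        raise ValueError("gamma2 must be > 0 to define a distance")
    k = params.constants.kappa_h() if kappa is None else kappa
    return (k * _rate_factor(params) / gamma2) ** (1.0 / 6.0)


def ensemble_r6_distance(tag: TagSite, position: np.ndarray) -> float:
    """Effective distance <r^-6>^(-1/6) from a tag conformer cloud to a point."""
    d = np.linalg.norm(tag.positions - np.asarray(position, float), axis=1)
    if np.any(d <= 0):
        raise ValueError("probe coincides with a tag conformer")
    return float(np.mean(d**-6.0) ** (-1.0 / 6.0))


def default_tag_conformers(
    model: StructureModel,
    attachment: tuple[str, int, str],
    n_conformers: int = 10,
    offset: float = 3.5,
    radius: float = 2.0,
    seed: int = 0,
) -> tuple[tuple[float, float, float], ...]:
    """Generate a fixed conformer cloud for a spin label.

    Points are sampled uniformly on a sphere of the given radius centred
    ``offset`` Angstrom outward from the attachment C-beta along the
    Calpha -> Cbeta direction, approximating the reach of a nitroxide tag
    without a force-field ensemble.
    """
    chain, resnum, _ = attachment
    cb = model.position(chain, resnum, "CB")
    ca = model.position(chain, resnum, "CA")
    u = cb - ca
    u = u / np.linalg.norm(u)
    centre = cb + offset * u
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_conformers, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = centre + radius * v
    return tuple(map(tuple, pts.tolist()))


def back_calculate_pre_profile(
    model: StructureModel,
    tag: TagSite,
    probes: Sequence[tuple[str, int, str]],
    params: SBMFParameters,
    kappa: float | None = None,
) -> tuple[list[float], list[tuple[str, int, str]]]:
    """Predict Gamma2_H for each probe atom from a structure and tag ensemble.

    Ensemble averaging is over r^-6 (the PRE-relevant average), so a probe's
    rate is kappa * <r^-6> * S^2 tau1 (4 + 3/(1+w^2 t^2)).  Returns the rates
    (NaN for probes missing from the model) and the list of skipped probes.
    """
    k = params.constants.kappa_h() if kappa is None else kappa
    factor = _rate_factor(params)
    rates: list[float] = []
    skipped: list[tuple[str, int, str]] = []
    for probe in probes:
        try:
            pos = model.position(*probe)
        except Exception:
            skipped.append(probe)
            rates.append(float("nan"))
            continue
        d = np.linalg.norm(tag.positions - pos, axis=1)
        rates.append(k * float(np.mean(d**-6.0)) * factor)
    return rates, skipped


def fit_correlation_time(
    measurements: Sequence[PREMeasurement],
    model: StructureModel,
    tag: TagSite,
    params: SBMFParameters,
    bounds: tuple[float, float] = (5e-9, 40e-9),
    n_bootstrap: int = 500,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Fit the electron-nucleus correlation time tau1 to measured PREs.

    Weighted least squares of measured vs back-calculated Gamma2 over tau1
    within ``bounds`` (default 5-40 ns); weights are 1/sigma^2 when
    measurement uncertainties are available, else uniform.  The uncertainty
    of the fitted tau1 is estimated by a nonparametric bootstrap over probes.

    Returns (tau1_hat, tau1_stderr, residual).
    """
    quantified = [
        m for m in measurements
        if m.status == STATUS_QUANTIFIED and np.isfinite(m.gamma2_h)
    ]
    if len(quantified) < 5:
        raise ValueError("need >= 5 quantified measurements to fit tau1")
    probes = [m.probe_id for m in quantified]
    meas = np.array([m.gamma2_h for m in quantified])
    errs = np.array([m.gamma2_err for m in quantified])
    w = np.where(np.isfinite(errs) & (errs > 0), errs, np.nan)
    weights = 1.0 / w**2 if np.isfinite(w).all() else np.ones_like(meas)

    # distance part is tau-independent: precompute kappa*<r^-6> per probe
    base = params.with_tau1(bounds[0])
    k = params.constants.kappa_h()
    r6 = np.empty(len(probes))
    for i, probe in enumerate(probes):
        pos = model.position(*probe)
        d = np.linalg.norm(tag.positions - pos, axis=1)
        r6[i] = float(np.mean(d**-6.0))
    del base

    def objective(tau: float, idx: np.ndarray) -> float:
        pred = k * r6[idx] * _rate_factor(params.with_tau1(tau))
        return float(np.sum(weights[idx] * (meas[idx] - pred) ** 2))

    def fit(idx: np.ndarray) -> float:
        res = minimize_scalar(
            objective, bounds=bounds, args=(idx,), method="bounded",
            options={"xatol": 1e-13},
        )
        return float(min(max(res.x, bounds[0]), bounds[1]))

    all_idx = np.arange(len(probes))
    tau_hat = fit(all_idx)
    residual = objective(tau_hat, all_idx)

    rng = np.random.default_rng(seed)
    if n_bootstrap > 0:
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, len(probes), size=len(probes))
            boots[b] = fit(idx)
        stderr = float(np.std(boots, ddof=1))
    else:
        stderr = float("nan")
    return tau_hat, stderr, residual
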
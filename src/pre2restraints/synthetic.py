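"""Ground-truth synthetic fixtures for every pipeline stage.

The generator builds toy two-domain complexes from ideal poly-alanine
helices (N, CA, CB atoms only), attaches nitroxide-tag conformer clouds,
and forward-simulates the observables the pipeline consumes:

* PRE peak tables — per probe, the electron-nucleus effective distance is
  taken from the structure (r^-6 ensemble average over tag conformers),
  converted to a rate with the simplified SBMF law, then to a peak height
  ratio through the methyl-HMQC lineshape expression (or a plain
  exponential for the volume protocol); multiplicative Gaussian noise
  emulates peak-height error behaviour.
* CSP tables — a planted interface perturbs shifts with an amplitude that
  decays exponentially with distance from the partner surface.
* relaxation decay series — mono-exponential decays over the standard
  delay list.

All randomness flows from explicit integer seeds through named generators;
a fixed seed reproduces every output byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pre_extraction import AcquisitionSettings, PEAK_TABLE_COLUMNS, forward_height_ratio
from .sbmf import SBMFParameters, TagSite, ensemble_r6_distance, gamma2_from_distance
from .structure import Atom, StructureModel

__all__ = [
    "SyntheticTruth",
    "make_toy_complex",
    "attach_tag",
    "simulate_pre_dataset",
    "simulate_csp_dataset",
    "simulate_decay_series",
    "DEFAULT_DECAY_DELAYS",
]

# standard relaxation-delay list for 1H R2 decay measurements (s)
DEFAULT_DECAY_DELAYS: tuple[float, ...] = (
    0.0, 2e-3, 5e-3, 10e-3, 15e-3, 20e-3, 30e-3, 40e-3
)

# ideal alpha-helix geometry (Angstrom / degrees)
_HELIX_RISE = 1.5
_HELIX_TWIST = 100.0
_CA_RADIUS = 2.3
_N_RADIUS = 1.6
_N_PHASE = -26.0
_N_Z = -0.9
_CB_RADIUS = 3.3
_INTERFACE_CUTOFF = 8.0
_CLASH_CUTOFF = 2.0


@dataclass
class SyntheticTruth:
    """Everything a recovery test needs to score a pipeline run."""

    complex_model: StructureModel
    free_models: dict[str, StructureModel]
    tag_sites: list[TagSite] = field(default_factory=list)
    true_tau1: float = 20e-9
    true_distances: dict[tuple[str, str, int, str], float] = field(default_factory=dict)
    true_gamma2: dict[tuple[str, str, int, str], float] = field(default_factory=dict)
    planted_interface: dict[str, set[int]] = field(default_factory=dict)
    seed: int = 0


def _helix_chain(
    chain: str, n_residues: int, origin: np.ndarray, axis: str = "z"
) -> list[Atom]:
    # axis="x" rotates the helix long axis from z onto x (rotation about y)
    rot = np.eye(3)
    if axis == "x":
        rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
    atoms: list[Atom] = []
    for i in range(n_residues):
        ang = math.radians(_HELIX_TWIST * i)
        ca = np.array(
            [_CA_RADIUS * math.cos(ang), _CA_RADIUS * math.sin(ang), _HELIX_RISE * i]
        )
        ang_n = math.radians(_HELIX_TWIST * i + _N_PHASE)
        nn = np.array(
            [_N_RADIUS * math.cos(ang_n), _N_RADIUS * math.sin(ang_n),
             _HELIX_RISE * i + _N_Z]
        )
        cb = np.array(
            [_CB_RADIUS * math.cos(ang), _CB_RADIUS * math.sin(ang),
             _HELIX_RISE * i + 0.5]
        )
        for name, pos, el in (("N", nn, "N"), ("CA", ca, "C"), ("CB", cb, "C")):
            p = rot @ pos + origin
            atoms.append(
                Atom(chain=chain, residue_number=i + 1, residue_name="ALA",
                     atom_name=name, element=el,
                     position=(float(p[0]), float(p[1]), float(p[2])))
            )
    return atoms


def make_toy_complex(
    n_residues_a: int = 30,
    n_residues_b: int = 30,
    pose_offset: Sequence[float] = (7.0, 0.0, 22.0),
    seed: int = 0,
) -> SyntheticTruth:
    """Two ideal-helix pseudo-domains, partner B displaced by ``pose_offset``.

    Chain A runs along z; chain B runs along x starting at ``pose_offset``,
    so the two helices meet end-to-side in a T-shaped contact and the
    binding site is a compact patch (residues far from it see an
    essentially unperturbed environment, as in a real complex).  Raises if
    the pose produces a steric clash (inter-chain atom pair below 2
    Angstrom).  The planted interface is the set of residues of each chain
    with any atom within 8 Angstrom of the other chain.
    """
    if n_residues_a < 10 or n_residues_b < 10:
        raise ValueError("domains need >= 10 residues")
    atoms_a = _helix_chain("A", n_residues_a, np.zeros(3))
    atoms_b = _helix_chain(
        "B", n_residues_b, np.asarray(pose_offset, dtype=float), axis="x"
    )
    complex_model = StructureModel("toy_complex", atoms_a + atoms_b)

    xyz_a = np.array([a.position for a in atoms_a])
    xyz_b = np.array([a.position for a in atoms_b])
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=-1)
    if d.min() < _CLASH_CUTOFF:
        raise ValueError(
            f"pose_offset {tuple(pose_offset)} produces a steric clash "
            f"(min inter-chain distance {d.min():.2f} A)"
        )
    interface = {
        "A": {atoms_a[i].residue_number for i, j in zip(*np.where(d < _INTERFACE_CUTOFF))},
        "B": {atoms_b[j].residue_number for i, j in zip(*np.where(d < _INTERFACE_CUTOFF))},
    }
    free_models = {
        "A": StructureModel("toy_free_A", atoms_a),
        "B": StructureModel("toy_free_B", atoms_b),
    }
    return SyntheticTruth(
        complex_model=complex_model,
        free_models=free_models,
        planted_interface=interface,
        seed=seed,
    )


def attach_tag(
    truth: SyntheticTruth,
    chain: str,
    residue_number: int,
    n_conformers: int = 10,
    offset: float = 3.5,
    radius: float = 2.0,
    seed: int | None = None,
) -> TagSite:
    """Attach a tag conformer cloud at a residue of the complex model.

    Conformers are sampled uniformly on a sphere of ``radius`` centred
    ``offset`` Angstrom outward from the C-beta along the CA->CB direction.
    """
    from .sbmf import default_tag_conformers

    site_seed = truth.seed if seed is None else seed
    conformers = default_tag_conformers(
        truth.complex_model, (chain, residue_number, "CB"),
        n_conformers=n_conformers, offset=offset, radius=radius,
        seed=site_seed + residue_number,
    )
    tag = TagSite(
        site_id=f"{chain}{residue_number}C",
        attachment=(chain, residue_number, "CB"),
        conformers=conformers,
    )
    truth.tag_sites.append(tag)
    return tag


def simulate_pre_dataset(
    truth: SyntheticTruth,
    settings: AcquisitionSettings,
    noise_sigma: float = 0.0,
    seed: int = 0,
    params: SBMFParameters | None = None,
    probe_chain: str | None = None,
    probe_atom: str = "N",
    mode: str = "height",
    nominal_intensity: float = 1000.0,
) -> pd.DataFrame:
    """Forward-simulate a PRE peak table for every tag site in the truth.

    Probes default to the ``probe_atom`` of every residue on the chain
    opposite each tag.  The truth object is updated in place with the
    per-probe effective distances and rates.  ``mode`` selects the
    observable: ``height`` uses the methyl-HMQC height-ratio expression,
    ``volume`` the plain exponential exp(-Gamma2 * Delta).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if params is None:
        params = SBMFParameters(tau_1=truth.true_tau1, field_mhz=settings.field_mhz)
    rng = np.random.default_rng(seed)
    model = truth.complex_model
    rows = []
    for tag in truth.tag_sites:
        tag_chain = tag.attachment[0]
        chain = probe_chain or ("B" if tag_chain == "A" else "A")
        residues = [
            (c, n) for c, n, _ in model.residues() if c == chain
        ]
        for c, resnum in residues:
            pos = model.position(c, resnum, probe_atom)
            r_eff = ensemble_r6_distance(tag, pos)
            gamma2 = gamma2_from_distance(r_eff, params)
            key = (tag.site_id, c, resnum, probe_atom)
            truth.true_distances[key] = r_eff
            truth.true_gamma2[key] = gamma2
            if mode == "height":
                ratio = forward_height_ratio(gamma2, settings)
            elif mode == "volume":
                ratio = math.exp(-gamma2 * settings.delta_total)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            i_dia = nominal_intensity * (1.0 + noise_sigma * rng.standard_normal())
            i_para = ratio * nominal_intensity * (
                1.0 + noise_sigma * rng.standard_normal()
            )
            row = {
                "tag_site": tag.site_id,
                "chain": c,
                "resnum": resnum,
                "probe": probe_atom,
                "i_para": float("nan"),
                "i_dia": float("nan"),
                "v_para": float("nan"),
                "v_dia": float("nan"),
                "sigma_i": noise_sigma,
            }
            if mode == "height":
                row["i_para"], row["i_dia"] = i_para, i_dia
            else:
                row["v_para"], row["v_dia"] = i_para, i_dia
            rows.append(row)
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def simulate_csp_dataset(
    truth: SyntheticTruth,
    chain: str,
    amplitude: float = 0.2,
    decay_length: float = 5.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Free and bound shift tables with a planted interface.

    The perturbation magnitude decays exponentially with each residue's
    minimum distance to the partner chain; the magnitude is split randomly
    between the 1H and (0.15-weighted) 15N channels with random signs, so
    the combined CSP of a noiseless residue equals the planted magnitude.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    model = truth.complex_model
    other = [c for c in model.chains() if c != chain]
    other_idx = [i for i, a in enumerate(model.atoms) if a.chain in other]
    other_xyz = model.coords[other_idx]
    rows_free, rows_bound = [], []
    for c, resnum, _ in model.residues():
        if c != chain:
            continue
        idx = model.residue_atoms(c, resnum)
        d = float(
            np.linalg.norm(
                model.coords[idx][:, None, :] - other_xyz[None, :, :], axis=-1
            ).min()
        )
        mag = amplitude * math.exp(-d / decay_length)
        frac = rng.uniform(0.3, 0.7)
        sign_h, sign_n = rng.choice([-1.0, 1.0], size=2)
        delta_h = sign_h * frac * mag
        delta_n = sign_n * math.sqrt(max(0.0, mag**2 - (frac * mag) ** 2)) / 0.15
        delta_h += noise_sigma * rng.standard_normal()
        delta_n += noise_sigma / 0.15 * rng.standard_normal()
        rows_free.append(
            {"chain": c, "resnum": resnum, "delta_h_ppm": 0.0,
             "delta_n_ppm": 0.0, "intensity_loss": 0}
        )
        rows_bound.append(
            {"chain": c, "resnum": resnum, "delta_h_ppm": delta_h,
             "delta_n_ppm": delta_n, "intensity_loss": 0}
        )
    return pd.DataFrame(rows_free), pd.DataFrame(rows_bound)


def simulate_decay_series(
    rate: float,
    delays: Sequence[float] = DEFAULT_DECAY_DELAYS,
    noise_sigma: float = 0.0,
    seed: int = 0,
    i0: float = 1000.0,
) -> pd.DataFrame:
    """Mono-exponential decay I(t) = I0 exp(-R t) with multiplicative noise."""
    if len(delays) == 0:
        raise ValueError("delays must be non-empty")
    rng = np.random.default_rng(seed)
    t = np.asarray(delays, dtype=float)
    y = i0 * np.exp(-rate * t) * (1.0 + noise_sigma * rng.standard_normal(t.size))
    return pd.DataFrame({"delay_s": t, "intensity": y})
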
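# Methods

## PRE quantification

The transverse PRE Γ₂ᴴ of a ¹H spin is the extra relaxation contributed by
a nearby unpaired electron.  Three protocols convert measured peak
intensities to rates:

* **Two time point.**  Each sample (paramagnetic and diamagnetic) is
  measured as a two-plane relaxation experiment with delays τ₁ < τ₂;
  Γ₂ᴴ = −ln(I_ratio,para / I_ratio,dia)/(τ₂ − τ₁).  Defaults: τ₁ = 0,
  τ₂ = 10 ms.
* **Single time point, volumes.**  Peak volumes are insensitive to the
  PRE-induced line broadening, so Γ₂ᴴ = −ln(V_para/V_dia)/Δ with Δ the
  total transverse-¹H delay of the pulse sequence (10.3 ms for the amide
  experiments, 7.7 ms for the methyl HMQC).
* **Single time point, heights.**  Peak heights fold in the linewidths of
  both dimensions.  With pure exponential apodization (line broadenings
  LB_F1, LB_F2) the height ratio is

      I_para/I_dia = exp(−Γ₂ᴴΔ) · (R₂ᴹQ + πLB₁)(R₂ᴴ + πLB₂)
                     / [(R₂ᴹQ + πLB₁ + f·Γ₂ᴴ)(R₂ᴴ + πLB₂ + Γ₂ᴴ)]

  where R₂ᴹQ, R₂ᴴ are the diamagnetic multiple-quantum and ¹H rates and
  f = 1 + (γ_C/γ_H)² ≈ 1.063 scales the proton PRE to the ¹H/¹³C
  multiple-quantum coherence (assuming identical electron–nucleus geometry
  for the methyl H and C, and dominance of J(0)).  The ratio equals 1 at
  Γ₂ᴴ = 0 and decreases strictly monotonically, so the inverse is a unique
  root; it is found by geometric bracket expansion from [0, 10³ s⁻¹]
  followed by Brent refinement to |forward(Γ̂) − ratio| < 10⁻¹⁰.

Ratios marginally above 1 are noise: they clamp to Γ₂ᴴ = 0 with status
`no_pre`.  Peaks absent from the paramagnetic spectrum are `bleached`,
carry no finite rate, and are excluded from restraint building (with a
logged count).  Diamagnetic rates come from mono-exponential fits
I(t) = I₀e^(−Rt) over the standard delay list (0, 2, 5, 10, 15, 20, 30,
40 ms); with exactly two points the closed form −ln(I₂/I₁)/Δt is used.

Uncertainties are propagated by Monte Carlo: I_para, I_dia, R₂ᴴ and R₂ᴹQ
are resampled from Gaussians centred on the measured values, each
replicate is re-inverted, and the sample standard deviation (n−1) of the
replicate rates is reported.  Replicates with non-positive intensities or
rates are redrawn (truncation by redraw); the redraw count is returned.
The noise model is Gaussian and the intensity error is an explicit input
(spectral noise floor or fit residual — the package does not choose).
All Monte Carlo paths require an explicit seed.

## Distance conversion (SBMF)

Rates convert to electron–nucleus distances via the Solomon–Bloembergen
model-free rate law (see README for the expressions).  Parameters:

| parameter | meaning | default | unit |
|---|---|---|---|
| τ₁ | electron–nucleus correlation time (tumbling ⊕ electronic T₁) | 20 ns | s |
| S² | squared order parameter of internal tag motion | 1.0 | – |
| τ_i | internal-motion correlation time | ∞ (rigid) | s |
| ω_H | ¹H angular frequency | 2π·850 MHz | rad s⁻¹ |

The restraint-generation defaults (S² = 1, τ₁ = 20 ns) use the simplified
rate law in which the second spectral-density term is dropped; the full
two-term J(ω) is available for sensitivity analysis.  The prefactor κ_H is
always derived from the bundled constants, never stored.  The default
constant set evaluates κ_H with the spin-only electron g-factor g = 2,
which reproduces the conventional PRE-literature prefactor
1.2311 × 10¹⁶ Å⁶ s⁻² (= 1.23 × 10⁻³² cm⁶ s⁻²); a CODATA-2018 set with
g_e = 2.00231930436256 (κ_H larger by 0.23 %) is provided for sensitivity
checks.  The 0.23 % difference in κ corresponds to 0.04 % in distance and
is negligible against the 6 Å restraint padding.

Back-calculation from a structure uses a nitroxide-tag conformer cloud
and averages r⁻⁶ over conformers (the PRE-relevant average), not the
distances themselves.  The full tag-ensemble/τ co-optimisation of
molecular-dynamics protocols is deliberately replaced by a fixed conformer
cloud plus 1-D bounded optimisation of τ₁ (default window 5–40 ns,
weighted least squares of measured vs back-calculated Γ₂, weights 1/σ²
when uncertainties are present).  τ̂₁ uncertainty comes from a seeded
nonparametric bootstrap over probes (default 500 resamples).

## CSP mapping and AIRs

CSP = √(Δδ_H² + (0.15·Δδ_N)²).  Classification statistics (mean, SD with
n−1) are computed over residues with a finite CSP only; unassigned
residues and prolines simply carry no value and are never imputed.
Rules: active if CSP ≥ mean + 1.5 SD and relative accessibility > 15 %;
passive if CSP ≥ mean + 1 SD, or if the residue loses intensity on
binding and lies within the contiguity radius of an active residue.  The
"continuous surface" requirement is operationalised as: an active residue
with no other classified residue within 8 Å (minimum heavy-atom distance)
is demoted to passive.  The radius is a package choice; the criterion
itself has no standard quantitative definition.  If the SD is zero the
classification is degenerate and nothing is classified.  One AIR is
emitted per active residue, targeting the partner's active ∪ passive set
with an r⁻⁶-effective distance ceiling of 2.0 Å.

## Restraint building and filtering

PRE restraints connect proxy atoms: the amide nitrogen (amide probes) or
methyl carbon (methyl probes) to the Cβ of the tag-site residue.  Only
intensity ratios < 0.8 are converted (larger ratios carry no reliable
distance); the derived distance gets a 6 Å empirical padding as upper
bound with no lower bound, because incomplete saturation of the observed
species can only lengthen the apparent distance.  Encounter-complex
decontamination removes every restraint whose atom-pair distance is within
its upper bound in ANY member of the supplied encounter ensemble — the
conservative reading (a restraint explicable by the encounter state is
uninformative about the final complex).  Connectivity restraints are
emitted with fixed bounds: inter-domain linker Cα–Cα ≤ 59.5 Å,
phosphopantetheine-arm unfurling 14.0–16.5 Å (thiol S to phosphate P), and
active-site reach ≤ 8.0 Å (thiol S to the catalytic His Cε1).

Serialization uses assign statements `assign (a) (b) d dminus dplus` with
d = upper, dminus = upper − lower, dplus = 0 — a bit-exact, reversible
encoding of upper-bound-only and two-sided restraints, round-tripped by
the bundled reader.

## Solvent accessibility

SASA uses the Shrake–Rupley algorithm: each heavy atom is expanded by the
probe radius (default 1.4 Å) and covered with a golden-spiral point
lattice (default 960 points); the accessible fraction is the fraction of
points outside all neighbouring expanded spheres.  Hydrogens are ignored
by default, matching the heavy-atom convention of standard accessibility
programs.  Relative accessibility divides the per-residue SASA by a
bundled theoretical Gly-X-Gly maximum (Tien et al. 2013).  Because probe
radius, point density and reference maxima differ between implementations,
classifications of residues near the 15 % threshold can differ from those
of other accessibility programs.

## Synthetic data

The generator emulates the experimental inputs, not the spectra:

* **Toy complex.**  Two ideal poly-alanine helices (N, Cα, Cβ atoms;
  rise 1.5 Å, twist 100°), chain A along z and chain B along x, meeting in
  a T-shaped side contact (default pose offset (7, 0, 22), closest heavy
  atoms ≈ 4 Å).  The perpendicular arrangement is essential: it produces a
  compact binding patch with a quiet background, the feature the CSP
  classification stage exists to detect.  Poses producing inter-chain
  contacts below 2 Å are rejected.  The planted interface is the residue
  set within 8 Å of the partner.
* **Tag sites.**  Ten conformers sampled uniformly on a 2 Å sphere centred
  3.5 Å outward from the attachment Cβ along Cα→Cβ.  The maximum Cβ-to-
  conformer reach (5.5 Å) is deliberately kept below the 6 Å restraint
  padding so that, at zero noise, every restraint built from simulated
  data is satisfied by the generating pose by construction.
* **PRE tables.**  Per probe: effective distance from the structure
  (⟨r⁻⁶⟩ over conformers) → rate via the simplified SBMF law → observable
  via the height-ratio expression (or a plain exponential for the volume
  protocol) → intensities with multiplicative Gaussian noise
  (peak-height errors scale with the peak).
* **CSP tables.**  |Δδ| = amplitude · exp(−d/decay) with defaults
  0.2 ppm and 5 Å, split randomly between the ¹H and (0.15-weighted) ¹⁵N
  channels with random signs, plus additive Gaussian noise.
* **Decay series.**  I(t) = I₀e^(−Rt) over the standard 8-delay list with
  multiplicative noise.

All randomness flows from explicit integer seeds through named
`numpy.random.Generator` instances; fixed seeds give byte-identical
outputs.

What the generator does **not** emulate: peak overlap and line shapes,
NUS reconstruction artifacts, exchange broadening, chemical-shift
anisotropy, side-chain packing and real SASA variation (poly-alanine
only), and tag conformers biased by sterics.  Passing recovery tests
therefore demonstrates the correctness of the quantification, inversion,
conversion and bookkeeping machinery — not robustness to spectral
pathologies of real data.

## Numerical choices and problem sizes

* Root finding: `scipy.optimize.brentq` after geometric bracket expansion;
  monotonicity guarantees the bracket.
* Exponential fits: log-linear initialisation, then nonlinear least
  squares (`curve_fit`); standard errors use n−1 conventions throughout.
* τ₁ optimisation: `minimize_scalar(method="bounded")` with xatol 1e-13 s;
  the distance part of the objective is precomputed per probe.
* Degenerate inputs: zero-SD CSP sets classify nothing; equal para/dia
  ratios give exactly Γ₂ = 0; empty atom groups, unknown elements,
  unknown residue types and unknown tag sites raise named errors.
* Test problem sizes: 30–50 residues per synthetic domain, 1–3 tag sites,
  20 noise seeds for correlation-time recovery, 5 000-replicate Monte
  Carlo runs checked against a 50 000-replicate reference — sizes chosen
  to make the statistical checks stable at desk scale.

## Known limitations

* The encounter-complex filter uses single proxy-atom distances; ambiguous
  methyl pairs (unstereoassigned Leu/Val) are represented by their carbon
  proxy rather than an r⁻⁶ selection over both methyls.
* The contiguous-surface rule and the 8 Å contiguity radius are one
  reasonable operationalisation among several.
* The 8 Å planted-interface cutoff is generous relative to a 5 Å CSP decay
  length: residues near the cutoff produce small perturbations, and
  relative-threshold classification recovers the core of the patch more
  reliably than its rim.
* SASA is heavy-atom Shrake–Rupley with fixed radii; no slice-based or
  analytic alternative is provided.
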
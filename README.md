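# pre2restraints

From paramagnetic relaxation enhancements to docking restraints: a tested,
reusable implementation of the NMR analysis pipeline used to determine the
architecture of transient protein–protein complexes, exercised end to end
on synthetic data with known ground truth.

## The problem

Large, weakly bound protein complexes — such as a nonribosomal peptide
synthetase condensation domain engaging its substrate-loaded carrier
protein — often cannot be crystallised in the bound state.  Solution NMR
offers two complementary kinds of sparse structural data:

* **PREs** (paramagnetic relaxation enhancements): a nitroxide spin label
  attached to an engineered surface cysteine broadens the resonances of
  nuclei up to ~35 Å away.  The extra transverse relaxation Γ₂ᴴ scales as
  r⁻⁶ and is converted into long-range electron–nucleus distance
  restraints.
* **CSPs** (chemical shift perturbations): weighted ¹H/¹⁵N shift changes
  upon complex formation map the binding interface and define
  active/passive residues for ambiguous interaction restraints (AIRs) in
  data-driven docking.

This package implements the complete path from peak-intensity tables to
filtered, validated restraint files, plus a synthetic-data generator so
that every stage can be tested against planted ground truth.

## The model

PRE rates relate to electron–nucleus distances through the
Solomon–Bloembergen model-free (SBMF) formalism,

  Γ₂ᴴ = (κ_H / r⁶) · [4 J(0) + 3 J(ω_H)],
  J(ω) = S²τ₁/(1 + ω²τ₁²) + (1 − S²)τ_t/(1 + ω²τ_t²),

with κ_H = (γ_H g_e β)² (μ₀/4π)² S(S+1)/15 = 1.2311 × 10¹⁶ Å⁶ s⁻² for an
electron spin S = 1/2.  τ₁ combines global tumbling and electronic T₁
(1/τ₁ = 1/τ_m + 1/T1e); τ_t additionally folds in internal tag motion.
For restraint generation the fast-internal-motion simplification is used
(S² = 1, second spectral-density term dropped):

  Γ₂ᴴ = (κ_H / r⁶) · S² τ₁ (4 + 3/(1 + ω_H²τ₁²)).

Three extraction protocols are supported: two-time-point intensity ratios,
single-time-point volume ratios (Γ₂ᴴ = −ln(V_para/V_dia)/Δ), and
single-time-point methyl-HMQC *height* ratios, where the ratio depends on
the diamagnetic ¹H and ¹H/¹³C multiple-quantum rates, the apodization
line broadening, and the multiple-quantum PRE factor
1 + (γ_C/γ_H)² = 1.063; this expression has no closed-form inverse and is
inverted by bracketed root finding.  Uncertainties propagate by Monte
Carlo resampling of the measured inputs.

CSPs are computed as CSP = √(Δδ_H² + (0.15·Δδ_N)²); residues perturbed by
≥ 1.5 SD (active, if > 15 % solvent accessible) or ≥ 1 SD (passive) above
the mean define AIRs with a 2.0 Å effective-distance ceiling.  PRE
restraints use proxy atoms (amide N or methyl C ↔ tag-site Cβ), keep only
intensity ratios < 0.8, add a 6 Å empirical padding, are upper-bound-only,
and are cleared of encounter-complex contamination by eliminating any
restraint already satisfiable in an encounter-ensemble member.

## Worked example

```bash
pre2restraints simulate --seed 17 --out demo          # synthetic dataset + truth
pre2restraints extract-pre --peaks demo/peaks.tsv --mode height --out demo/pre.tsv
pre2restraints fit-tau --pre demo/pre.tsv --pdb demo/true_complex.pdb \
    --tag-chain A --tag-resnum 15 --seed 32
```

prints

```
wrote 90 peaks and truth to demo
extracted 90 PREs to demo/pre.tsv
tau1 = 20.01 +/- 0.00 ns (residual 170)
```

The simulated dataset used τ₁ = 20 ns; fitting the extracted rates back
against the structure and the generating tag-conformer cloud recovers it.
(With an independently guessed tag cloud — omit `--seed 32` — the fit
lands at 26.9 ± 3.1 ns, illustrating the sensitivity to the assumed tag
geometry.)  The full pipeline with restraint building and validation runs
from one config:

```bash
echo "seed: 4" > cfg.yaml
pre2restraints run --config cfg.yaml
# {"peaks": 90, "quantified": 89, "bleached": 1, "filtered_ratio": 59, "retained": 30}
```

Of 90 simulated peaks, 89 were quantifiable (one was broadened beyond
detection), 59 had intensity ratios above the 0.8 cutoff and carry no
usable distance, and 30 became upper-bound restraints — all satisfied by
the generating pose (`violations.tsv`).

Small calculators anchored to the same study are included:

```bash
pre2restraints plan-nus --nominal 0.0055 --dims 3 --oversample 2
# effective sparsity 4.4% (35% per indirect dimension)
pre2restraints mass --formula C13H12N2O2 --protonated
# nominal 229 Da, monoisotopic 229.0977 Da
```

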
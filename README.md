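# emdock

Likelihood-based signal/noise analysis of cryo-EM half-maps and
likelihood targets for docking atomic models into reconstructions.

## The problem

Placing an atomic model into a cryo-EM reconstruction is the cryo-EM
analogue of molecular replacement, with one crucial difference: the map
retains phase information.  Making full use of it requires an error model
for the reconstruction itself.  Because of preferred particle
orientations, both the signal power and the noise power of the Fourier
terms vary with **direction** as well as resolution, so a single FSC curve
per shell is not enough.

`emdock` estimates these error parameters from a pair of unfiltered,
unmasked half-maps and builds the corresponding likelihood scores:

* **Error model.**  Matching half-map Fourier terms are modelled as
  F₁ = S + ε₁, F₂ = S + ε₂ with complex-normal signal S (variance Σ_S) and
  independent noise ε (variance Σ_E).  Maximum-likelihood estimates over a
  small sphere of neighbouring terms are analytic:
  Σ̂_S = ⟨Re F₁F₂*⟩ and Σ̂_E = ⟨|F₁−F₂|²⟩/2.
* **Hybrid signal model.**  Local Σ_S estimates are blended with a refined
  parametric model Σ_S = A₀² exp(−½ sᵀβ_A s) · m_bin · BEST(s) (anisotropic
  tensor β_A, restrained bin multipliers against a reference spectrum) via
  a sigmoid in the local half-map correlation, so the smooth model takes
  over exactly where local estimates become unreliable.  Noise is always
  estimated locally — preferred-orientation noise need not obey any
  symmetry.
* **Data quality per term.**  D_obs = [Σ_S/(Σ_S + Σ_E/2)]^½ is the complex
  correlation between the normalized averaged coefficient E_mean and the
  truth — the single-term analogue of FSC_ref.
* **Docking targets.**  With model quality σ_A = √f·exp(−2π²Δ²s²/3)
  (completeness f, rms error Δ) and x = D_obs·σ_A, the per-term
  log-likelihood gain over an uninformative model is

      LLG = −ln(1−x²) + [2x·E_m·E_c·cos Δφ − x²(E_m²+E_c²)] / (1−x²).

  Orientations are scored with the amplitude-only (Rice) form of the same
  likelihood; translations are scored exactly on the whole grid with a
  single FFT, because only the correlation part of the LLG depends on the
  translation.  Rigid-body refinement optimizes rotations about the model
  centre of mass, translations, Δ and a cell (voxel-size) scale factor.
* **Planning scores.**  Expected LLGs have closed forms:
  eLLG_tra = −ln(1−x²) per term, eLLG_rot = −½ln(1−x⁴); at x = 0.01 their
  ratio is ≈ 20 000 — the value of the phases.  The per-term information
  gain of the reconstruction is D_KL = −ln(1−D_obs²) nats, which matches
  the Fourier shell information K·log₂[(1+FSC)/(1−FSC)] after the
  Rosenthal–Henderson substitution.  Terms carrying < 0.01 bit (after the
  oversampling correction, particle/box volume ratio) are dropped.

A synthetic-data generator (`emdock.synthetic`) produces half-map pairs
with exactly this statistical structure — Gaussian-atom models blurred by
a known anisotropic tensor plus directional complex-normal noise — with
all ground-truth fields recorded, so every estimator can be tested against
a known answer.

## Worked example

```python
import numpy as np
from emdock import (analyze_half_maps, AtomModel, OversamplingInfo,
                    dock_model, make_info_report)
from emdock.synthetic import (SyntheticSpec, generate_true_map,
                              simulate_half_maps)

spec = SyntheticSpec(seed=1)                  # 64^3 grid, 1.2 A voxels
true_map, truth = generate_true_map(spec)
half1, half2, truth = simulate_half_maps(true_map, truth)

analysis = analyze_half_maps(half1, half2, d_min=3.0)
print(analysis.shell_table(bins=6).round(3).to_string(index=False))
```

```
 s_min  s_max  d_min  n_terms  sigma_s  sigma_e   fsc  d_obs  mean_e2
 0.013  0.183  5.458     5860  105.418   37.794 0.746  0.764    0.987
 0.183  0.231  4.327     5860    6.492   38.278 0.141  0.498    0.998
 0.231  0.265  3.779     5860    2.937   37.895 0.066  0.365    1.002
 0.265  0.291  3.435     5860    1.653   37.737 0.029  0.282    0.996
 0.291  0.314  3.186     5860    0.951   37.308 0.021  0.219    0.999
 0.314  0.333  3.003     5860    0.506   38.118 0.006  0.160    1.000
```

Signal power falls steeply with resolution while noise power is flat, so
D_obs drops from 0.76 to 0.16 across the band (crossing 0.5 near
half-Nyquist by construction of the fixture); the mean-square normalized
coefficient stays at 1 as it must.  Planning scores and a full docking
run:

```python
over = OversamplingInfo(ordered_volume=4/3*np.pi*20.0**3,
                        box_volume=half1.box_volume)
info = make_info_report(analysis.normalized, over)
# eLLG_rot = 99.5   eLLG_tra = 469.7   information = 1096 bits

model = AtomModel(truth.coords, width=1.2)
result = dock_model(analysis.normalized, model, over, delta=0.5,
                    n_orientations=1500)
# LLG = 690.6, peak z = 13.0, rotation error = 0.08 deg,
# |translation| = 0.013 A
```

The translation eLLG exceeds the rotation eLLG almost five-fold even for
this compact particle — phase information at work — and the full search
(orientation scan → FFT translation search → rigid-body refinement)
recovers the generating pose to a few hundredths of a degree and of an
Angstrom.

The same pipeline is available from the shell:

```
emdock simulate    --out-dir sim --seed 1
emdock prepare-map --halfmap1 sim/halfmap_1.mrc --halfmap2 sim/halfmap_2.mrc --out-dir prep
emdock dock        --halfmap1 sim/halfmap_1.mrc --halfmap2 sim/halfmap_2.mrc \
                   --model sim/model.pdb --out-dir docked
emdock info        --halfmap1 sim/halfmap_1.mrc --halfmap2 sim/halfmap_2.mrc --out-dir info
```

`prepare-map` writes the two docking coefficient sets (the
expected-true-map "centroid" coefficients D_obs·E_mean and the
likelihood-weighted coefficients 2x/(1−x²)·E_mean) as MRC maps and
tabular text, plus per-shell and per-axis signal/noise profiles.

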
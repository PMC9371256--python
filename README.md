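# crossmodalfc

Region-wise mapping of band-limited electromagnetic functional
connectivity (FC) onto haemodynamic FC, for researchers studying how
MEG/EEG-derived and fMRI-derived network architectures relate across the
cortex.

Electromagnetic and haemodynamic recordings see the same neural activity
through very different physiological filters. A productive way to compare
them is a **regional multilinear model**: for each region *i*, the fMRI
connectivity profile (row *i* of the FC matrix, self-connection excluded)
is regressed on the corresponding MEG profiles in the six canonical bands
(δ 2–4, θ 5–7, α 8–12, β 15–29, lo-γ 30–59, hi-γ 60–90 Hz),

FC<sub>i</sub> = b₁FC(δ)<sub>i</sub> + b₂FC(θ)<sub>i</sub> + b₃FC(α)<sub>i</sub> + b₄FC(β)<sub>i</sub> + b₅FC(lo-γ)<sub>i</sub> + b₆FC(hi-γ)<sub>i</sub> + b₀,

with goodness of fit quantified by adjusted R² (n = N−1 observations,
p = 6 predictors). The resulting R² map measures regional cross-modal
correspondence. Around this core the package provides:

- **Connectivity measures** — amplitude envelope correlation (AEC) with
  pairwise leakage (zero-lag) orthogonalization, phase-locking value
  (PLV), Pearson haemodynamic FC, and a decibel source-SNR utility.
- **Dominance analysis** — each band's percent relative importance from
  all 2⁶−1 = 63 submodels, plus one-way ANOVA band contrasts with
  Bonferroni-corrected pairwise t tests and Cohen's d.
- **Cross-validation** — distance-dependent region-level splits (train on
  the 75% of profile entries closest to a source region, test on the
  rest; all N−1 sources enumerated) and leave-one-subject-out validation.
- **Spin-permutation inference** — spatial-autocorrelation-preserving
  null models from mirrored random sphere rotations, with two-tailed
  p_spin and Benjamini–Hochberg FDR control.
- **Cortical context** — diffusion-map principal FC gradient,
  structure–function coupling, laminar depth-profile associations,
  robust-sigmoid expression normalization, and cross-donor differential
  stability.
- **Synthetic data** — a generator that plants every quantity the
  pipeline estimates (mixing weights, noise gradient, analytic target R²,
  depth peaks, expression associations, envelope/phase couplings), so
  each stage has an exact recovery oracle.

## Worked example

```python
from crossmodalfc.synthetic import (SyntheticConfig, make_geometry,
                                    make_band_fc_set, make_crossmodal_truth)
from crossmodalfc.mapping import fit_all_regions, fit_global_model
from crossmodalfc.nulls import generate_spins, spin_pvalue

cfg = SyntheticConfig(n_parcels=200, seed=1)          # graded-noise study
geo = make_geometry(cfg.n_parcels, seed=cfg.seed)
bands = make_band_fc_set(geo, cfg)
haemo, truth = make_crossmodal_truth(bands, geo, cfg)

results, r2_map = fit_all_regions(haemo, bands)
print(f"regional adj R2: {r2_map.min():.3f} .. {r2_map.max():.3f}")
print(f"global adj R2:   {fit_global_model(haemo, bands).adj_r2:.3f}")

spins = generate_spins(geo, n_spin=1000, seed=5)
test = spin_pvalue(r2_map, truth.hierarchy, spins)
print(f"R2 vs hierarchy: r_s = {test.r:.3f}, p_spin = {test.p_spin:.4f}")
```

Output:

```
regional adj R2: 0.004 .. 0.710
global adj R2:   0.376
R2 vs hierarchy: r_s = -0.929, p_spin = 0.0010
```

The regional fits span near-zero to strong correspondence, the single
global model hides that heterogeneity, and the R² map declines along the
planted unimodal→transmodal hierarchy (strong negative rank correlation,
significant against 1,000 spin nulls) — the generator's noise gradient is
recovered by the analysis.

The same study runs from the shell:

```bash
crossmodalfc run-all --n-parcels 200 --seed 1 --out results/demo
```

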
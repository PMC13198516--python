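# carospec

Automated single-cell Raman / SERS analysis of carotenoid composition in
plant cell cultures.

Metabolically engineered, non-photosynthetic cell lines (e.g. tobacco BY-2
suspension cells) accumulate carotenoids — astaxanthin, canthaxanthin and
β-carotene — in vesicle-like intracellular structures. Raman imaging can
see them label-free: all carotenoids share strong resonance-enhanced bands
at the C–C stretch (υ₂, ~1160 cm⁻¹) and C=C stretch (υ₁, ~1520 cm⁻¹). But
a single-cell Raman map contains thousands of pixel spectra, most of which
carry no carotenoid signal at all, and telling the three structurally
near-identical compounds apart requires subtle spectral features. This
package automates the whole chain for spectroscopists and plant
synthetic-biology groups:

1. **Preprocessing** — arPLS baseline correction (iteratively reweighted
   penalized least squares with second-difference penalty λ‖Dz‖²),
   Whitaker–Hayes-style cosmic-ray removal via the modified z-score of
   first differences, z = 0.6745(ΔI − median ΔI)/MAD(ΔI), and discard of
   noisy spectra by correlation with the class mean.
2. **Characteristic peaks** — the k most important carotenoid bands are
   selected from pure-standard spectra by clustering detected peaks across
   compounds and ranking by (share count, mean normalized prominence);
   with k = 2 this yields the 1160 / 1520 cm⁻¹ pair.
3. **Knee-point triage** — each map pixel is scored by
   f = Σ_p I(peak_p); sorting the score vector F and locating the knee of
   the curve (maximum normalized distance to the endpoint chord) splits
   informative from non-informative spectra.
4. **Representative spectra** — per cell line, 10 averages of random
   halves of the pooled informative spectra.
5. **Composition regression** — a 412–100–10–3 tanh MLP (L-BFGS or ADAM)
   predicts the (astaxanthin, canthaxanthin, β-carotene) percentages under
   multi-label stratified fivefold cross-validation, scored by MSE, MAE
   and R² = 1 − SS_res/SS_tot, repeated 50 times (mean / SD / best).

A synthetic spectral simulator (Lorentzian fingerprints at the published
band positions, fluorescence-like background, Gaussian noise, cosmic-ray
spikes, vesicle-structured maps) provides ground truth for every stage;
see `docs/methods.md` for the model and its limits.

## Worked example

```python
import carospec as cs
from carospec.pipeline import run_pipeline

bench = cs.simulate_benchmark(seed=0)          # 34 standards + 7 lines x 4 maps
result = run_pipeline(bench, n_runs=5, seed=0)

print([f"{c:.0f}" for c in result.peak_set.centers])
print(result.dataset.features.shape)
agg = result.report.aggregate("test")
print(f"held-out R2 mean {agg['r2']['mean']:.4f} best {agg['r2']['best']:.4f}")
```

prints

```
['1160', '1517']
(104, 412)
held-out R2 mean 0.9885 best 0.9900
```

i.e. the peak-importance step recovered the two shared carotenoid bands
(υ₂ at 1160 cm⁻¹, υ₁ at 1517 cm⁻¹, within the ±5 cm⁻¹ match tolerance of
the canonical ~1520 cm⁻¹ position), the pipeline assembled 34 standards +
70 representative spectra into the 104 × 412 training matrix, and the
cross-validated network predicts the three carotenoid fractions of
held-out spectra with R² close to 1 (1 = perfect prediction; MSE/MAE near
0). The scripts in `examples/` walk through each capability one at a time
(simulation + preprocessing, peak selection, map triage, training,
map rendering); each prints the numbers it computes and what they mean.

A thin CLI mirrors the pipeline for shell use:

```bash
carospec --seed 0 --out-dir out run-all      # simulate -> ... -> train
carospec --out-dir out find-peaks --k 2      # prints the two band centers
```

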
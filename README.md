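# deepmaldi

Semi-quantitative processing of Deep-MALDI time-of-flight profile spectra.

Deep-MALDI analysis averages hundreds of 800-laser-shot raster spectra of a
serum sample into a single ~400,000-shot spectrum, raising the sensitivity of
MALDI-TOF profiling enough to see well over a thousand peptide and protein
peaks spanning more than 3.5 orders of magnitude in intensity between 3 and
30 kDa. Turning such spectra into reproducible relative-abundance estimates —
the feature values fed to machine-learning classifiers in blood-based
diagnostics — is hard: peaks overlap, they sit on broad unresolved structure,
and their widths and asymmetry change systematically with m/z. This package
implements a complete processing chain built around three ideas:

1. **A calibrated peak-shape model.** Isolated peaks are asymmetric Gaussians

   ```
   s(m) = A0 · exp(−(m − m0)² ln2 / σ_L²)   m <  m0
   s(m) = A0 · exp(−(m − m0)² ln2 / σ_R²)   m ≥  m0
   ```

   with independent left/right half-widths at half maximum whose trends vs
   m/z (linear at low mass, quadratic at high mass, FWHM = σ_L + σ_R) are
   calibrated once per instrument from isolated reference peaks
   (`calibrate_peak_shape`).

2. **A three-way spectral decomposition.** An asymmetric two-penalty
   Whittaker background (Eilers-style: weight `p` on points above the fit,
   `1 − p` below; second- and first-difference penalties λ₁, λ₂) is run at
   two stiffness regimes — stiff (λ₁ = 1e11, λ₂ = 1e4) for the instrument
   background `bg1`, relaxed (λ₁ = 1e6, λ₂ = 1e2) for background plus broad
   "bumps" `bg2` — giving the exact additive partition
   `y = bg1 + (bg2 − bg1) + (y − bg2) = bg1 + bumps + fine`. The bumps are
   slowly varying *biological* signal (unresolved overlapping peaks,
   multiply charged high-mass proteins) and are deliberately kept.

3. **Convolution-enhanced detection and cluster fitting.** The fine
   structure is matched-filtered with the local peak shape; candidates are
   local minima of the second derivative of that response, kept at SNR > 10.
   Mutually influencing candidates (centers within 0.5 FWHM, or either
   peak's tail above 10% of the other's amplitude) form clusters fitted
   jointly by N asymmetric Gaussians, so overlapping peaks get unbiased
   amplitudes. Per-sample peak lists are aligned to a common m/z axis
   (quadratic warp, four sub-ranges, 1/m weights) and merged into a master
   list of unique peaks; every spectrum is then re-fit amplitude-only at the
   master positions. The **standard feature value** is the fitted amplitude
   A0; the **enhanced feature value** adds the bump intensity under the
   peak, `FV_E(m) = FV_S(m) + Bumps(m)`, which is markedly more reproducible
   for weak peaks. A protein-set-enrichment stage (Spearman correlations
   against a protein panel, split-averaged weighted-KS score, permutation
   null, Benjamini-Hochberg FDR) links features to biological processes.

A first-class synthetic-data module generates ground-truth rasters, averaged
spectra, replicate sets and protein panels, so every stage is testable
without instrument data.

## Worked example

Process eight synthetic replicate preparations end-to-end and compare the
reproducibility of standard vs enhanced feature values:

```python
import numpy as np
from deepmaldi import synth
from deepmaldi.pipeline import PipelineConfig, run_pipeline
from deepmaldi.raster import AlignmentPointSet
from deepmaldi.features import normalize_total, replicate_cv

truth = synth.make_truth(n_peaks=300, seed=5, n_points=40000, noise_sd=10.0,
                         min_amplitude=50.0)
reps = synth.make_replicates(truth, 8, amp_cv=0.10, bump_cv=0.02,
                             warp_scale=1.0, seed=55)
points = np.sort(truth.peak_positions[truth.amplitudes
                                      > np.quantile(truth.amplitudes, 0.4)])
cfg = PipelineConfig(alignment_points=AlignmentPointSet(mz_points=points))
result = run_pipeline([(f"rep{k}", r) for k, r in enumerate(reps)],
                      shape=truth.shape, config=cfg)

print(f"master peaks: {len(result.master)}  "
      f"(true peaks with SNR > 10: {(truth.true_snr() > 10).sum()})")
cv_std = replicate_cv(normalize_total(result.standard))["cv"]
cv_enh = replicate_cv(normalize_total(result.enhanced))["cv"]
print(f"median CV, standard feature values: {100 * np.nanmedian(cv_std):.2f}%")
print(f"median CV, enhanced feature values: {100 * np.nanmedian(cv_enh):.2f}%")
```

Output:

```
master peaks: 295  (true peaks with SNR > 10: 270)
median CV, standard feature values: 9.59%
median CV, enhanced feature values: 8.10%
```

The master list recovers essentially all detectable peaks (295 entries for
270 peaks above the detection threshold plus sporadically detected weaker
ones), and with 10% replicate amplitude jitter the enhanced values are more
reproducible than the standard ones — the bump layer pools many unresolved
proteins and is more stable than individual weak-peak amplitudes.

The same stages are available from the shell:

```sh
deepmaldi synth spectrum --seed 1 --out demo/
deepmaldi decompose --in demo/spectrum.csv --out demo/layers.csv
deepmaldi detect --in demo/spectrum.csv --out demo/peaks.csv
deepmaldi run --in spectra_dir/ --out results/
```

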
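# eegage

Estimating chronological age from the resting-state EEG power spectrum.

The peak alpha frequency (PAF) of eyes-closed resting EEG slows with age by
roughly a quarter of a hertz per decade, and the shape of the whole
0.1–45 Hz spectrum carries additional age information.  `eegage` is a
pipeline for researchers who want to quantify both: it cleans DC-coupled
EEG, estimates spectra, computes five established PAF estimators, predicts
"EEG-age" from the broad spectrum with latent-variable regression, and runs
the full method-comparison statistics battery.  A synthetic-cohort
generator with known ground truth makes every stage testable without any
data download.

## What it computes

**PAF estimators** (log2-amplitude scale, alpha band 7–13 Hz):

| method | spectrum | summary rule |
|--------|----------|--------------|
| N-PAF | AR (covariance method, order 256) per channel | highest peak per channel, channel mean |
| D-PAF | first SVD component across channels | highest peak of the component |
| M-PAF | first SVD component | alpha centre μ₂ of the parametric fit |
| C-PAF | smoothed Welch per channel | SNR-weighted mean of admissible channel peaks |
| K-PAF | smoothed Welch per channel | centre of gravity over an individual alpha band |

The parametric model behind M-PAF is an aperiodic background plus five
Gaussian band peaks on the log2-amplitude scale,

    log2 A(f) = A0·(0.1 f)^m + Σᵢ Aᵢ exp(−½((f−μᵢ)/σᵢ)²) + k ,

fitted by bound-constrained multi-start non-linear least squares.

**EEG-age models**: PLS1 regression of age on the SVD-summarised spectrum
with permutation-based factor selection (1000 permutations) and VIP scores;
recursive weighted PLS (R-PLS) that reduces the spectrum to a few critical
frequencies; PARAFAC diagnostics (SSE / CORCONDIA / iterations, 25
replications, factor counts 1–10) and trilinear PLS on the
participants × channels × frequencies tensor.

**Statistics**: Pearson/partial correlations, Hotelling–Williams tests for
dependent correlations, Bland–Altman limits of agreement, OLS with RMSE,
paired t tests, MINQUE(1) variance components for the participant × channel
PAF grid, and Jeffreys–Zellner–Siow Bayes factors (r scale 0.354) for
nested regressions.

See `docs/methods.md` for the model, assumptions, defaults and numerical
choices.

## Worked example

```python
import numpy as np
from eegage import (CohortSpec, generate_cohort, synthesize_timeseries,
                    clean_raw, ar_psd_covariance, power_to_log2amplitude,
                    svd_first_component, fit_spectral_model, modeled_paf,
                    FrequencyGrid)

grid = FrequencyGrid()                      # 0.1 ... 45.0 Hz, 450 points
spec = CohortSpec(seed=1, paf_residual_sd=0.3)
participant = generate_cohort(spec)[0]      # age 24, true alpha 10.16 Hz

eeg = synthesize_timeseries(participant, duration_s=120.0, seed=11)
clean = clean_raw(eeg.raw)                  # demean, flag ±120 uV, crop, CAR
spectra = np.vstack([
    power_to_log2amplitude(
        ar_psd_covariance(clean.segment[c], order=256, fs=500, grid=grid).values)
    for c in range(clean.segment.shape[0])
])
svd = svd_first_component(spectra)
fit = fit_spectral_model(svd.component_spectrum, grid.values, seed=0)
print(f"clean segment: {clean.duration:.1f} s, dropped {clean.dropped_channels}")
print(f"true alpha centre {participant.true_params.alpha.mu:.3f} Hz, "
      f"M-PAF {modeled_paf(fit).value:.3f} Hz, adj R2 {fit.adj_r2:.4f}")
```

prints

```
clean segment: 120.0 s, dropped []
true alpha centre 10.163 Hz, M-PAF 10.146 Hz, adj R2 0.9990
```

i.e. from two minutes of synthesized 19-channel EEG the full
cleaning → AR spectrum → SVD → model-fit chain recovers this participant's
planted alpha peak to within 0.02 Hz, with the spectral model explaining
99.9% of the variance of the summary spectrum.

The same chain runs from the shell:

```bash
eegage run-all --seed 1 --out my_run --n-participants 60
```

which writes `cohort.csv`, `paf.csv`, `eeg_age.csv`, the statistics tables
(`stats_*.csv/json`) and a `manifest.json` with parameters and file hashes;
`eegage simulate|preprocess|spectra|paf|eeg-age|stats` run the pipeline
through a single stage.

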
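# pymbms

Rapid screening of extractable aromatic secondary metabolites in plant
biomass from pyrolysis molecular-beam mass spectrometry (py-MBMS)
spectra, with GC/MS validation and NIPALS PLS calibration.

## The problem

Comprehensive metabolomics of large plant populations (hundreds of
*Populus* genotypes for GWAS or feedstock breeding) is bottlenecked by
extraction, derivatization and chromatography. py-MBMS needs only
cryo-milled tissue: flash pyrolysis plus a molecular-beam mass
spectrometer yields a unit-mass-binned fragment spectrum (m/z 30–450)
per sample in seconds. This package implements the screening analysis
that turns those spectra into actionable phenotypes:

* **Aromatic ion-summation score.** After total-ion-current (TIC)
  normalization and replicate averaging, the score of sample *i* is

  `score_i = Σ_{z ∈ A} x_iz`,  A = {68, 71, 77, 91, 94, 105, 107, 108, 122},

  the fraction of total ion current carried by ions deriving from
  aromatic secondary metabolites (salicylates, phenolics, benzoates).
  It proxies the extractable aromatic fraction without any fitted
  model, and ranks samples for prioritization (rank 1 = most aromatic).
* **Lignin content (% DW)** from mean-normalized spectra:
  `lignin_i = RF · Σ_{z ∈ L} x_iz`, with the single-point response
  factor `RF = Klason% / Σ_{z ∈ L} x_ref,z` calibrated on a standard of
  known Klason lignin, L the 17 lignin marker ions (120–210).
* **S/G ratio** `= Σ_S x_iz / Σ_G x_iz` over syringyl- and
  guaiacyl-derived ion subsets (scale-invariant).
* **Chemometrics.** NIPALS PCA on mean-centered TIC spectra, NIPALS
  PLS1 calibration against GC/MS traits (window m/z 50–250, mean
  centering only, seeded random-holdout cross-validation), per-ion
  trait correlations, and Pearson/Spearman/R² validation statistics.
* **Synthetic paired data.** A latent mixture generator producing
  spectra + GC/MS tables with known ground truth (compositional
  sugar–aromatic anticorrelation, duplicate replicates, multiplicative
  noise, the m/z 71 sugar/aromatic confounder), so every stage is
  testable without the undeposited field data.

## Worked example

```python
from pymbms import (SyntheticConfig, generate_dataset, screen_spectra,
                    run_validation, make_reference_spectrum,
                    calibrate_response_factor, mean_normalize)

spectra, metabolites, truth = generate_dataset(SyntheticConfig(n_samples=200, seed=3))
ref, klason = make_reference_spectrum(0.10, 9.5)          # 9.5% Klason standard
cal = calibrate_response_factor(mean_normalize(ref), klason)
results = screen_spectra(spectra, calibration=cal)        # score, rank, lignin, S/G
report, ranks = run_validation(results, metabolites, trait="sum")
print(report.to_dict())
```

prints (exact output of this snippet):

```
{'pearson_r': 0.836..., 'spearman_rho': 0.858..., 'r_squared': 0.700..., 'n': 200}
```

i.e. the one-line spectral score tracks the summed GC/MS aromatic
abundance with r ≈ 0.84 and reproduces its sample ranking with
ρ ≈ 0.86 under the default 5% spectral / 25% trait-coupling noise;
`results` also carries lignin ≈ 9.5 ± 2% DW and S/G ≈ 0.65 for the same
samples. The `examples/` scripts walk each capability: simulate+screen,
GC/MS validation, PLS calibration, ion discovery and PCA loadings.

A thin CLI mirrors the library:
`pymbms simulate|screen|fit-pls|correlate|validate --help`.

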
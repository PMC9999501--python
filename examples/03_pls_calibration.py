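"""Fit a NIPALS PLS calibration predicting the GC/MS aromatic trait.

Spectra are TIC-normalized, replicate-averaged, restricted to m/z
50-250 and mean-centered (no column scaling); a 3-factor PLS1 model is
fit and cross-validated on a single random 20-sample holdout, plus a
repeated-split mode for a stabler estimate.
"""

from pymbms import (
    SyntheticConfig,
    aromatic_sum,
    average_replicates,
    cross_validate_pls,
    cross_validate_pls_repeated,
    fit_pls_nipals,
    generate_dataset,
    tic_normalize,
)

spectra, metabolites, _ = generate_dataset(SyntheticConfig(n_samples=200, seed=17))
tic = average_replicates(tic_normalize(spectra))
y = aromatic_sum(metabolites).loc[tic.sample_ids].to_numpy()

model = fit_pls_nipals(tic, y, n_factors=3)
print(f"3-factor PLS, window m/z {model.mz_window[0]}-{model.mz_window[1]}, "
      f"{len(model.mz)} variables")
print(f"calibration R^2 = {model.cv_stats['r2_calibration']:.3f}, "
      f"RMSE = {model.cv_stats['rmse_calibration']:.2f} ug/g")

cv = cross_validate_pls(tic, y, n_factors=3, n_holdout=20, seed=17)
print(f"single 20-sample holdout: R^2_val = {cv['r2_validation']:.3f}, "
      f"RMSE_val = {cv['rmse_validation']:.2f} ug/g")

rep = cross_validate_pls_repeated(tic, y, n_factors=3, n_holdout=20,
                                  n_repeats=50, seed=17)
print(f"50 repeated splits: R^2_val = {rep['r2_validation_mean']:.3f} "
      f"+/- {rep['r2_validation_sd']:.3f}")
print("\nvalidation R^2 ~0.7-0.8 matches what a trait with ~25% coupling "
      "noise admits; a single random split is visibly noisier than the "
      "repeated-split mean.")
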
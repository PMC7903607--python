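"""Missing-value imputation with resampling-averaged linear SVR.

Pipeline: generate a cohort with a planted linear dependency → temporal
3:1 train/test split → z-score normalization with train-only statistics
→ per-clinotype ε-insensitive SVR trained on balanced 1:1:1 resamples →
fill missing cells → score predictions on the held-out split with the
3-class (high/normal/low) confusion scheme.
"""

from cpa import (
    GeneratorConfig,
    LatentModel,
    SVLRConfig,
    apply_normalization,
    evaluate_imputation,
    fit_all_models,
    fit_normalization,
    generate_cohort,
    impute_missing,
    temporal_split,
)

clins = [f"C{i:02d}" for i in range(8)]
latent = LatentModel(
    coefficients={"C05": {"C00": 0.7, "C01": -0.5, "C02": 0.3}},
    noise_sd={"C05": 0.2},
)
config = GeneratorConfig(
    n_patients=1500, clinotypes=clins, latent=latent, missing_rate=0.05, seed=7
)
matrix, *_ = generate_cohort(config)

split = temporal_split(matrix, "2013-06-30")
params = fit_normalization(split.train)
train = apply_normalization(split.train, params)
test = apply_normalization(split.test, params)
print(f"split: {split.train.n_patients} train / {split.test.n_patients} test "
      f"(ratio {split.ratio:.2f})")

models = fit_all_models(train, config=SVLRConfig(n_repetitions=10, seed=0))
completed = impute_missing(test, models)
print(f"imputed {int(completed.imputed.sum().sum())} missing cells in the test split")

w = models["C05"].w
top = w.abs().sort_values(ascending=False).head(3)
print("C05 model, largest averaged coefficients (planted: C00, C01, C02):")
for name in top.index:
    print(f"  {name}: {w[name]:+.3f}")

per_clinotype, weighted = evaluate_imputation(test, models)
print(f"weighted ACC={weighted.ACC:.3f} PPV={weighted.PPV:.3f} NPV={weighted.NPV:.3f} "
      f"over {weighted.n_cells} cells")
print("(random 3-class guessing would score 0.33 on each metric; the linear "
      "target C05 is predicted far better than the independent clinotypes)")
print(f"C05 alone: ACC={per_clinotype['C05'].ACC:.3f}")
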
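"""One-class DD-SIMCA model of Prototaxites.

Fits a PCA-based acceptance region on the 12 Prototaxites band-feature
vectors (component count chosen by leave-one-out sensitivity), then tests
every non-Prototaxites sample against it.  Specificity is the fraction
of alien samples rejected, per lineage and pooled.
"""

import json
from pathlib import Path

import warnings

import numpy as np

import fossilftir as ff

# band extraction warns on spectra without history; the reloaded CSVs
# are the preprocessed ones, so the warning is spurious here
warnings.filterwarnings("ignore", message="extracting bands from unpreprocessed")

OUT = Path(__file__).resolve().parent.parent / "results"
ALPHA = 0.05

pre = ff.load_spectra(OUT / "spectra_preprocessed.csv", dialect="wide-csv",
                      labels=OUT / "labels.csv")
features = ff.extract_band_matrix(pre)
taxa = np.asarray(features.attrs["taxon"])
target = features.to_numpy()[taxa == "Prototaxites"]

a, sens = ff.select_components_by_sensitivity(target, [1, 2, 3, 4, 5],
                                              alpha=ALPHA)
model = ff.fit_ddsimca(target, a, alpha=ALPHA)
aliens = {cls: features.to_numpy()[taxa == cls]
          for cls in sorted(set(taxa)) if cls != "Prototaxites"}
per_class, pooled = ff.specificity(model, aliens)

report = {
    "alpha": ALPHA,
    "n_components": a,
    "loo_sensitivity_by_a": {str(k): v for k, v in sens.items()},
    "n_sd": model.n_sd,
    "n_od": model.n_od,
    "c_crit": model.c_crit,
    "training_outliers": int(model.training_outlier_flags.sum()),
    "specificity_per_class": per_class,
    "specificity_pooled": pooled,
}
(OUT / "oneclass.json").write_text(json.dumps(report, indent=2,
                                              sort_keys=True) + "\n")

print(f"chosen components a = {a} "
      f"(LOO sensitivity {sens[a]:.3f}); DoF N_SD={model.n_sd}, "
      f"N_OD={model.n_od}")
print(f"training outliers flagged: {int(model.training_outlier_flags.sum())}")
for cls, value in per_class.items():
    print(f"  specificity vs {cls:11s} {value:.3f}")
print(f"pooled specificity (true negative rate): {pooled:.3f}")
print(f"wrote {OUT / 'oneclass.json'}")
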
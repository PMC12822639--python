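"""Data exploration: PCA diagnostics, bootstrap stability, T2/Q outlier
screening, and canonical correspondence analysis.

PCA runs on the full preprocessed spectra; the first ten components are
summarized with explained and cumulative variance, their loading stability
is measured over 100 bootstrap resamples (cosine to the reference
loadings), samples are screened with Hotelling T2 and Q residuals at 99%
confidence, and CCA relates the one-hot lineage matrix to the
standardized band intensities (scaling 1).
"""

import sys
from pathlib import Path

import warnings

import numpy as np
import pandas as pd

import fossilftir as ff

# band extraction warns on spectra without history; the reloaded CSVs
# are the preprocessed ones, so the warning is spurious here
warnings.filterwarnings("ignore", message="extracting bands from unpreprocessed")

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parent.parent / "results"

pre = ff.load_spectra(OUT / "spectra_preprocessed.csv", dialect="wide-csv",
                      labels=OUT / "labels.csv")
matrix = pre.matrix()

pca = ff.fit_pca(matrix, n_components=10)
pd.DataFrame({
    "pc": np.arange(1, 11),
    "eigenvalue": pca.eigenvalues,
    "explained_variance": pca.explained_variance_ratio,
    "cumulative_variance": pca.cumulative_variance_ratio,
}).to_csv(OUT / "pca_scree.csv", index=False, float_format="%.10g")

stability = ff.bootstrap_stability(matrix, n_components=10, n_boot=100,
                                   seed=SEED)
pd.DataFrame({"pc": np.arange(1, 11),
              "mean_cosine": stability.mean_cosines}).to_csv(
    OUT / "pca_stability.csv", index=False, float_format="%.10g")

screen = ff.fit_pca(matrix, n_components=5)
report = ff.detect_outliers(screen, matrix, confidence=0.99)
pd.DataFrame({"sample_id": pre.sample_ids, "taxon": pre.labels,
              "t2": report.t2, "q": report.q,
              "flagged": report.flags}).to_csv(
    OUT / "outlier_screen.csv", index=False, float_format="%.10g")
clean = (ff.remove_outliers_and_recompile(pre, report)
         if report.flags.any() else pre)

features = ff.extract_band_matrix(clean)
onehot = clean.onehot
cca = ff.fit_cca(onehot[:, onehot.sum(axis=0) > 0], features.to_numpy())
pd.DataFrame({"axis": np.arange(1, len(cca.eigenvalues) + 1),
              "eigenvalue": cca.eigenvalues}).to_csv(
    OUT / "cca_eigenvalues.csv", index=False, float_format="%.10g")
scores = pd.DataFrame(cca.site_scores, index=clean.sample_ids,
                      columns=[f"CCA{i+1}"
                               for i in range(cca.site_scores.shape[1])])
scores.insert(0, "taxon", list(clean.labels))
scores.to_csv(OUT / "cca_site_scores.csv", index_label="sample_id",
              float_format="%.10g")

print(f"PC1-4 cumulative variance: {pca.cumulative_variance_ratio[3]:.3f}")
print(f"mean bootstrap cosine PC1: {stability.mean_cosines[0]:.3f}")
print(f"outliers flagged at 99% (T2 or Q): {int(report.flags.sum())} of "
      f"{len(pre)}; {len(clean)} samples retained")
print(f"CCA constrained inertia {cca.constrained_inertia:.3f} of total "
      f"{cca.total_inertia:.3f} "
      f"({cca.constrained_inertia / cca.total_inertia:.1%})")
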
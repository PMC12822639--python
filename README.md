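# fossilftir

Chemotaxonomic analysis of FTIR spectra from chert-hosted fossils, built
around the question of whether the giant Early Devonian fossil
*Prototaxites* shares the molecular fingerprint of Fungi or of any other
lineage preserved alongside it. The package implements the complete
statistical pipeline — spectral preprocessing, band-feature extraction,
multivariate exploration, supervised binary discrimination, one-class
modelling, and aliphatic chain-length chemometrics — and ships a
synthetic-spectrum generator that emulates the study design, so every
stage runs and is tested without any external data.

## What it computes

**Preprocessing.** Three composable, history-tracked recipes: ATR
(truncation to the informative windows 1445–1750 and 2760–3000 cm⁻¹,
asymmetric-least-squares baseline, light Gaussian smoothing,
normalization on the silica-overtone maximum near 1615 cm⁻¹), benchtop
transmission (smoothing, baseline, Savitzky–Golay second derivative,
window 21, order 2), and synchrotron (truncation to 1440–3000 cm⁻¹,
SG(9, 2) second derivative or baseline variant, smoothing, vector
normalization).

**Exploration.** Mean-centered PCA by SVD with a fixed sign convention;
loading stability over bootstrap resamples measured by the cosine
|l·l_boot| per component; outlier screening with Hotelling's T² (F-based
limit) against the Q residual (Jackson–Mudholkar limit), flagging on the
OR rule at 99 % confidence; canonical correspondence analysis (ter
Braak) of the one-hot lineage matrix constrained by standardized band
intensities, scaling 1.

**Discrimination.** Stratified 70/30 split (largest-remainder
allocation), PCA projection fitted on training rows only, SMOTE
balancing of the minority class, LDA first with escalation to an RBF SVM
tuned by leave-one-out grid search over C and γ, and five metrics
(accuracy, precision, recall, F1, MCC) with *Prototaxites* as the
positive class.

**One-class DD-SIMCA.** A PCA model of the target class defines score
(SD) and orthogonal (OD) distances; each scaled distance is matched to a
chi-square law whose degrees of freedom are estimated from leave-one-out
distances, and a sample is accepted iff

    c = N_SD·SD/SD₀ + N_OD·OD/OD₀ ≤ χ²(1−α, N_SD+N_OD).

**Chain length.** The aliphatic ratio R₃/₂ = I(CH₃, ≈2960 cm⁻¹) /
I(CH₂, ≈2925 cm⁻¹) maps to an equivalent unbranched alkane length via
n = 2k/R₃/₂ + 2 with k = 2.625, anchoring R₃/₂ = 0.75 at nine carbons.

## Worked example

The analysis is a sequence of numbered drivers; each reads the previous
step's tables from `results/` and appends its own:

```sh
python analysis/01_simulate.py 1          # 102 labeled synthetic spectra
python analysis/02_preprocess_features.py # ATR recipe + band features
python analysis/03_explore.py 1          # PCA, stability, T2/Q, CCA
python analysis/04_classify.py 1         # four binary tasks
python analysis/05_oneclass.py           # DD-SIMCA specificity
python analysis/06_chain_length.py 1     # CH3/CH2 ratio
```

With seed 1 this prints, among other lines:

```
preprocessed 102 spectra -> 137 grid points inside the two analysis windows
PC1-4 cumulative variance: 0.985
mean bootstrap cosine PC1: 0.997
outliers flagged at 99% (T2 or Q): 5 of 102; 97 samples retained
vs-fungi      lda     test: acc 1.000 prec 1.000 rec 1.000 f1 1.000 mcc 1.000
pooled specificity (true negative rate): 1.000
50 synthetic Prototaxites spots: mean CH3/CH2 ratio 0.789 (sd 0.099)
equivalent chain length 8.7 carbons (about nine for ratios near 0.75)
```

Read: the synthetic design separates cleanly (perfect test metrics on
the generated contrasts — the generator's class profiles are strong by
construction), PCA axes are highly stable under resampling, the
one-class model rejects every non-*Prototaxites* sample, and the
aliphatic ratio of the *Prototaxites* profile sits near 0.75,
i.e. chains of about nine carbons. The same stages are available
programmatically (`fossilftir.run_pipeline(validate_config({...}))`)
with a byte-reproducible manifest.

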
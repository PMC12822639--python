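"""Supervised discrimination of Prototaxites from the other lineages.

Runs the four binary tasks (vs bacteria, vs Fungi, vs chitinous organisms,
vs plants): stratified 70/30 split, PCA projection fitted on the training
rows (2 PCs for the bacteria task, 4 otherwise), SMOTE balancing when the
classes are imbalanced, LDA first with escalation to an RBF SVM under
leave-one-out grid search, and the five metrics with Prototaxites
positive.  Learning curves check that the sample sizes saturate.
"""

import json
import sys
from pathlib import Path

import pandas as pd

import fossilftir as ff
from fossilftir.classify import TASKS, learning_curve

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parent.parent / "results"

pre = ff.load_spectra(OUT / "spectra_preprocessed.csv", dialect="wide-csv",
                      labels=OUT / "labels.csv")

results = {}
for i, task in enumerate(sorted(TASKS)):
    rep = ff.run_binary_task(pre, task, seed=SEED + i)
    results[task] = {
        "model": rep.model.kind,
        "best_C": rep.model.best_C,
        "best_gamma": rep.model.best_gamma,
        "train": rep.train_metrics.as_dict(),
        "test": rep.test_metrics.as_dict(),
        "params": rep.params,
    }
    t = rep.test_metrics
    print(f"{task:13s} {rep.model.kind:7s} test: acc {t.accuracy:.3f} "
          f"prec {t.precision:.3f} rec {t.recall:.3f} f1 {t.f1:.3f} "
          f"mcc {t.mcc:.3f}")

(OUT / "classification.json").write_text(
    json.dumps(results, indent=2, sort_keys=True) + "\n")

# learning curve on the Fungi task in the train-PCA space
sub = pre.subset_classes(("Prototaxites", "Fungi"))
pcs = ff.fit_pca(sub.matrix(), n_components=4).transform(sub.matrix())
rows = learning_curve(pcs, sub.labels, fractions=(0.4, 0.6, 0.8, 1.0),
                      n_repeats=5, seed=SEED)
pd.DataFrame(rows, columns=["fraction", "mean_loo_accuracy", "sd"]).to_csv(
    OUT / "learning_curve_vs_fungi.csv", index=False, float_format="%.10g")
print("learning curve (vs-fungi):",
      ", ".join(f"{f:.0%}->{m:.3f}" for f, m, _ in rows))
print(f"wrote {OUT / 'classification.json'}")
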
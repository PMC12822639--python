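"""End-to-end pipeline orchestration with a validated config and a
machine-readable manifest.

``run_pipeline`` chains: simulate (or load) → preprocess → band features →
explore (PCA, stability, T²/Q screening with optional removal, CCA) →
binary classification tasks → one-class DD-SIMCA, writing every table as
CSV and every report as JSON under ``out_dir``, plus a ``manifest.json``
listing artifacts with content hashes and the seeds used.  Outputs carry
no timestamps, so a rerun with the same config is byte-identical.

Configs are YAML (JSON being a YAML subset is accepted too); every field
has a default matching the emulated study design.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bands as bands_mod
from . import classify as classify_mod
from . import explore as explore_mod
from . import oneclass as oneclass_mod
from .io import SpectralDataset, SpectrumError, load_spectra, save_spectra
from .preprocess import RECIPES, apply_recipe
from .synthgen import DEFAULT_COUNTS, StudyDesign, default_profiles, generate_dataset


@dataclass
class PipelineConfig:
    """All pipeline settings, defaulted to the emulated study design."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # input: either a file to load or the synthetic design
    input_path: str = None
    input_dialect: str = "wide-csv"
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    recipe: str = "atr-paper"
    band_mode: str = "height"
    n_pcs_explore: int = 10
    n_boot: int = 100
    outlier_confidence: float = 0.99
    outlier_rule: str = "or"
    remove_outliers: bool = True
    outlier_screen_pcs: int = 3
    tasks: tuple = ("vs-bacteria", "vs-fungi", "vs-chitinous", "vs-plants")
    test_fraction: float = 0.30
    lda_escalation_threshold: float = 0.95
    smote_k: int = 5
    oneclass_alpha: float = 0.05
    oneclass_mode: str = "moments"
    oneclass_components: str = "auto"   # "auto" or an integer

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


_VALIDATORS = {
    "test_fraction": lambda v: 0 < v < 1,
    "oneclass_alpha": lambda v: 0 < v < 1,
    "outlier_confidence": lambda v: 0 < v < 1,
    "n_boot": lambda v: isinstance(v, int) and v >= 1,
    "n_pcs_explore": lambda v: isinstance(v, int) and v >= 1,
    "outlier_screen_pcs": lambda v: isinstance(v, int) and v >= 1,
    "seed": lambda v: isinstance(v, int),
    "smote_k": lambda v: isinstance(v, int) and v >= 1,
    "recipe": lambda v: v in RECIPES,
    "band_mode": lambda v: v in ("height", "area"),
    "outlier_rule": lambda v: v in ("or", "and"),
    "oneclass_mode": lambda v: v in ("moments", "robust"),
}


def validate_config(source) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON file path or a dict,
    reporting every problem at once (not fail-fast)."""
    if isinstance(source, (str, Path)):
        try:
            raw = yaml.safe_load(Path(source).read_text()) or {}
        except yaml.YAMLError as err:
            raise SpectrumError(f"unparseable config: {err}") from err
    else:
        raw = dict(source or {})
    if not isinstance(raw, dict):
        raise SpectrumError("config root must be a mapping")
    errors = []
    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown field {key!r}")
    for key, check in _VALIDATORS.items():
        if key in raw and not check(raw[key]):
            errors.append(f"invalid value for {key!r}: {raw[key]!r}")
    if "tasks" in raw:
        bad = [t for t in raw["tasks"] if t not in classify_mod.TASKS]
        if bad:
            errors.append(f"unknown tasks {bad}")
    oc = raw.get("oneclass_components")
    if oc is not None and oc != "auto" and not isinstance(oc, int):
        errors.append(f"oneclass_components must be 'auto' or an int, got {oc!r}")
    if errors:
        raise SpectrumError("invalid config: " + "; ".join(errors))
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    cfg.tasks = tuple(cfg.tasks)
    return cfg


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def record(name: str, path: Path):
        artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    # ---- stage 1: simulate or load -------------------------------------
    if config.input_path:
        dataset = load_spectra(config.input_path, dialect=config.input_dialect)
    else:
        design = StudyDesign(counts=dict(config.counts),
                             seed=config.stage_seed("simulate"))
        dataset = generate_dataset(design, default_profiles())
    raw_path = out / "spectra_raw.csv"
    save_spectra(dataset, raw_path, dialect="wide-csv")
    record("spectra_raw", raw_path)

    # ---- stage 2: preprocess -------------------------------------------
    pre = apply_recipe(dataset, config.recipe)
    pre_path = out / "spectra_preprocessed.csv"
    save_spectra(pre, pre_path, dialect="wide-csv")
    record("spectra_preprocessed", pre_path)

    # ---- stage 3: band features ----------------------------------------
    table = bands_mod.extract_band_matrix(pre, mode=config.band_mode)
    feats_path = out / "band_features.csv"
    feats = table.copy()
    feats.insert(0, "taxon", table.attrs["taxon"])
    feats.to_csv(feats_path, index_label="sample_id", float_format="%.10g")
    record("band_features", feats_path)

    # ---- stage 4: explore ----------------------------------------------
    matrix = pre.matrix()
    n_pcs = min(config.n_pcs_explore, len(pre) - 1, matrix.shape[1])
    pca = explore_mod.fit_pca(matrix, n_components=n_pcs)
    scree = pd.DataFrame(
        {
            "pc": np.arange(1, n_pcs + 1),
            "eigenvalue": pca.eigenvalues,
            "explained_variance": pca.explained_variance_ratio,
            "cumulative_variance": pca.cumulative_variance_ratio,
        }
    )
    scree.to_csv(out / "pca_scree.csv", index=False, float_format="%.10g")
    record("pca_scree", out / "pca_scree.csv")
    scores = pd.DataFrame(
        pca.transform(matrix),
        index=pre.sample_ids,
        columns=[f"PC{i+1}" for i in range(n_pcs)],
    )
    scores.insert(0, "taxon", list(pre.labels))
    scores.to_csv(out / "pca_scores.csv", index_label="sample_id",
                  float_format="%.10g")
    record("pca_scores", out / "pca_scores.csv")

    stab = explore_mod.bootstrap_stability(
        matrix, n_components=n_pcs, n_boot=config.n_boot,
        seed=config.stage_seed("bootstrap"),
    )
    pd.DataFrame(
        {"pc": np.arange(1, n_pcs + 1), "mean_cosine": stab.mean_cosines}
    ).to_csv(out / "pca_stability.csv", index=False, float_format="%.10g")
    record("pca_stability", out / "pca_stability.csv")

    screen_model = explore_mod.fit_pca(
        matrix, n_components=min(config.outlier_screen_pcs, n_pcs)
    )
    report = explore_mod.detect_outliers(
        screen_model, matrix, confidence=config.outlier_confidence,
        rule=config.outlier_rule,
    )
    pd.DataFrame(
        {
            "sample_id": pre.sample_ids,
            "taxon": pre.labels,
            "t2": report.t2,
            "q": report.q,
            "flagged": report.flags,
        }
    ).to_csv(out / "outliers.csv", index=False, float_format="%.10g")
    record("outliers", out / "outliers.csv")
    if config.remove_outliers and report.flags.any():
        pre = explore_mod.remove_outliers_and_recompile(pre, report)
        table = bands_mod.extract_band_matrix(pre, mode=config.band_mode)

    cca = explore_mod.fit_cca(pre.onehot[:, pre.onehot.sum(axis=0) > 0],
                              table.to_numpy())
    pd.DataFrame(
        {"axis": np.arange(1, len(cca.eigenvalues) + 1),
         "eigenvalue": cca.eigenvalues}
    ).to_csv(out / "cca_eigenvalues.csv", index=False, float_format="%.10g")
    record("cca_eigenvalues", out / "cca_eigenvalues.csv")
    cca_scores = pd.DataFrame(
        cca.site_scores,
        index=pre.sample_ids,
        columns=[f"CCA{i+1}" for i in range(cca.site_scores.shape[1])],
    )
    cca_scores.insert(0, "taxon", list(pre.labels))
    cca_scores.to_csv(out / "cca_site_scores.csv", index_label="sample_id",
                      float_format="%.10g")
    record("cca_site_scores", out / "cca_site_scores.csv")

    # ---- stage 5: binary classification tasks --------------------------
    task_results = {}
    for task in config.tasks:
        rep = classify_mod.run_binary_task(
            pre,
            task,
            test_fraction=config.test_fraction,
            smote_k=config.smote_k,
            lda_escalation_threshold=config.lda_escalation_threshold,
            seed=config.stage_seed(f"classify:{task}"),
        )
        task_results[task] = {
            "model": rep.model.kind,
            "best_C": rep.model.best_C,
            "best_gamma": rep.model.best_gamma,
            "train": rep.train_metrics.as_dict(),
            "test": rep.test_metrics.as_dict(),
            "params": rep.params,
        }
    _write_json(out / "classification.json", task_results)
    record("classification", out / "classification.json")

    # ---- stage 6: one-class DD-SIMCA -----------------------------------
    target = table.to_numpy()[np.asarray(table.attrs["taxon"]) == "Prototaxites"]
    if config.oneclass_components == "auto":
        candidates = list(range(1, min(5, target.shape[0] - 3) + 1))
        a, sens_report = oneclass_mod.select_components_by_sensitivity(
            target, candidates, alpha=config.oneclass_alpha,
            mode=config.oneclass_mode,
        )
    else:
        a = int(config.oneclass_components)
        sens_report = {}
    model = oneclass_mod.fit_ddsimca(
        target, a, alpha=config.oneclass_alpha, mode=config.oneclass_mode
    )
    aliens = {
        cls: table.to_numpy()[np.asarray(table.attrs["taxon"]) == cls]
        for cls in sorted(set(table.attrs["taxon"])) if cls != "Prototaxites"
    }
    per_class, pooled = oneclass_mod.specificity(model, aliens)
    _write_json(
        out / "oneclass.json",
        {
            "n_components": a,
            "alpha": config.oneclass_alpha,
            "mode": config.oneclass_mode,
            "n_sd": model.n_sd,
            "n_od": model.n_od,
            "c_crit": model.c_crit,
            "loo_sensitivity_by_a": {str(k): v for k, v in sens_report.items()},
            "training_outliers": int(model.training_outlier_flags.sum()),
            "specificity_per_class": per_class,
            "specificity_pooled": pooled,
        },
    )
    record("oneclass", out / "oneclass.json")

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stage_seeds": {
            s: config.stage_seed(s)
            for s in ["simulate", "bootstrap"]
            + [f"classify:{t}" for t in config.tasks]
        },
        "n_samples": len(dataset),
        "n_after_outlier_removal": len(pre),
        "artifacts": artifacts,
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
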
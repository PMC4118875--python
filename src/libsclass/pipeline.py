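"""End-to-end orchestration of the classification experiments.

Ties the stages together in the canonical order — laser-notch masking,
reference-line normalization, per-class dendrogram outlier removal,
optional continuum removal, resampled classifier evaluation — and handles
configuration files, output artifacts and stage logging. The three entry
points mirror how the analysis is actually run:

* :func:`cmd_simulate` — write a labelled synthetic dataset plus its
  generative ground truth;
* :func:`cmd_explore` — PCA variance table, scores, class dendrogram;
* :func:`cmd_run` — the classification experiments (raw and/or
  background-removed) with the comparison p-value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .baseline import BaselineConfig
from .errors import ConfigError
from .evaluation import EvaluationConfig, compare_reports, run_iterations
from .outliers import (
    OutlierRule,
    class_mean_spectra,
    class_similarity_dendrogram,
    detect_outliers_by_class,
    tree_to_json,
    tree_to_newick,
)
from .pca import fit_pca, project, variance_explained
from .spectra import (
    PreprocessConfig,
    SpectraSet,
    apply_notch_mask,
    normalize_to_reference_line,
    read_spectra,
    write_report,
    write_spectra,
)
from .synthetic import (
    NoiseModel,
    default_formulation_profiles,
    default_grid,
    simulate_dataset_with_truth,
)

__all__ = ["PipelineConfig", "cmd_simulate", "cmd_explore", "cmd_run"]

log = logging.getLogger("libsclass")


@dataclass
class PipelineConfig:
    """Everything one experiment needs, round-trippable through YAML."""

    data_path: str | None = None
    label_column: str = "class"
    data_format: str | None = None
    sheet: int | str = 0
    orientation: str = "rows"
    output_dir: str = "results"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    outlier_rule: OutlierRule = field(default_factory=OutlierRule)
    outlier_metric: str = "euclidean"
    outlier_linkage: str = "ward"
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    variant: str = "raw"  # "raw" | "baseline_removed" | "both"
    pca_components: int = 10
    simulate_n_per_class: int = 100
    simulate_seed: int = 0
    noise: NoiseModel = field(default_factory=NoiseModel)
    grid_channels: int = 2068
    grid_lo: float = 350.0
    grid_hi: float = 900.0

    # -- (de)serialization --------------------------------------------

    _NESTED = {
        "preprocess": PreprocessConfig,
        "baseline": BaselineConfig,
        "outlier_rule": OutlierRule,
        "evaluation": EvaluationConfig,
        "noise": NoiseModel,
    }

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                value = dataclasses.asdict(value)
            out[f.name] = value
        return out

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise ConfigError(f"unknown config keys: {', '.join(bad)}")
        kwargs = {}
        for key, value in raw.items():
            nested = cls._NESTED.get(key)
            if nested is not None and isinstance(value, dict):
                try:
                    value = _build_nested(nested, value)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"bad {key!r} section: {exc}") from exc
            kwargs[key] = value
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def grid(self) -> np.ndarray:
        return default_grid(self.grid_channels, self.grid_lo, self.grid_hi)


def _build_nested(cls, value: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    bad = sorted(set(value) - known)
    if bad:
        raise ConfigError(f"unknown keys for {cls.__name__}: {', '.join(bad)}")
    return cls(**value)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage %-22s %.2f s", stage, time.perf_counter() - self.t0)

    return _Timer()


# ---------------------------------------------------------------------------
# Commands
# ---------------------------------------------------------------------------


def cmd_simulate(config: PipelineConfig, out_dir=None) -> dict:
    """Write a synthetic labelled dataset and its ground-truth sidecar."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = default_formulation_profiles()
    with _timed("simulate"):
        dataset, truth = simulate_dataset_with_truth(
            registry,
            config.simulate_n_per_class,
            config.grid(),
            config.noise,
            seed=config.simulate_seed,
        )
    spectra_path = out / "spectra.csv"
    write_spectra(dataset, spectra_path)
    truth_path = out / "truth.json"
    truth_payload = {
        "grid": [float(v) for v in truth["grid"]],
        "gains": [float(v) for v in truth["gains"]],
        "continuum": {k: [float(v) for v in c] for k, c in truth["continuum"].items()},
        "line_centers": truth["line_centers"],
        "line_amplitudes": [[float(v) for v in row] for row in truth["line_amplitudes"]],
    }
    truth_path.write_text(json.dumps(truth_payload))
    log.info("wrote %d spectra to %s", dataset.n_spectra, spectra_path)
    return {"spectra": str(spectra_path), "truth": str(truth_path)}


def _load_and_preprocess(config: PipelineConfig) -> tuple[SpectraSet, dict]:
    """Shared front half: read (or require) data, notch, normalize, outliers."""
    if config.data_path is None:
        raise ConfigError("data_path is not set")
    with _timed("read"):
        spectra = read_spectra(
            config.data_path,
            format_hint=config.data_format,
            label_column=config.label_column,
            sheet=config.sheet,
            orientation=config.orientation,
        )
    log.info("loaded %d spectra, %d channels", spectra.n_spectra, spectra.n_channels)
    with _timed("preprocess"):
        spectra = apply_notch_mask(spectra, config.preprocess)
        spectra = normalize_to_reference_line(spectra, config.preprocess)
    with _timed("outlier removal"):
        flagged = detect_outliers_by_class(
            spectra, config.outlier_rule, config.outlier_metric, config.outlier_linkage
        )
        keep = np.setdiff1d(np.arange(spectra.n_spectra), flagged)
        cleaned = spectra.select(keep)
    log.info(
        "outlier screening: %d in, %d flagged, %d retained",
        spectra.n_spectra, flagged.size, cleaned.n_spectra,
    )
    counts = {
        "n_input": int(spectra.n_spectra),
        "n_outliers": int(flagged.size),
        "n_retained": int(cleaned.n_spectra),
        "outlier_rows": [int(i) for i in flagged],
    }
    return cleaned, counts


def cmd_explore(config: PipelineConfig, out_dir=None) -> dict:
    """PCA summary, score matrix and class-similarity dendrogram files."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra, counts = _load_and_preprocess(config)
    k = min(config.pca_components, spectra.n_spectra - 1, int(spectra.valid_mask.sum()))
    with _timed("pca"):
        model = fit_pca(spectra, k)
        scores = project(model, spectra)
    variance_path = out / "variance_explained.csv"
    with variance_path.open("w") as fh:
        fh.write("component,fraction,cumulative\n")
        for j in range(1, k + 1):
            fh.write(
                f"{j},{model.variance_fractions[j - 1]:.6f},"
                f"{variance_explained(model, j):.6f}\n"
            )
    scores_path = out / "scores.csv"
    with scores_path.open("w") as fh:
        fh.write("class," + ",".join(f"PC{j}" for j in range(1, k + 1)) + "\n")
        for label, row in zip(spectra.labels, scores):
            fh.write(label + "," + ",".join(f"{v:.6g}" for v in row) + "\n")
    with _timed("dendrogram"):
        means = class_mean_spectra(spectra)
        tree = class_similarity_dendrogram(
            means, config.outlier_metric, config.outlier_linkage
        )
    (out / "class_dendrogram.json").write_text(tree_to_json(tree))
    (out / "class_dendrogram.nwk").write_text(tree_to_newick(tree))
    (out / "preprocess_counts.json").write_text(json.dumps(counts, indent=2))
    return {
        "variance": str(variance_path),
        "scores": str(scores_path),
        "dendrogram_json": str(out / "class_dendrogram.json"),
        "dendrogram_newick": str(out / "class_dendrogram.nwk"),
        "counts": counts,
    }


def cmd_run(config: PipelineConfig, out_dir=None) -> dict:
    """Run the classification experiment(s) and write report files.

    ``config.variant`` selects the raw experiment, the background-removed
    experiment, or both (in which case the Welch comparison p-value of
    the per-iteration average correct rates is also written).
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra, counts = _load_and_preprocess(config)
    variants = ["raw", "baseline_removed"] if config.variant == "both" else [config.variant]
    reports = {}
    artifacts: dict = {"counts": counts}
    for variant in variants:
        cfg = dataclasses.replace(config.evaluation, variant=variant)
        with _timed(f"evaluate[{variant}]"):
            report = run_iterations(spectra, cfg)
        reports[variant] = report
        path = out / f"report_{variant}.json"
        write_report(report, path)
        artifacts[variant] = str(path)
        log.info(
            "%s variant: average correct %.3f, misclassified %.3f, unclassified %.3f",
            variant, *report.average_mean,
        )
    if len(reports) == 2:
        p = compare_reports(reports["raw"], reports["baseline_removed"])
        comparison = {
            "raw_average_correct": reports["raw"].average_mean[0],
            "baseline_removed_average_correct": reports["baseline_removed"].average_mean[0],
            "welch_p_value": p,
        }
        (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
        artifacts["comparison"] = str(out / "comparison.json")
        log.info("raw vs baseline-removed Welch p = %.3g", p)
    return artifacts
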
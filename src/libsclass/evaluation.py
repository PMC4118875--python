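"""Resampled evaluation: stratified 70/30 splits, many iterations, rates.

The protocol mirrors standard chemometric validation of small spectral
datasets: the data are repeatedly re-split into stratified training (70%)
and test (30%) sets, the chosen classifier is refitted from scratch on
every training split, and the per-class correct / misclassified /
unclassified rates on the held-out spectra are averaged over iterations
(default 100), with standard deviations quantifying split-to-split
variability. The unweighted mean over classes is reported as the average
row.

Two preprocessing variants are supported — raw spectra, and spectra with
the continuum background removed — so the information content of the
continuum itself can be assessed by comparing the two resulting reports
with a Welch two-sample t test on the per-iteration average correct
rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .baseline import BaselineConfig, batch_correct
from .classifiers import fit_ann, fit_plsda, predict_ann, predict_plsda
from .errors import ClassSizeError, DimensionError
from .pca import fit_pca, project
from .simca import ClassificationOutcome, SIMCAConfig, classify_set, fit_simca
from .spectra import SpectraSet

__all__ = [
    "EvaluationConfig",
    "EvaluationReport",
    "stratified_split",
    "rates_from_outcomes",
    "run_iterations",
    "compare_reports",
]

_VERDICTS = ("correct", "misclassified", "unclassified")


@dataclass(frozen=True)
class EvaluationConfig:
    """One evaluation experiment: split protocol, classifier, variant."""

    train_fraction: float = 0.70
    n_iterations: int = 100
    base_seed: int = 0
    classifier: str = "simca"  # "simca" | "plsda" | "ann"
    variant: str = "raw"  # "raw" | "baseline_removed"
    simca: SIMCAConfig = field(default_factory=SIMCAConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    plsda_n_latent: int | None = None
    plsda_max_latent: int = 10
    ann_width: int = 8
    ann_epochs: int = 800
    ann_pca_components: int = 10

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.classifier not in ("simca", "plsda", "ann"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.variant not in ("raw", "baseline_removed"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class EvaluationReport:
    """Mean and sd of the rate trichotomy per class and on average."""

    classes: tuple[str, ...]
    per_class_mean: dict  # class -> (correct, misclassified, unclassified)
    per_class_sd: dict
    average_mean: tuple[float, float, float]
    average_sd: tuple[float, float, float]
    per_iteration_average_correct: np.ndarray
    config: dict

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "per_class_mean": {c: list(v) for c, v in self.per_class_mean.items()},
            "per_class_sd": {c: list(v) for c, v in self.per_class_sd.items()},
            "average_mean": list(self.average_mean),
            "average_sd": list(self.average_sd),
            "per_iteration_average_correct": [
                float(v) for v in self.per_iteration_average_correct
            ],
            "config": self.config,
        }


def stratified_split(
    spectra: SpectraSet,
    train_fraction: float = 0.70,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; round-half-up of ``n_c * fraction`` to train.

    Every class contributes at least one row to each side. The split is
    disjoint and exhaustive, and deterministic given the rng state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for name in spectra.classes:
        idx = spectra.class_indices(name)
        n_c = idx.size
        if n_c < 2:
            raise ClassSizeError(
                f"class {name!r} has a single row and cannot be split",
                class_name=name,
            )
        n_train = int(np.floor(n_c * train_fraction + 0.5))
        n_train = min(max(n_train, 1), n_c - 1)
        perm = rng.permutation(n_c)
        train_idx.extend(int(i) for i in idx[perm[:n_train]])
        test_idx.extend(int(i) for i in idx[perm[n_train:]])
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def rates_from_outcomes(outcomes: list[ClassificationOutcome]) -> dict:
    """Per-class verdict fractions plus their unweighted class average."""
    if not outcomes:
        raise DimensionError("no outcomes to summarize")
    by_class: dict[str, list[str]] = {}
    for o in outcomes:
        by_class.setdefault(o.true_class, []).append(o.verdict)
    rates: dict[str, tuple[float, float, float]] = {}
    for name, verdicts in by_class.items():
        n = len(verdicts)
        rates[name] = tuple(verdicts.count(v) / n for v in _VERDICTS)
    triples = np.array([rates[c] for c in rates])
    rates["average"] = tuple(float(v) for v in triples.mean(axis=0))
    return rates


def _predict_outcomes(cfg, train, test) -> list[ClassificationOutcome]:
    if cfg.classifier == "simca":
        model = fit_simca(train, cfg.simca)
        return classify_set(model, test)
    if cfg.classifier == "plsda":
        model = fit_plsda(
            train, n_latent=cfg.plsda_n_latent, max_latent=cfg.plsda_max_latent
        )
        assigned = predict_plsda(model, test)
    else:  # ann on global PCA scores
        k = min(cfg.ann_pca_components, train.n_spectra - 1,
                int(train.valid_mask.sum()))
        pca = fit_pca(train, k)
        model = fit_ann(
            project(pca, train), train.labels, width=cfg.ann_width,
            seed=cfg.base_seed, epochs=cfg.ann_epochs,
        )
        assigned = predict_ann(model, project(pca, test))
    return [
        ClassificationOutcome(
            true_class=t,
            accepted_classes=frozenset((a,)),
            assigned_class=a,
            verdict="correct" if a == t else "misclassified",
        )
        for t, a in zip(test.labels, assigned)
    ]


def run_iterations(spectra: SpectraSet, cfg: EvaluationConfig) -> EvaluationReport:
    """Run the full resampled evaluation; bit-reproducible under base_seed.

    For the ``baseline_removed`` variant the continuum is estimated and
    subtracted once for the whole dataset before any splitting, matching
    a preprocessing step applied uniformly to all spectra.
    """
    if cfg.variant == "baseline_removed":
        spectra = batch_correct(spectra, cfg.baseline)
    classes = spectra.classes
    per_iter = {c: [] for c in classes}
    avg_correct = []
    avg_triples = []
    for i in range(1, cfg.n_iterations + 1):
        rng = np.random.default_rng(cfg.base_seed + i)
        try:
            train_idx, test_idx = stratified_split(spectra, cfg.train_fraction, rng)
            outcomes = _predict_outcomes(
                cfg, spectra.select(train_idx), spectra.select(test_idx)
            )
        except Exception as exc:
            raise RuntimeError(f"evaluation iteration {i} failed: {exc}") from exc
        rates = rates_from_outcomes(outcomes)
        for c in classes:
            per_iter[c].append(rates[c])
        avg_triples.append(rates["average"])
        avg_correct.append(rates["average"][0])

    per_class_mean, per_class_sd = {}, {}
    for c in classes:
        arr = np.array(per_iter[c])
        per_class_mean[c] = tuple(float(v) for v in arr.mean(axis=0))
        per_class_sd[c] = tuple(float(v) for v in arr.std(axis=0, ddof=0))
    avg_arr = np.array(avg_triples)
    return EvaluationReport(
        classes=tuple(classes),
        per_class_mean=per_class_mean,
        per_class_sd=per_class_sd,
        average_mean=tuple(float(v) for v in avg_arr.mean(axis=0)),
        average_sd=tuple(float(v) for v in avg_arr.std(axis=0, ddof=0)),
        per_iteration_average_correct=np.array(avg_correct),
        config={
            "train_fraction": cfg.train_fraction,
            "n_iterations": cfg.n_iterations,
            "base_seed": cfg.base_seed,
            "classifier": cfg.classifier,
            "variant": cfg.variant,
        },
    )


def compare_reports(a: EvaluationReport, b: EvaluationReport) -> float:
    """Welch two-sample t test on per-iteration average correct rates.

    Returns the two-tailed p-value; identical degenerate vectors (zero
    variance on both sides, equal means) give 1.0 by convention.
    """
    x = np.asarray(a.per_iteration_average_correct, dtype=float)
    y = np.asarray(b.per_iteration_average_correct, dtype=float)
    if x.std() == 0.0 and y.std() == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    result = stats.ttest_ind(x, y, equal_var=False)
    return float(result.pvalue)
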
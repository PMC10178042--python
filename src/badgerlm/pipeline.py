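"""End-to-end experiment driver: spectra -> preprocessing -> split -> model -> tables.

Reproduces the study protocol: load or generate labeled spectra, apply one
preprocessing treatment (none / min-max / MSC / SNV; MSC statistics fitted on
the training partition only), split 3:1 stratified per class, then train
either a plain ELM or an ELM whose hidden parameters are chosen by a
metaheuristic (GA / HBA / tHBA) minimising the misclassification rate of an
evaluation partition, and finally score the held-out test set.

Fitness evaluation set: the historical protocol scored optimizer candidates
directly on the test set (``test_paper_mode``); the default ``validation``
mode carves an internal stratified 80/20 validation split out of the training
set so that test labels never influence model selection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as prep
from .elm import ELMConfig, elm_predict, elm_train, pack_position, unpack_position
from .metrics import MetricsReport, confusion, per_class_metrics
from .optimizers import (
    GAConfig,
    HBAConfig,
    OptimizerRun,
    SearchSpace,
    THBAConfig,
    ga_optimize,
    hba_optimize,
    thba_optimize,
)
from .synthetic import (
    LabeledSpectra,
    SpectraConfig,
    generate_spectra,
    read_csv,
    stratified_split,
)

logger = logging.getLogger("badgerlm")

PREPROCESSORS = ("none", "nm", "msc", "snv")
OPTIMIZERS = ("none", "ga", "hba", "thba")

#: hidden-layer sizes used in the study: 135 for the plain ELM benchmark,
#: 120 for every metaheuristic-optimized ELM
DEFAULT_L_PLAIN = 135
DEFAULT_L_OPTIMIZED = 120


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of one experiment; ``seed`` drives all stochastic stages."""

    data_source: str = "synthetic"  # "synthetic" or a CSV path
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    preprocessing: str = "nm"
    train_fraction: float = 0.75
    n_hidden: int | None = None  # default: 135 plain, 120 optimized
    optimizer: str = "none"
    pop_size: int = 50
    max_iter: int = 300
    mutation_prob: float = 0.8
    fitness_eval_set: str = "validation"  # or "test_paper_mode"
    validation_fraction: float = 0.2  # of the training set, validation mode only
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.preprocessing not in PREPROCESSORS:
            raise ValueError(f"preprocessing must be one of {PREPROCESSORS}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if self.fitness_eval_set not in ("validation", "test_paper_mode"):
            raise ValueError("fitness_eval_set must be 'validation' or 'test_paper_mode'")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")

    @property
    def resolved_n_hidden(self) -> int:
        if self.n_hidden is not None:
            return self.n_hidden
        return DEFAULT_L_PLAIN if self.optimizer == "none" else DEFAULT_L_OPTIMIZED

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


class FitnessAdapter:
    """Maps a packed (omega, bias) position to an eval-set error rate in [0, 1].

    Deterministic given the position: the hidden parameters are fully supplied,
    so ELM training reduces to one least-squares solve.
    """

    def __init__(self, train_X, train_y, eval_X, eval_y, n_hidden: int,
                 weight_low: float = -1.0, weight_high: float = 1.0):
        self.train_X = np.asarray(train_X, dtype=float)
        self.train_y = np.asarray(train_y)
        self.eval_X = np.asarray(eval_X, dtype=float)
        self.eval_y = np.asarray(eval_y)
        self.d = self.train_X.shape[1]
        self.L = n_hidden
        self.elm_config = ELMConfig(n_hidden=n_hidden, weight_low=weight_low,
                                    weight_high=weight_high)
        self.space = SearchSpace.cube(self.d * self.L + self.L, weight_low, weight_high)
        self.n_calls = 0

    def __call__(self, position: np.ndarray) -> float:
        omega, bias = unpack_position(position, self.d, self.L)
        model = elm_train(self.train_X, self.train_y, self.elm_config, omega=omega, bias=bias)
        pred = elm_predict(model, self.eval_X)
        self.n_calls += 1
        return float(np.mean(pred != self.eval_y))


def make_fitness(train: LabeledSpectra, eval_set: LabeledSpectra, n_hidden: int) -> FitnessAdapter:
    """Fitness = misclassification rate on ``eval_set`` of an ELM with the
    hidden layer decoded from the position and trained on ``train``."""
    return FitnessAdapter(train.reflectance, train.labels,
                          eval_set.reflectance, eval_set.labels, n_hidden)


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def apply_preprocessing(
    train: LabeledSpectra, test: LabeledSpectra, method: str
) -> tuple[LabeledSpectra, LabeledSpectra]:
    """Apply a treatment to both partitions; MSC fits its reference on train only."""
    if method == "none":
        return train, test
    if method == "nm":
        f = prep.normalize_minmax
        return (train.replace(reflectance=f(train.reflectance)),
                test.replace(reflectance=f(test.reflectance)))
    if method == "snv":
        return (train.replace(reflectance=prep.snv(train.reflectance)),
                test.replace(reflectance=prep.snv(test.reflectance)))
    if method == "msc":
        ref = prep.fit_msc(train.reflectance)
        return (train.replace(reflectance=prep.apply_msc(train.reflectance, ref)),
                test.replace(reflectance=prep.apply_msc(test.reflectance, ref)))
    raise ValueError(f"unknown preprocessing {method!r}")


@dataclass
class ExperimentResult:
    config: PipelineConfig
    report: MetricsReport
    confusion: "np.ndarray"
    test_accuracy: float
    optimizer_run: OptimizerRun | None
    model: object
    split_fingerprint: int  # hash of the train/test partition, for pairing checks


def _load_spectra(config: PipelineConfig, seed: int) -> LabeledSpectra:
    if config.data_source == "synthetic":
        return generate_spectra(dataclasses.replace(config.spectra, seed=seed))
    return read_csv(config.data_source)


def run_experiment(config: PipelineConfig) -> ExperimentResult:
    """Execute the full stage chain and (optionally) write run artifacts."""
    config.validate()
    gen_seed, split_seed, val_seed, elm_seed, opt_seed = _subseeds(config.seed, 5)
    try:
        spectra = _load_spectra(config, gen_seed)
    except Exception as e:
        raise RuntimeError(f"[load] {e}") from e

    try:
        train, test = stratified_split(spectra, config.train_fraction, split_seed)
        train, test = apply_preprocessing(train, test, config.preprocessing)
    except Exception as e:
        raise RuntimeError(f"[preprocess/split] {e}") from e

    fingerprint = hash((train.reflectance.tobytes(), test.reflectance.tobytes()))
    L = config.resolved_n_hidden
    run: OptimizerRun | None = None

    try:
        if config.optimizer == "none":
            model = elm_train(train.reflectance, train.labels, ELMConfig(n_hidden=L, seed=elm_seed))
        else:
            if config.fitness_eval_set == "validation":
                fit_train, fit_eval = stratified_split(
                    train, 1.0 - config.validation_fraction, val_seed
                )
            else:  # historical protocol: optimizer candidates scored on the test set
                fit_train, fit_eval = train, test
            adapter = make_fitness(fit_train, fit_eval, L)
            if config.optimizer == "hba":
                run = hba_optimize(adapter, adapter.space, HBAConfig(
                    pop_size=config.pop_size, max_iter=config.max_iter, seed=opt_seed))
            elif config.optimizer == "thba":
                run = thba_optimize(adapter, adapter.space, THBAConfig(
                    pop_size=config.pop_size, max_iter=config.max_iter,
                    mutation_prob=config.mutation_prob, seed=opt_seed))
            else:
                run = ga_optimize(adapter, adapter.space, GAConfig(
                    pop_size=config.pop_size, max_iter=config.max_iter, seed=opt_seed))
            omega, bias = unpack_position(run.best_position, train.n_channels, L)
            # best (omega, b) re-fitted on the full training partition
            model = elm_train(train.reflectance, train.labels,
                              ELMConfig(n_hidden=L, seed=elm_seed), omega=omega, bias=bias)
    except Exception as e:
        raise RuntimeError(f"[train] {e}") from e

    pred = elm_predict(model, test.reflectance)
    cm = confusion(test.labels, pred, len(test.class_names), test.class_names)
    report = per_class_metrics(cm)
    result = ExperimentResult(
        config=config,
        report=report,
        confusion=cm.counts,
        test_accuracy=report.overall_accuracy_global,
        optimizer_run=run,
        model=model,
        split_fingerprint=fingerprint,
    )
    if config.output_dir is not None:
        _write_artifacts(result, cm, config)
    return result


def _write_artifacts(result: ExperimentResult, cm, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = _model_name(config)
    result.report.write_csv(out / "metrics.csv", model=name)
    cm.write_csv(out / "confusion.csv")
    if result.optimizer_run is not None:
        result.optimizer_run.write_trace(out / "trace.csv")
    manifest = dataclasses.asdict(config.replace(spectra=config.spectra))
    manifest["spectra"] = dataclasses.asdict(config.spectra)
    manifest["model_name"] = name
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("wrote artifacts for %s to %s", name, out)


def _model_name(config: PipelineConfig) -> str:
    pre = {"none": "", "nm": "NM-", "msc": "MSC-", "snv": "SNV-"}[config.preprocessing]
    opt = {"none": "", "ga": "GA-", "hba": "HBA-", "thba": "tHBA-"}[config.optimizer]
    return f"{pre}{opt}ELM"


def compare_models(
    base_config: PipelineConfig, models: list[str], seeds: list[int]
) -> pd.DataFrame:
    """Run each optimizer setting on identical per-seed splits; summary table.

    Every model sees exactly the same generated data and partition for a given
    seed (paired comparison), which the split fingerprint makes checkable.
    """
    if not models or not seeds:
        raise ValueError("need at least one model and one seed")
    rows = []
    for seed in seeds:
        for m in models:
            if m not in OPTIMIZERS and m != "elm":
                raise ValueError(f"unknown model {m!r}")
            opt = "none" if m == "elm" else m
            cfg = base_config.replace(optimizer=opt, seed=seed, output_dir=None)
            res = run_experiment(cfg)
            rows.append(
                {
                    "model": m,
                    "seed": seed,
                    "test_accuracy": res.test_accuracy,
                    "macro_f1": res.report.overall_f1,
                    "split_fingerprint": res.split_fingerprint,
                    "best_fitness": (res.optimizer_run.best_fitness
                                     if res.optimizer_run else np.nan),
                }
            )
    df = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(models)}
    summary = (
        df.groupby("model")
        .agg(mean_accuracy=("test_accuracy", "mean"), sd_accuracy=("test_accuracy", "std"),
             mean_f1=("macro_f1", "mean"))
        .reset_index()
        .sort_values(by="model", key=lambda s: s.map(order))
        .reset_index(drop=True)
    )
    summary.attrs["per_seed"] = df
    return summary
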
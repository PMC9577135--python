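"""The iterative active-learning (AL) pipeline and its random-learning (RL)
control.

One experiment: a bootstrap training set D0 of 4 ROIs is drawn at random from
the training pool and used to train classifier C0 from scratch. At each
iteration the current classifier segments the never-selected remainder of the
pool; each predicted tissue map receives a quality-assurance grade of 0-5 per
class present in its ground truth (here produced by a simulated pathologist:
the per-image, per-class Dice mapped to round(5*dice), optionally perturbed
by integer Gaussian noise); the 4 worst-graded ROIs are promoted into the
training set, and the classifier is retrained from fresh initialization. The
RL control is identical except the 4 promoted ROIs are drawn uniformly at
random, and it is run in triplicate; AL and every RL batch share D0, so the
comparison is always at matched training-set size. Final per-class holdout
Dice of AL is compared against the RL-batch mean with a two-sided paired
Wilcoxon signed-rank test.

All randomness derives from one experiment seed through named SeedSequence
streams (bootstrap, per-iteration model init, validation split, RL batch
draws, oracle noise), so the whole multi-stream experiment is reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .legend import ClassLegend, CohortSplit, LabelMap
from .metrics import (
    ConfusionCounts,
    MetricsReport,
    accumulate_confusion,
    build_report,
    dice_per_class,
)
from .preprocessing import compute_stats
from .unet import ModelSpec, TrainConfig, build_model, predict_tissue_map, train

__all__ = [
    "OracleConfig",
    "QaGrade",
    "IterationRecord",
    "ExperimentResult",
    "derive_seed",
    "bootstrap_selection",
    "oracle_grade",
    "select_lowest",
    "run_al",
    "run_rl",
    "compare_strategies",
    "run_experiment",
]


class PipelineError(ValueError):
    pass


@dataclass
class OracleConfig:
    """Simulated pathologist: grade = round(5 * per-class Dice) +- noise."""

    noise_sd: float = 0.0


@dataclass
class QaGrade:
    roi_id: str
    per_class_grade: dict  # class index -> int 0..5 (classes present in truth)
    aggregate: float  # unweighted mean of per-class grades

    def __post_init__(self):
        if any(not 0 <= g <= 5 for g in self.per_class_grade.values()):
            raise PipelineError("grades must lie in 0..5")


@dataclass
class IterationRecord:
    """State of one AL/RL round: training set D_i, classifier C_i's holdout
    report, the grades C_i assigned to the remaining pool, and the ROIs it
    selected for D_{i+1} (empty at the last iteration)."""

    iteration: int
    strategy: str  # "AL" | "RL"
    batch_id: int
    training_ids: frozenset
    selected_ids: tuple
    grades: list
    report: MetricsReport
    final_train_loss: float
    final_val_loss: float
    gt_pixels_added: int  # non-avoid pixels in the ROIs newly added to D_i


@dataclass
class ExperimentResult:
    al_records: list
    rl_records: list  # one list of IterationRecords per RL batch
    rl_mean: dict = field(default_factory=dict)
    rl_std: dict = field(default_factory=dict)
    per_class_delta: dict = field(default_factory=dict)
    mean_dice_delta: float = float("nan")
    comparison_p: float | None = None
    comparison_note: str = ""


def derive_seed(master: int, *tags) -> int:
    """Named child seed (< 2**31) from one experiment master seed."""
    ints = [int(master) & 0x7FFFFFFF]
    for t in tags:
        ints.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31))


def bootstrap_selection(pool, n: int = 4, seed: int = 0) -> set:
    """Uniform draw of ``n`` ROI ids without replacement; seed-deterministic."""
    pool = sorted(pool)
    if n > len(pool):
        raise PipelineError(f"cannot select {n} from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    return set(rng.choice(pool, size=n, replace=False).tolist())


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def oracle_grade(
    pred: LabelMap,
    truth: LabelMap,
    legend: ClassLegend,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> QaGrade:
    """Grade one predicted tissue map against its ground truth.

    For every class present in the truth (avoid excluded), the per-image Dice
    d_c maps to the integer grade round(5 * d_c); optional Gaussian noise is
    rounded to an integer and the sum clamped to 0..5. 5 means an essentially
    perfect segmentation of that class, 0 a useless one.
    """
    t = truth.indices if isinstance(truth, LabelMap) else np.asarray(truth)
    if not (t != legend.avoid_index).any():
        raise PipelineError("ground truth entirely avoid-class: ungradeable")
    counts = accumulate_confusion(pred, truth, legend, ConfusionCounts(legend.n_classes))
    dice, _ = dice_per_class(counts)
    present = set(np.unique(t[t != legend.avoid_index]).tolist())
    rng = np.random.default_rng(seed)
    grades = {}
    for c in sorted(present):
        g = _round_half_up(5.0 * dice.get(c, 0.0))
        if noise_sd > 0:
            g += _round_half_up(rng.normal(0.0, noise_sd))
        grades[c] = int(np.clip(g, 0, 5))
    roi_id = getattr(pred, "roi_id", "")
    return QaGrade(roi_id=roi_id, per_class_grade=grades,
                   aggregate=float(np.mean(list(grades.values()))))


def select_lowest(grades, k: int = 4):
    """The k ROI ids with the lowest aggregate grade; ties break by roi_id."""
    if not grades:
        raise PipelineError("no grades to select from")
    if k < 1:
        raise PipelineError("k must be >= 1")
    ranked = sorted(grades, key=lambda g: (g.aggregate, g.roi_id))
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} candidates remain; selecting all")
    return [g.roi_id for g in ranked[:k]]


def _validation_ids(training_ids, fraction: float, seed: int) -> frozenset:
    ids = sorted(training_ids)
    n_val = max(1, int(round(fraction * len(ids))))
    n_val = min(n_val, len(ids) - 1)  # always leave something to fit
    rng = np.random.default_rng(seed)
    return frozenset(rng.choice(ids, size=n_val, replace=False).tolist())


def _gt_pixels(samples_by_id, ids, avoid_index: int) -> int:
    return int(
        sum((samples_by_id[i].labels.indices != avoid_index).sum() for i in ids)
    )


def _run_strategy(
    cohort,
    split: CohortSplit,
    model_spec: ModelSpec,
    train_config: TrainConfig,
    n_iterations: int,
    seed: int,
    strategy: str,
    batch_id: int = 0,
    oracle: OracleConfig | None = None,
    n_bootstrap: int = 4,
    k_per_iter: int = 4,
    val_fraction: float = 0.25,
    stats=None,
    legend: ClassLegend | None = None,
):
    oracle = oracle or OracleConfig()
    samples = {s.roi_id: s for s in cohort}
    legend = legend or cohort[0].labels.legend
    avoid = legend.avoid_index
    holdout = [samples[i] for i in sorted(split.holdout_ids)]
    pool = set(split.train_pool_ids)
    if stats is None:
        stats = compute_stats([samples[i] for i in sorted(pool)])

    d_i = bootstrap_selection(pool, n_bootstrap, derive_seed(seed, "bootstrap"))
    remaining = pool - d_i
    records = []
    selected = tuple(sorted(d_i))
    for i in range(n_iterations + 1):
        tag = f"{i}{strategy}" if i > 0 else "C0"
        # C0 is the same classifier for AL and every RL batch (identical D0,
        # init, shuffle order, and validation split); later iterations derive
        # their own streams per strategy and batch.
        s_tag, b_tag = ("shared", 0) if i == 0 else (strategy, batch_id)
        cfg = TrainConfig(
            epochs=train_config.epochs,
            learning_rate=train_config.learning_rate,
            batch_size=train_config.batch_size,
            seed=derive_seed(seed, "train", s_tag, b_tag, i),
            optimizer_name=train_config.optimizer_name,
            validation_ids=_validation_ids(
                d_i, val_fraction, derive_seed(seed, "val", s_tag, b_tag, i)
            ),
        )
        model = build_model(
            model_spec, derive_seed(seed, "init", s_tag, b_tag, i), version_tag=tag
        )
        train(model, [samples[r] for r in sorted(d_i)], cfg, stats, avoid_index=avoid)
        report = build_report(holdout, model, stats, legend, version_tag=tag)

        grades = []
        next_selected: tuple = ()
        if i < n_iterations and remaining:
            if strategy == "AL":
                for rid in sorted(remaining):
                    pred = predict_tissue_map(model, samples[rid], stats)
                    g = oracle_grade(
                        pred,
                        samples[rid].labels,
                        legend,
                        noise_sd=oracle.noise_sd,
                        seed=derive_seed(seed, "oracle", i, rid),
                    )
                    g.roi_id = rid
                    grades.append(g)
                next_selected = tuple(select_lowest(grades, k_per_iter))
            else:
                rng = np.random.default_rng(derive_seed(seed, "rl", batch_id, i))
                picks = sorted(remaining)
                take = min(k_per_iter, len(picks))
                next_selected = tuple(
                    sorted(rng.choice(picks, size=take, replace=False).tolist())
                )
        records.append(
            IterationRecord(
                iteration=i,
                strategy=strategy,
                batch_id=batch_id,
                training_ids=frozenset(d_i),
                selected_ids=selected,
                grades=grades,
                report=report,
                final_train_loss=model.train_history[-1][0],
                final_val_loss=model.train_history[-1][1],
                gt_pixels_added=_gt_pixels(samples, selected, avoid),
            )
        )
        if i < n_iterations:
            if not next_selected:
                warnings.warn("training pool exhausted; stopping early")
                break
            d_i = d_i | set(next_selected)
            remaining -= set(next_selected)
            selected = next_selected
    return records


def run_al(
    cohort,
    split: CohortSplit,
    model_spec: ModelSpec,
    train_config: TrainConfig,
    n_iterations: int = 3,
    seed: int = 0,
    oracle: OracleConfig | None = None,
    **kw,
):
    """Run the QA-grade-driven pipeline; returns one IterationRecord per
    classifier version C0..C_n."""
    return _run_strategy(
        cohort, split, model_spec, train_config, n_iterations, seed,
        strategy="AL", oracle=oracle, **kw,
    )


def run_rl(
    cohort,
    split: CohortSplit,
    model_spec: ModelSpec,
    train_config: TrainConfig,
    n_iterations: int = 3,
    n_batches: int = 3,
    seed: int = 0,
    **kw,
):
    """Run the random-selection control ``n_batches`` times.

    Every batch shares the AL bootstrap set D0 (same derived bootstrap seed)
    and draws its 4 promotions uniformly without replacement from the
    never-selected pool.
    """
    return [
        _run_strategy(
            cohort, split, model_spec, train_config, n_iterations, seed,
            strategy="RL", batch_id=b, **kw,
        )
        for b in range(n_batches)
    ]


def compare_strategies(al_records, rl_batches) -> ExperimentResult:
    """Compare final AL holdout Dice against the mean of the RL batches.

    Pairs per-class Dice (classes defined in the AL report and every RL
    batch) and reports a two-sided paired Wilcoxon signed-rank p-value plus
    the mean-Dice delta. Fewer than 3 paired classes skips the test.
    """
    al_final = al_records[-1].report
    rl_finals = [b[-1].report for b in rl_batches]
    common = set(al_final.dice)
    for r in rl_finals:
        common &= set(r.dice)
    rl_mean_dice = {
        c: float(np.mean([r.dice[c] for r in rl_finals])) for c in sorted(common)
    }
    deltas = {c: al_final.dice[c] - rl_mean_dice[c] for c in sorted(common)}

    note = ""
    p = None
    diff = np.array(list(deltas.values()))
    if len(diff) < 3:
        note = f"only {len(diff)} paired classes; test skipped"
    elif np.allclose(diff, 0):
        p = 1.0
    else:
        p = float(sps.wilcoxon(diff, alternative="two-sided").pvalue)

    # per-iteration summaries across RL batches
    n_iter = min(len(b) for b in rl_batches)
    rl_mean = {
        "mean_dice": [
            float(np.mean([b[i].report.mean_dice for b in rl_batches]))
            for i in range(n_iter)
        ],
        "final_val_loss": [
            float(np.mean([b[i].final_val_loss for b in rl_batches]))
            for i in range(n_iter)
        ],
    }
    rl_std = {
        "mean_dice": [
            float(np.std([b[i].report.mean_dice for b in rl_batches]))
            for i in range(n_iter)
        ],
        "final_val_loss": [
            float(np.std([b[i].final_val_loss for b in rl_batches]))
            for i in range(n_iter)
        ],
    }
    rl_final_mean = float(np.mean(list(rl_mean_dice.values()))) if rl_mean_dice else float("nan")
    al_mean_over_common = (
        float(np.mean([al_final.dice[c] for c in rl_mean_dice])) if rl_mean_dice else float("nan")
    )
    return ExperimentResult(
        al_records=al_records,
        rl_records=rl_batches,
        rl_mean=rl_mean,
        rl_std=rl_std,
        per_class_delta=deltas,
        mean_dice_delta=al_mean_over_common - rl_final_mean,
        comparison_p=p,
        comparison_note=note,
    )


def run_experiment(
    cohort,
    split: CohortSplit,
    model_spec: ModelSpec,
    train_config: TrainConfig,
    n_iterations: int = 3,
    n_rl_batches: int = 3,
    seed: int = 0,
    oracle: OracleConfig | None = None,
    **kw,
) -> ExperimentResult:
    """AL run + triplicate RL control + comparison, all from one seed."""
    samples = {s.roi_id: s for s in cohort}
    stats = compute_stats([samples[i] for i in sorted(split.train_pool_ids)])
    al = run_al(
        cohort, split, model_spec, train_config, n_iterations, seed,
        oracle=oracle, stats=stats, **kw,
    )
    rl = run_rl(
        cohort, split, model_spec, train_config, n_iterations, n_rl_batches,
        seed, stats=stats, **kw,
    )
    return compare_strategies(al, rl)
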
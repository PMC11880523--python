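"""Orchestration of the label-noise experiments.

Two protocols are provided:

* :func:`run_three_arm` — at one noise proportion rho, compare a classifier
  trained on the noisy BL/AL labels, on the SSL-derived G1/G2 labels, and
  on the intersection subset (rows where both label sets agree), all tested
  against the noisy BL/AL labels of the held-out folds.
* :func:`run_noise_sweep` — sweep rho over 0..0.5 and trace three curves:
  an ideal arm trained on clean class labels, a noisy arm trained on the
  mixed labels, and the SSL-relabeled arm.

Accuracies are compared with Welch's unequal-variance t-test over the
cross-validation folds (or over seeds in the sweep), with the usual
significance stars at 0.05/0.01/0.001/0.0001.

A global ``scale`` factor shrinks the full protocol (10,000 windows per
class, 500 SSL epochs, 200 CNN epochs) to desk scale while keeping every
ratio of the design intact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import CNNConfig, CVResult, cross_validate
from .relabel import AugmentationConfig, EncoderConfig, RelabelResult, relabel_dataset
from .simulate import LabeledDataset, SimConfig, generate_dataset, inject_label_noise

__all__ = [
    "ComparisonStat",
    "ThreeArmResult",
    "SweepRow",
    "FULL_N_PER_CLASS",
    "welch_t_test",
    "significance_stars",
    "scaled_configs",
    "run_three_arm",
    "run_noise_sweep",
    "sweep_to_frame",
    "report",
]

#: Full-protocol problem size: 10,000 windows per class (20,000 total).
FULL_N_PER_CLASS = 10_000


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ComparisonStat:
    """Welch t-test between two arms' accuracy samples."""

    arm_a: str
    arm_b: str
    t: float
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)

    def to_dict(self) -> dict:
        return {
            "arm_a": self.arm_a,
            "arm_b": self.arm_b,
            "t": self.t,
            "p": self.p,
            "stars": self.stars,
        }


def welch_t_test(a, b, arm_a: str = "a", arm_b: str = "b") -> ComparisonStat:
    """Two-sided Welch (unequal-variance) t-test on accuracy samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return ComparisonStat(arm_a, arm_b, 0.0, 1.0)
        raise ValueError("both groups have zero variance; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonStat(arm_a, arm_b, float(t), float(p))


def scaled_configs(
    scale: float = 1.0,
    seed: int = 0,
    sim: SimConfig | None = None,
    ssl: EncoderConfig | None = None,
    cnn: CNNConfig | None = None,
) -> tuple[int, SimConfig, EncoderConfig, CNNConfig]:
    """Shrink the full protocol by ``scale`` while keeping its ratios.

    ``scale`` multiplies the per-class sample count and both epoch budgets
    (minimum 1 each); model widths are untouched.  Returns
    ``(n_per_class, sim_config, ssl_config, cnn_config)``.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    sim = sim or SimConfig(seed=seed)
    ssl = ssl or EncoderConfig(seed=seed)
    cnn = cnn or CNNConfig(seed=seed)
    n_per_class = max(10, int(round(FULL_N_PER_CLASS * scale)))
    ssl = replace(ssl, epochs=max(1, int(round(ssl.epochs * scale))))
    cnn = replace(cnn, epochs=max(1, int(round(cnn.epochs * scale))))
    return n_per_class, sim, ssl, cnn


@dataclass
class ThreeArmResult:
    """Outcome of the fixed-rho comparison."""

    rho: float
    arms: dict[str, CVResult]
    stats: list[ComparisonStat]
    relabel: RelabelResult
    agreement_with_truth: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "arms": {k: v.to_dict() for k, v in self.arms.items()},
            "stats": [s.to_dict() for s in self.stats],
            "composition": self.relabel.composition.tolist(),
            "agreement_with_truth": self.agreement_with_truth,
        }


def _label_agreement(dataset: LabeledDataset, labels: np.ndarray) -> float:
    """Fraction of rows where a label vector matches the hidden true class.

    Group labels are compared under the better of the two group-to-class
    mappings, since cluster naming is arbitrary with respect to the truth.
    """
    match = float(np.mean(labels == dataset.true_class))
    return max(match, 1.0 - match)


def run_three_arm(
    rho: float,
    n_per_class: int = FULL_N_PER_CLASS,
    sim: SimConfig = SimConfig(),
    ssl: EncoderConfig = EncoderConfig(),
    cnn: CNNConfig = CNNConfig(),
    aug: AugmentationConfig = AugmentationConfig(),
    cv_seed: int = 0,
    arms: tuple[str, ...] = ("original", "ssl_groups", "intersection"),
    progress: bool = False,
) -> ThreeArmResult:
    """Generate data at ``rho``, relabel, and cross-validate every arm."""
    clean = generate_dataset(n_per_class, config=sim)
    noisy = inject_label_noise(
        clean, rho, np.random.default_rng((sim.seed, int(round(1000 * rho))))
    )
    relabel_result, _, _ = relabel_dataset(noisy, ssl, aug, progress=progress)
    results: dict[str, CVResult] = {}
    for arm in arms:
        results[arm] = cross_validate(
            noisy, arm, cnn, relabel_result=relabel_result, seed=cv_seed
        )
    pair_stats = []
    names = list(results)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair_stats.append(
                welch_t_test(
                    results[names[i]].per_fold_accuracy,
                    results[names[j]].per_fold_accuracy,
                    names[i],
                    names[j],
                )
            )
    agreement = {
        "observed": _label_agreement(noisy, np.asarray(noisy.observed_label)),
        "ssl_groups": _label_agreement(noisy, relabel_result.group),
    }
    return ThreeArmResult(rho, results, pair_stats, relabel_result, agreement)


@dataclass
class SweepRow:
    """One (rho, arm, seed) cell of the noise sweep."""

    rho: float
    arm: str
    seed: int
    cv: CVResult
    agreement_with_truth: float


def run_noise_sweep(
    rhos=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    n_per_class: int = FULL_N_PER_CLASS,
    sim: SimConfig = SimConfig(),
    ssl: EncoderConfig = EncoderConfig(),
    cnn: CNNConfig = CNNConfig(),
    aug: AugmentationConfig = AugmentationConfig(),
    seeds: tuple[int, ...] = (0,),
    arms: tuple[str, ...] = ("true_class", "original", "ssl_groups"),
    progress: bool = False,
) -> list[SweepRow]:
    """Trace the ideal / noisy / SSL accuracy curves over the noise grid.

    Per (rho, seed): a fresh dataset is generated, labels are mixed at rho,
    the SSL relabeler is trained when its arm is requested, and each arm is
    cross-validated.  The ideal arm (``true_class``) trains on clean class
    labels but, like every arm, is tested against the noisy observed labels.
    """
    rows: list[SweepRow] = []
    for rho in rhos:
        if not 0.0 <= rho <= 0.5:
            raise ValueError("rho values must be in [0, 0.5]")
        for seed in seeds:
            sim_s = replace(sim, seed=int(np.random.default_rng((sim.seed, seed)).integers(2**31)))
            ssl_s = replace(ssl, seed=sim_s.seed)
            cnn_s = replace(cnn, seed=sim_s.seed)
            clean = generate_dataset(n_per_class, config=sim_s)
            noisy = inject_label_noise(
                clean,
                rho,
                np.random.default_rng((sim_s.seed, int(round(1000 * rho)))),
            )
            relabel_result = None
            if "ssl_groups" in arms or "intersection" in arms:
                relabel_result, _, _ = relabel_dataset(noisy, ssl_s, aug, progress=progress)
            for arm in arms:
                cv = cross_validate(
                    noisy, arm, cnn_s, relabel_result=relabel_result, seed=seed
                )
                if arm == "ssl_groups":
                    agreement = _label_agreement(noisy, relabel_result.group)
                elif arm == "original":
                    agreement = _label_agreement(noisy, np.asarray(noisy.observed_label))
                else:
                    agreement = 1.0
                rows.append(SweepRow(float(rho), arm, seed, cv, agreement))
    return rows


def sweep_to_frame(rows: list[SweepRow]) -> pd.DataFrame:
    """Flatten sweep rows into a tidy table (one row per rho/arm/seed)."""
    records = []
    for row in rows:
        records.append(
            {
                "rho": row.rho,
                "arm": row.arm,
                "seed": row.seed,
                "mean_accuracy": row.cv.mean,
                "sem": row.cv.sem,
                "f1": row.cv.f1,
                "precision": row.cv.precision,
                "recall": row.cv.recall,
                "agreement_with_truth": row.agreement_with_truth,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "rho",
            "arm",
            "seed",
            "mean_accuracy",
            "sem",
            "f1",
            "precision",
            "recall",
            "agreement_with_truth",
        ],
    )


def _plot_three_arm(result: ThreeArmResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(result.arms)
    means = [result.arms[a].mean for a in names]
    sems = [result.arms[a].sem for a in names]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(names, means, yerr=sems, capsize=4, color=["0.6", "0.3", "0.1"])
    ax.set_ylabel("accuracy vs observed labels")
    ax.set_title(f"labeling arms at rho = {result.rho:.0%}")
    ax.set_ylim(0.4, 1.0)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_sweep(frame: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    styles = {
        "true_class": ("k--", "ideal (clean training labels)"),
        "original": ("-", "noisy labels"),
        "ssl_groups": ("k-", "SSL relabeled"),
    }
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for arm, group in frame.groupby("arm"):
        agg = group.groupby("rho")["mean_accuracy"].agg(["mean", "sem"])
        style, label = styles.get(arm, ("-", arm))
        color = "0.5" if arm == "original" else "k"
        ax.errorbar(
            agg.index, agg["mean"], yerr=agg["sem"].fillna(0.0),
            fmt=style, color=color, capsize=3, label=label,
        )
    ax.set_xlabel("label noise proportion rho")
    ax.set_ylabel("accuracy vs observed labels")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(
    out_dir: str | Path,
    three_arm: ThreeArmResult | None = None,
    sweep: list[SweepRow] | None = None,
    manifest: dict | None = None,
    plots: bool = True,
) -> dict[str, Path]:
    """Write CSV/JSON summaries (and plots) of completed runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if three_arm is not None:
        path = out / "three_arm.json"
        path.write_text(json.dumps(three_arm.to_dict(), indent=2))
        written["three_arm_json"] = path
        frame = pd.DataFrame(
            [
                {"arm": a, "mean_accuracy": r.mean, "sem": r.sem, "f1": r.f1}
                for a, r in three_arm.arms.items()
            ]
        )
        csv_path = out / "three_arm.csv"
        frame.to_csv(csv_path, index=False)
        written["three_arm_csv"] = csv_path
        if plots:
            plot_path = out / "three_arm.png"
            _plot_three_arm(three_arm, plot_path)
            written["three_arm_plot"] = plot_path
    if sweep is not None:
        frame = sweep_to_frame(sweep)
        csv_path = out / "sweep.csv"
        frame.to_csv(csv_path, index=False)
        written["sweep_csv"] = csv_path
        if plots and len(frame):
            plot_path = out / "sweep.png"
            _plot_sweep(frame, plot_path)
            written["sweep_plot"] = plot_path
    if manifest is not None:
        path = out / "manifest.json"
        path.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
        written["manifest"] = path
    return written


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
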
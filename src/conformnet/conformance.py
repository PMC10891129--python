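"""Optimizer-conformance study: do Adam fits track SGD fits?

For one generative function, a study draws a fresh dataset per run, fits
the two-parameter line with SGD, RMSprop and Adam on the *same* (X, Y)
sample, predicts on the shared X, and measures how far each pair of
fitted models sits apart through the point-set distance

    d(a, b) = sqrt( Σ_i (x_i^a − x_i^b)² + (z_i^a − z_i^b)² )

where z_i are the model predictions. d_SA pairs SGD with Adam and d_SR
pairs SGD with RMSprop; because the x sample is shared within a run, the
x terms vanish and the distance reduces to the Euclidean distance of
prediction vectors (the general form is kept for robustness). Over the
runs (9 by default) the two distance samples are compared with a
two-sided Welch t-test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .optimizers import (
    DivergenceError,
    FitResult,
    OptimizerConfig,
    default_config,
    predict,
)
from .optimizers import fit as fit_with
from .synthetic_data import RegressionDataset, generate_regression_data

__all__ = [
    "ConformanceRun",
    "ConformanceStudy",
    "model_distance",
    "welch_t_test",
    "run_conformance_study",
    "export_conformance_outputs",
]


def model_distance(x_a, z_a, x_b, z_b) -> float:
    """Point-set distance between two fitted models' (x, prediction) pairs."""
    x_a, z_a, x_b, z_b = (np.asarray(v, dtype=float) for v in (x_a, z_a, x_b, z_b))
    if not (x_a.shape == z_a.shape == x_b.shape == z_b.shape):
        raise ValueError("all four arrays must share one shape, paired by index")
    return float(np.sqrt(np.sum((x_a - x_b) ** 2 + (z_a - z_b) ** 2)))


def welch_t_test(a, b) -> tuple[float, float]:
    """Two-sided two-sample t-test with Welch degrees of freedom.

    Degenerate samples are resolved by convention: if both samples have
    zero variance the test statistic is taken as 0 with p = 1 when the
    means agree, and ±inf with p = 0 when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t_test needs at least two observations per sample")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class ConformanceRun:
    run_index: int
    dataset: RegressionDataset
    fit_sgd: FitResult
    fit_rmsprop: FitResult
    fit_adam: FitResult
    d_sa: float
    d_sr: float


@dataclass(frozen=True)
class ConformanceStudy:
    fn_id: str
    runs: tuple[ConformanceRun, ...]
    t_statistic: float
    p_value: float
    mean_d_sa: float
    mean_d_sr: float
    base_seed: int

    def distances_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": [r.run_index for r in self.runs],
                "d_sa": [r.d_sa for r in self.runs],
                "d_sr": [r.d_sr for r in self.runs],
            }
        )

    def summary(self) -> dict:
        return {
            "fn_id": self.fn_id,
            "n_runs": len(self.runs),
            "mean_d_sa": self.mean_d_sa,
            "mean_d_sr": self.mean_d_sr,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "base_seed": self.base_seed,
        }


def _run_seeds(base_seed: int, n_runs: int) -> list[list[int]]:
    """Seven reproducible substream seeds per run: data, 3x init, 3x shuffle."""
    ss = np.random.SeedSequence(base_seed)
    return [[int(c.generate_state(1)[0]) for c in child.spawn(7)] for child in ss.spawn(n_runs)]


def run_conformance_study(
    fn_id: str,
    n_runs: int = 9,
    m: int = 100,
    noise_sd: float = 0.2,
    base_seed: int = 0,
    configs: dict[str, OptimizerConfig] | None = None,
    shared_theta_init: tuple[float, float] | None = None,
) -> ConformanceStudy:
    """Run the n-run, three-optimizer study for one generative function.

    Each run draws a fresh dataset shared by the three optimizers; each
    optimizer gets its own θ-initialisation and shuffle substream so any
    single run is individually reproducible from ``base_seed``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 (the t-test needs two observations)")
    configs = configs or {}
    runs: list[ConformanceRun] = []
    for run_index, seeds in enumerate(_run_seeds(base_seed, n_runs), start=1):
        data_seed, i_s, i_r, i_a, s_s, s_r, s_a = seeds
        dataset = generate_regression_data(fn_id, m=m, seed=data_seed, noise_sd=noise_sd)
        fits = {}
        for method, init_seed, shuffle_seed in (
            ("SGD", i_s, s_s),
            ("RMSPROP", i_r, s_r),
            ("ADAM", i_a, s_a),
        ):
            cfg = configs.get(method, default_config(method))
            cfg = replace(cfg, init_seed=init_seed, shuffle_seed=shuffle_seed)
            try:
                fits[method] = fit_with(dataset, cfg, theta_init=shared_theta_init)
            except DivergenceError as err:
                raise DivergenceError(f"{err.method} (run {run_index})", err.epoch) from err
        x = dataset.x
        d_sa = model_distance(x, fits["SGD"].predictions, x, fits["ADAM"].predictions)
        d_sr = model_distance(x, fits["SGD"].predictions, x, fits["RMSPROP"].predictions)
        runs.append(
            ConformanceRun(
                run_index=run_index,
                dataset=dataset,
                fit_sgd=fits["SGD"],
                fit_rmsprop=fits["RMSPROP"],
                fit_adam=fits["ADAM"],
                d_sa=d_sa,
                d_sr=d_sr,
            )
        )
    d_sa = np.array([r.d_sa for r in runs])
    d_sr = np.array([r.d_sr for r in runs])
    t, p = welch_t_test(d_sa, d_sr)
    return ConformanceStudy(
        fn_id=fn_id,
        runs=tuple(runs),
        t_statistic=t,
        p_value=p,
        mean_d_sa=float(d_sa.mean()),
        mean_d_sr=float(d_sr.mean()),
        base_seed=base_seed,
    )


def export_conformance_outputs(study: ConformanceStudy, out_dir) -> list[Path]:
    """Write per-run prediction scatter plots, the d_SA/d_SR boxplot, a
    distances CSV (n rows plus one summary row) and a JSON summary."""
    if len(study.runs) == 0:
        raise ValueError("cannot export an empty study")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    table = study.distances_frame()
    summary_row = pd.DataFrame(
        {
            "run": ["mean"],
            "d_sa": [study.mean_d_sa],
            "d_sr": [study.mean_d_sr],
            "t_statistic": [study.t_statistic],
            "p_value": [study.p_value],
        }
    )
    csv_path = out / f"{study.fn_id}_distances.csv"
    pd.concat([table, summary_row], ignore_index=True).to_csv(
        csv_path, index=False, float_format="%.12g"
    )
    written.append(csv_path)

    json_path = out / f"{study.fn_id}_summary.json"
    json_path.write_text(json.dumps(study.summary(), indent=2, sort_keys=True) + "\n")
    written.append(json_path)

    ncol = 3
    nrow = int(np.ceil(len(study.runs) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    for ax in axes.flat:
        ax.axis("off")
    for run, ax in zip(study.runs, axes.flat):
        ax.axis("on")
        order = np.argsort(run.dataset.x)
        x = run.dataset.x[order]
        ax.plot(x, run.fit_sgd.predictions[order], "o", ms=2.5, label="SGD")
        ax.plot(x, run.fit_adam.predictions[order], "s", ms=2.5, label="Adam")
        ax.plot(x, run.fit_rmsprop.predictions[order], "^", ms=2.5, label="RMSprop")
        ax.set_title(f"{study.fn_id} run {run.run_index}", fontsize=8)
    axes.flat[0].legend(fontsize=6)
    fig.tight_layout()
    scatter_path = out / f"{study.fn_id}_model_predictions.png"
    fig.savefig(scatter_path, dpi=120)
    plt.close(fig)
    written.append(scatter_path)

    fig, ax = plt.subplots(figsize=(3.5, 3.2))
    ax.boxplot(
        [table["d_sa"], table["d_sr"]], tick_labels=["AdamSGD (d_SA)", "RMSpropSGD (d_SR)"]
    )
    ax.set_ylabel("model distance")
    ax.set_title(f"{study.fn_id}: p = {study.p_value:.3g}", fontsize=9)
    fig.tight_layout()
    box_path = out / f"{study.fn_id}_distance_boxplot.png"
    fig.savefig(box_path, dpi=120)
    plt.close(fig)
    written.append(box_path)
    return written
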
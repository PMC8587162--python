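"""End-to-end orchestration of the four regression model workflows.

Model 1: NIR derivative features (1596-1919 nm) -> LT and DT, Bayesian
regularization, 75/25 train/test split. Model 2: six canopy-architecture
parameters -> LT and DT, Levenberg-Marquardt, 60/20/20 split. Models 3-4:
canopy parameters -> ten sensory descriptor intensities (Chardonnay /
Shiraz), Levenberg-Marquardt, 60/20/20.

Each run executes preprocessing, splitting, neuron trimming, training,
per-stage diagnostics and the 95%-prediction-bound outlier report, and
writes one structured report (JSON + CSV, optional figure) laid out like a
stage table: one row per stage with sample and observation counts, R,
slope and MSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ann, evaluation, nir, synthetic

__all__ = [
    "MODEL_DEFS",
    "PipelineConfig",
    "ModelReport",
    "run_model",
    "run_model_synthetic",
    "load_config",
]

CANOPY_FEATURES = ["lai", "lai_e", "fc", "ff", "phi", "omega"]
VITALITY_TARGETS = ["LT", "DT"]

#: per-model workflow definitions: input/target blocks, algorithm, split
MODEL_DEFS = {
    1: {"inputs": "nir", "targets": VITALITY_TARGETS,
        "algorithm": "bayesian_regularization", "fractions": (0.75, 0.0, 0.25)},
    2: {"inputs": CANOPY_FEATURES, "targets": VITALITY_TARGETS,
        "algorithm": "levenberg_marquardt", "fractions": (0.60, 0.20, 0.20)},
    3: {"inputs": CANOPY_FEATURES, "targets": synthetic.CHARDONNAY_DESCRIPTORS,
        "algorithm": "levenberg_marquardt", "fractions": (0.60, 0.20, 0.20)},
    4: {"inputs": CANOPY_FEATURES, "targets": synthetic.SHIRAZ_DESCRIPTORS,
        "algorithm": "levenberg_marquardt", "fractions": (0.60, 0.20, 0.20)},
}


@dataclass
class PipelineConfig:
    """Validated run configuration for one model workflow."""

    model_id: int
    features_csv: Optional[str] = None
    targets_csv: Optional[str] = None
    out_dir: str = "results"
    seed: int = 0
    neuron_candidates: tuple[int, ...] = ann.DEFAULT_NEURON_CANDIDATES
    max_epochs: int = 1000
    sg_window: int = nir.DEFAULT_SG_WINDOW
    sg_polyorder: int = nir.DEFAULT_SG_POLYORDER
    band: tuple[float, float] = nir.MODEL_BAND_NM
    outlier_level: float = 0.95
    make_figure: bool = False

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_DEFS:
            raise ValueError(f"model_id must be one of {sorted(MODEL_DEFS)}")
        if not self.neuron_candidates:
            raise ValueError("neuron_candidates must be non-empty")
        if not 0 < self.outlier_level < 1:
            raise ValueError("outlier_level must be in (0, 1)")


def load_config(path: str | Path) -> PipelineConfig:
    blob = yaml.safe_load(Path(path).read_text())
    for key in ("neuron_candidates", "band"):
        if key in blob:
            blob[key] = tuple(blob[key])
    return PipelineConfig(**blob)


@dataclass
class ModelReport:
    model_id: int
    selected_neurons: int
    stage_table: pd.DataFrame
    outliers: evaluation.OutlierReport
    trimming_trace: list[str]
    network: ann.Network
    split: ann.SplitSpec
    predictions: Optional[np.ndarray] = None
    targets: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "selected_neurons": self.selected_neurons,
            "stages": self.stage_table.to_dict(orient="records"),
            "outliers": {"n_total": self.outliers.n_total,
                         "n_outliers": self.outliers.n_outliers,
                         "percent": self.outliers.percent,
                         "level": self.outliers.level},
            "trimming_trace": self.trimming_trace,
        }

    def write(self, out_dir: str | Path, make_figure: bool = False) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "json": out / f"model{self.model_id}_report.json",
            "csv": out / f"model{self.model_id}_stages.csv",
            "network": out / f"model{self.model_id}_network.json",
        }
        paths["json"].write_text(json.dumps(self.to_dict(), indent=1))
        self.stage_table.to_csv(paths["csv"], index=False)
        ann.save_network(self.network, paths["network"])
        if make_figure:
            paths["figure"] = out / f"model{self.model_id}_regression.png"
            _regression_figure(self, paths["figure"])
        return paths


def _stage_rows(net, X, Y, split: ann.SplitSpec) -> pd.DataFrame:
    rows = []
    stages = [("Training", split.train_idx), ("Validation", split.val_idx),
              ("Testing", split.test_idx)]
    for name, idx in stages:
        if idx is None or len(idx) == 0:
            continue
        d = evaluation.diagnostics(ann.forward(net, X[idx]), Y[idx], stage=name.lower())
        rows.append({"Stage": name, "Samples": d.n_samples,
                     "Observations": d.n_observations, "R": d.r,
                     "Slope": d.slope, "MSE": d.mse})
    d = evaluation.diagnostics(ann.forward(net, X), Y, stage="overall")
    rows.append({"Stage": "Overall", "Samples": d.n_samples,
                 "Observations": d.n_observations, "R": d.r,
                 "Slope": d.slope, "MSE": d.mse})
    return pd.DataFrame(rows)


def _prepare_model1_features(spectra: nir.SpectraSet, config: PipelineConfig,
                             targets: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    feats = nir.preprocess(spectra, window=config.sg_window,
                           polyorder=config.sg_polyorder, band=config.band)
    M, ids = feats.to_matrix()
    tt = targets.set_index("sample_id").loc[ids]
    return M, tt[VITALITY_TARGETS].to_numpy(dtype=float)


def run_model(model_id: int, features, targets, config: Optional[PipelineConfig] = None) -> ModelReport:
    """Run one model workflow on prepared inputs.

    ``features`` is either a :class:`~vinemetrics.nir.SpectraSet` (Model 1)
    or a DataFrame holding the canopy feature columns; ``targets`` is a
    DataFrame with a ``sample_id`` column (Model 1) or aligned row order
    (Models 2-4) holding the model's target columns.
    """
    config = config or PipelineConfig(model_id=model_id)
    mdef = MODEL_DEFS[model_id]

    if mdef["inputs"] == "nir":
        if not isinstance(features, nir.SpectraSet):
            raise TypeError("Model 1 expects a SpectraSet")
        X, Y = _prepare_model1_features(features, config, targets)
    else:
        missing = [c for c in mdef["inputs"] if c not in features.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        missing_t = [c for c in mdef["targets"] if c not in targets.columns]
        if missing_t:
            raise ValueError(f"missing target columns: {missing_t}")
        if len(features) != len(targets):
            raise ValueError("features and targets must have equal row counts")
        X = features[mdef["inputs"]].to_numpy(dtype=float)
        Y = targets[mdef["targets"]].to_numpy(dtype=float)

    split = ann.split_dataset(X.shape[0], ann.SplitSpec(fractions=mdef["fractions"],
                                                        seed=config.seed))
    net_config = ann.NetworkConfig(
        n_inputs=X.shape[1], n_hidden=config.neuron_candidates[0],
        n_outputs=Y.shape[1], algorithm=mdef["algorithm"],
        max_epochs=config.max_epochs, seed=config.seed)
    report = ann.neuron_trimming((X, Y), split, net_config, config.neuron_candidates)
    best = report.best

    stage_table = _stage_rows(best.network, X, Y, split)
    pred_all = ann.forward(best.network, X)
    outliers = evaluation.prediction_bound_outliers(pred_all, Y, level=config.outlier_level)
    return ModelReport(model_id=model_id, selected_neurons=report.selected,
                       stage_table=stage_table, outliers=outliers,
                       trimming_trace=report.criterion_trace,
                       network=best.network, split=split,
                       predictions=pred_all, targets=Y)


def run_model_synthetic(model_id: int, n_samples: int = 432, seed: int = 0,
                        config: Optional[PipelineConfig] = None) -> ModelReport:
    """Generate the model's synthetic inputs and run the workflow end to end."""
    config = config or PipelineConfig(model_id=model_id, seed=seed)
    if model_id == 1:
        spectra, truth = synthetic.make_nir_dataset(n_samples, rng_seed=seed)
        targets = pd.DataFrame({"sample_id": truth.params["berry_ids"],
                                "LT": truth.arrays["lt"], "DT": truth.arrays["bcd"]})
        return run_model(1, spectra, targets, config)
    cultivar = "chardonnay" if model_id == 3 else "shiraz"
    df, _ = synthetic.make_vineyard_dataset(n_samples, cultivar=cultivar, rng_seed=seed)
    return run_model(model_id, df, df, config)


def _regression_figure(report: ModelReport, path: Path) -> None:
    """Overall predicted-vs-target scatter with the OLS line and 95% bounds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats

    y = report.predictions.ravel()
    x = report.targets.ravel()
    n = len(x)
    b = float(np.cov(y, x, bias=True)[0, 1] / np.var(x))
    a = float(y.mean() - b * x.mean())
    resid = y - (a + b * x)
    s = np.sqrt(resid @ resid / (n - 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    grid = np.linspace(x.min(), x.max(), 100)
    half = stats.t.ppf(0.5 + report.outliers.level / 2, n - 2) * s * np.sqrt(
        1 + 1 / n + (grid - x.mean()) ** 2 / sxx)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(x, y, ".", ms=3, alpha=0.4)
    ax.plot(grid, a + b * grid, "k-", lw=1)
    ax.plot(grid, a + b * grid + half, "k--", lw=0.8)
    ax.plot(grid, a + b * grid - half, "k--", lw=0.8)
    ax.set_xlabel("target")
    ax.set_ylabel("prediction")
    ax.set_title(f"Model {report.model_id}: R stages in report; "
                 f"{report.outliers.percent}% outliers")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
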
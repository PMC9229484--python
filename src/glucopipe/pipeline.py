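"""End-to-end orchestration: simulate -> features -> fuse -> split -> train -> evaluate.

The fused predictor table has a frozen 30-column layout per participant:
12 PPG statistics (IR/Red interleaved), 7 physiological covariates
(age, height, weight, heart rate, blood flow, hemoglobin, SpO2), and 11
impedance PCA scores. The split is at participant level; the feature
scaler and (by default) the PCA are fitted on training rows only, and an
internal validation subset carved from the training rows drives early
stopping so the held-out test rows are touched only by the final
evaluation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import impedance, network, ppg, synthetic
from .errors import DataError
from .evaluation import EvaluationReport, evaluate

__all__ = [
    "RunConfig",
    "PHYSIO_COLUMNS",
    "FUSED_COLUMNS",
    "fuse_features",
    "split_cohort",
    "build_feature_table",
    "run_all",
]

log = logging.getLogger("glucopipe")

PHYSIO_COLUMNS = ["age", "height_cm", "weight_kg", "heart_rate_bpm",
                  "blood_flow_mm_s", "hemoglobin_g_l", "spo2_pct"]
PCA_COLUMNS = [f"pc{i}" for i in range(1, 12)]

#: Frozen 30-predictor ordering: PPG 1-12, physiological 13-19, impedance 20-30.
FUSED_COLUMNS = ppg.PPG_FEATURE_NAMES + PHYSIO_COLUMNS + PCA_COLUMNS


@dataclass
class RunConfig:
    """Master configuration for a full reproducible run."""

    seed: int = 7
    n_participants: int = 40
    split_fraction: float = 0.8
    pca_k: int = 11
    pca_fit_on: str = "train"  # "train" | "all" (faithfulness flag)
    val_fraction: float = 0.2  # of training rows, for early stopping
    cohort: synthetic.CohortConfig = None
    acquisition: synthetic.AcquisitionConfig = field(
        default_factory=synthetic.AcquisitionConfig)
    sweep: synthetic.SweepConfig = field(default_factory=synthetic.SweepConfig)
    filter: ppg.FilterConfig = field(default_factory=ppg.FilterConfig)
    peaks: ppg.PeakConfig = field(default_factory=ppg.PeakConfig)
    schedule: network.TrainingSchedule = field(
        default_factory=network.TrainingSchedule)
    layer_sizes: tuple[int, ...] = network.DEFAULT_LAYER_SIZES

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise DataError("split fraction must be in (0, 1)")
        if self.pca_fit_on not in ("train", "all"):
            raise DataError("pca_fit_on must be 'train' or 'all'")
        if self.cohort is None:
            self.cohort = synthetic.CohortConfig(
                n_participants=self.n_participants, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        simple = {"seed", "n_participants", "split_fraction", "pca_k",
                  "pca_fit_on", "val_fraction"}
        nested = {"cohort": synthetic.CohortConfig,
                  "acquisition": synthetic.AcquisitionConfig,
                  "sweep": synthetic.SweepConfig,
                  "filter": ppg.FilterConfig,
                  "peaks": ppg.PeakConfig,
                  "schedule": network.TrainingSchedule}
        for key, val in raw.items():
            if key in simple:
                kwargs[key] = val
            elif key in nested:
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in (val or {}).items()}
                kwargs[key] = nested[key](**sub)
            elif key == "layer_sizes":
                kwargs[key] = tuple(val)
            else:
                raise DataError(f"unknown config key {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layer_sizes"] = list(self.layer_sizes)
        return d


def fuse_features(ppg12: np.ndarray, physio7: np.ndarray,
                  pca11: np.ndarray) -> np.ndarray:
    """Concatenate the three blocks in the frozen order (30 predictors)."""
    ppg12 = np.asarray(ppg12, dtype=float).ravel()
    physio7 = np.asarray(physio7, dtype=float).ravel()
    pca11 = np.asarray(pca11, dtype=float).ravel()
    if len(ppg12) != 12 or len(physio7) != 7 or len(pca11) != 11:
        raise DataError(
            f"block sizes must be 12/7/11, got {len(ppg12)}/{len(physio7)}/{len(pca11)}")
    return np.concatenate([ppg12, physio7, pca11])


def split_cohort(n_rows: int, fraction: float = 0.8,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive participant-level train/test index split."""
    if n_rows < 5:
        raise DataError("need at least 5 rows to split")
    if not (0 < fraction < 1):
        raise DataError("fraction must be in (0, 1)")
    idx = np.random.default_rng(seed).permutation(n_rows)
    n_train = int(fraction * n_rows)
    return np.sort(idx[:n_train]), np.sort(idx[n_train:])


def build_feature_table(cohort: synthetic.Cohort,
                        fc: ppg.FilterConfig | None = None,
                        pc: ppg.PeakConfig | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-participant PPG features, raw 44 impedance features, covariates.

    Participants whose PPG vector is flagged invalid (fewer than 2 peaks
    on a channel) are dropped from all three frames, with a log line.
    Returns (ppg frame, impedance frame, physio+target frame) indexed by id.
    """
    fc = fc or ppg.FilterConfig()
    pc = pc or ppg.PeakConfig()
    ppg_rows, imp_rows, phys_rows, ids = [], [], [], []
    for p, rec, swps in zip(cohort.participants, cohort.recordings, cohort.sweeps):
        vec = ppg.extract_ppg_features(rec, fc, pc)
        if not vec.valid:
            log.warning("dropping %s: insufficient peaks (ir=%d, red=%d)",
                        p.id, vec.n_peaks_ir, vec.n_peaks_red)
            continue
        ids.append(p.id)
        ppg_rows.append(vec.as_array())
        imp_rows.append(impedance.flatten_sweeps(list(swps)))
        phys_rows.append(np.append(p.physio_vector, p.glucose_mg_dl))
    if not ids:
        raise DataError("no valid participants")
    ppg_df = pd.DataFrame(ppg_rows, index=ids, columns=ppg.PPG_FEATURE_NAMES)
    imp_df = pd.DataFrame(imp_rows, index=ids,
                          columns=impedance.IMPEDANCE_FEATURE_NAMES)
    phys_df = pd.DataFrame(phys_rows, index=ids,
                           columns=PHYSIO_COLUMNS + ["glucose_mg_dl"])
    return ppg_df, imp_df, phys_df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, outdir: str | Path | None = None,
            write_signals: bool = False) -> tuple[EvaluationReport, dict]:
    """Execute the full chain and (optionally) persist every artifact.

    Returns the held-out-test evaluation report and a results dict with
    the trained model, history, tables, and split indices.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    log.info("stage 1/6: simulate cohort (n=%d, seed=%d)",
             config.cohort.n_participants, config.seed)
    cohort = synthetic.generate_cohort(config.cohort, config.acquisition,
                                       config.sweep)
    if out is not None:
        synthetic.cohort_frame(cohort).to_csv(out / "cohort.csv", index=False)
        if write_signals:
            synthetic.write_cohort(cohort, out)

    log.info("stage 2/6: extract features")
    ppg_df, imp_df, phys_df = build_feature_table(cohort, config.filter,
                                                  config.peaks)
    n = len(ppg_df)

    log.info("stage 3/6: split %d participants %d/%d", n,
             int(config.split_fraction * n), n - int(config.split_fraction * n))
    train_idx, test_idx = split_cohort(n, config.split_fraction, config.seed)

    log.info("stage 4/6: PCA on impedance features (fit on %s)", config.pca_fit_on)
    fit_rows = imp_df.to_numpy() if config.pca_fit_on == "all" \
        else imp_df.to_numpy()[train_idx]
    pca = impedance.pca_fit(fit_rows, k=config.pca_k)
    scores = impedance.pca_transform(pca, imp_df.to_numpy())
    pca_df = pd.DataFrame(scores, index=imp_df.index, columns=PCA_COLUMNS)

    fused = pd.DataFrame(
        [fuse_features(ppg_df.iloc[i].to_numpy(),
                       phys_df.iloc[i][PHYSIO_COLUMNS].to_numpy(),
                       pca_df.iloc[i].to_numpy()) for i in range(n)],
        index=ppg_df.index, columns=FUSED_COLUMNS)
    target = phys_df["glucose_mg_dl"]

    log.info("stage 5/6: train %s network", "x".join(map(str, config.layer_sizes)))
    X = fused.to_numpy()
    y = target.to_numpy()
    # carve an internal validation subset from the training rows
    rng = np.random.default_rng(config.seed + 1)
    perm = rng.permutation(len(train_idx))
    n_val = max(1, int(config.val_fraction * len(train_idx)))
    val_rows = train_idx[perm[:n_val]]
    fit_rows_idx = train_idx[perm[n_val:]]
    if len(fit_rows_idx) == 0:
        raise DataError("training split too small for internal validation")

    scaler = network.Scaler().fit(X[fit_rows_idx], y[fit_rows_idx])
    net = network.init_network(config.layer_sizes, seed=config.seed)
    net, hist = network.train(
        net,
        scaler.transform_x(X[fit_rows_idx]), scaler.transform_y(y[fit_rows_idx]),
        scaler.transform_x(X[val_rows]), scaler.transform_y(y[val_rows]),
        config.schedule)

    log.info("stage 6/6: evaluate on %d held-out participants", len(test_idx))
    pred = network.predict_glucose(net, scaler, X[test_idx])
    report = evaluate(y[test_idx], pred,
                      plot_path=(out / "clarke.png") if out is not None else None)

    results = {"cohort": cohort, "ppg": ppg_df, "impedance": imp_df,
               "pca_scores": pca_df, "fused": fused, "target": target,
               "pca": pca, "net": net, "scaler": scaler, "history": hist,
               "train_idx": train_idx, "val_idx": val_rows,
               "fit_idx": fit_rows_idx, "test_idx": test_idx,
               "predictions": pred, "reference": y[test_idx]}

    if out is not None:
        ppg_df.to_csv(out / "ppg_features.csv", index_label="id")
        imp_df.to_csv(out / "impedance_features.csv", index_label="id")
        pca_df.to_csv(out / "impedance_pca.csv", index_label="id")
        fused.assign(glucose_mg_dl=target).to_csv(out / "features.csv",
                                                  index_label="id")
        pca.to_json(out / "pca_model.json")
        network.save_model(out / "model.json", net, scaler, config.schedule)
        pd.DataFrame({"epoch": range(len(hist)), "lr": hist.learning_rate,
                      "train_loss": hist.train_loss,
                      "val_loss": hist.val_loss}).to_csv(out / "history.csv",
                                                         index=False)
        report.to_json(out / "report.json")
        artifacts = ["cohort.csv", "ppg_features.csv", "impedance_features.csv",
                     "impedance_pca.csv", "features.csv", "pca_model.json",
                     "model.json", "history.csv", "report.json", "clarke.png"]
        manifest = {
            "seed": config.seed,
            "config": config.to_dict(),
            "n_participants": n,
            "files": {a: _sha256(out / a) for a in artifacts if (out / a).exists()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report, results
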
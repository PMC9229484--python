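"""CGM-style evaluation: MSE, RMSE, MAE, MARD, R², and Clarke error grid.

The Clarke error grid partitions the (reference, predicted) glucose
plane into five clinical-consequence regions: A (accurate), B (benign
deviation), C (over-correction), D (dangerous failure to detect), and
E (erroneous, opposite treatment). The canonical 1987 boundary
inequalities are frozen here, evaluated in the fixed order A, E, C, D,
else B, so every point receives exactly one label and boundary ties are
resolved deterministically (A wins its own boundary, then E, C, D).

MARD — mean absolute relative difference, ``mean(|pred - ref| / ref)`` —
is reported on the percent scale, the convention in the CGM literature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError

__all__ = [
    "EvaluationReport",
    "regression_metrics",
    "clarke_region",
    "clarke_regions",
    "clarke_summary",
    "plot_clarke",
    "evaluate",
]

CLARKE_REGIONS = ("A", "B", "C", "D", "E")


def _check_pairs(reference, predicted) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if ref.shape != pred.shape or ref.size < 1:
        raise DataError("reference and predicted must be equal-length, non-empty")
    if np.any(ref <= 0) or np.any(pred <= 0):
        raise DataError("glucose values must be positive (MARD divides by reference)")
    return ref, pred


@dataclass
class EvaluationReport:
    """Bundle of the six evaluation outputs."""

    mse: float
    rmse: float
    mae: float
    mard_pct: float
    r2: float
    clarke_counts: dict[str, int] = field(default_factory=dict)
    clarke_percent: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n": self.n, "mse": self.mse, "rmse": self.rmse, "mae": self.mae,
            "mard_pct": self.mard_pct, "r2": self.r2,
            "clarke_counts": self.clarke_counts,
            "clarke_percent": self.clarke_percent,
        }, indent=2))


def regression_metrics(reference, predicted) -> dict[str, float]:
    """MSE, RMSE, MAE, MARD (%) and R² of paired glucose values.

    R² uses the reference-mean baseline (coefficient of determination);
    with zero-variance references it is undefined and reported as NaN
    with a warning.
    """
    ref, pred = _check_pairs(reference, predicted)
    err = pred - ref
    mse = float(np.mean(err ** 2))
    mae = float(np.mean(np.abs(err)))
    mard = float(np.mean(np.abs(err) / ref) * 100.0)
    ss_res = float(np.sum(err ** 2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero-variance reference values: R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return {"mse": mse, "rmse": float(np.sqrt(mse)), "mae": mae,
            "mard_pct": mard, "r2": r2}


def clarke_region(ref: float, pred: float) -> str:
    """Clarke error-grid label for one (reference, predicted) pair in mg/dL."""
    if ref <= 0 or pred <= 0:
        raise DataError("glucose values must be positive")
    if abs(pred - ref) <= 0.2 * ref or (ref < 70 and pred < 70):
        return "A"
    if (ref >= 180 and pred <= 70) or (ref <= 70 and pred >= 180):
        return "E"
    if (70 <= ref <= 290 and pred >= ref + 110) or \
       (130 <= ref <= 180 and pred <= (7.0 / 5.0) * ref - 182):
        return "C"
    if (ref >= 240 and 70 <= pred <= 180) or \
       (ref <= 175.0 / 3.0 and 70 <= pred <= 180) or \
       (175.0 / 3.0 <= ref <= 70 and pred >= (6.0 / 5.0) * ref):
        return "D"
    return "B"


def clarke_regions(reference, predicted) -> list[str]:
    ref, pred = _check_pairs(reference, predicted)
    return [clarke_region(r, p) for r, p in zip(ref, pred)]


def clarke_summary(reference, predicted,
                   plot_path: str | Path | None = None
                   ) -> tuple[dict[str, int], dict[str, float]]:
    """Per-region tallies and percentages; optionally writes the grid plot."""
    labels = clarke_regions(reference, predicted)
    n = len(labels)
    counts = {r: labels.count(r) for r in CLARKE_REGIONS}
    percent = {r: 100.0 * c / n for r, c in counts.items()}
    if plot_path is not None:
        plot_clarke(reference, predicted, plot_path)
    return counts, percent


def plot_clarke(reference, predicted, path: str | Path) -> None:
    """Scatter of predictions over the Clarke grid with region boundaries."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref, pred = _check_pairs(reference, predicted)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(ref, pred, s=12, c="tab:blue", zorder=3)
    lims = (0, 400)
    ax.plot(lims, lims, "k:", lw=0.8)
    # canonical boundary segments
    segs = [
        ((0, 58.33), (70, 70)),            # lower A bound up to ref=58.33
        ((58.33, 400), (70, 480)),         # pred = 1.2*ref branch -> 20% line
        ((0, 70), (180, 180)),             # E/upper-left shelf
        ((70, 70), (180, 400)),
        ((70, 290), (180, 400)),           # C upper: pred = ref + 110
        ((130, 180), (0, 70)),             # C lower: pred = 1.4*ref - 182
        ((180, 400), (70, 70)),            # lower-right D/E shelf
        ((240, 240), (70, 180)),
        ((240, 400), (180, 180)),
        ((58.33, 58.33), (70, 180)),       # left D box
        ((0, 58.33), (180, 180)),
    ]
    for (x0, x1), (y0, y1) in segs:
        ax.plot([x0, x1], [y0, y1], "k-", lw=0.8, zorder=2)
    for txt, (x, y) in {"A": (320, 320), "B": (290, 210), "C": (160, 360),
                        "D": (320, 120), "E": (120, 320)}.items():
        ax.text(x, y, txt, fontsize=13, ha="center")
    ax.set_xlim(*lims)
    ax.set_ylim(*lims)
    ax.set_xlabel("Reference glucose (mg/dL)")
    ax.set_ylabel("Predicted glucose (mg/dL)")
    ax.set_title("Clarke error grid")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def evaluate(reference, predicted,
             plot_path: str | Path | None = None) -> EvaluationReport:
    """Full report: the five scalar metrics plus Clarke tallies."""
    ref, pred = _check_pairs(reference, predicted)
    m = regression_metrics(ref, pred)
    counts, percent = clarke_summary(ref, pred, plot_path=plot_path)
    return EvaluationReport(mse=m["mse"], rmse=m["rmse"], mae=m["mae"],
                            mard_pct=m["mard_pct"], r2=m["r2"],
                            clarke_counts=counts, clarke_percent=percent,
                            n=ref.size)
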
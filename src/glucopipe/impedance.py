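"""Bioimpedance feature assembly and PCA dimensionality reduction.

Each participant contributes several frequency sweeps (one per minute of
recording); these are averaged in the complex plane and flattened into a
44-element raw feature row — for each of the 11 frequencies ascending:
real, imaginary, phase, magnitude. A principal component analysis on the
z-scored rows (eigendecomposition of the correlation matrix, implemented
directly) reduces the 44 features to k scores, k = 11 by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, ParameterError
from .synthetic import ImpedanceSweep

__all__ = [
    "IMPEDANCE_FEATURE_NAMES",
    "PCAModel",
    "flatten_sweeps",
    "pca_fit",
    "pca_transform",
]


def _feature_names(frequencies_khz) -> list[str]:
    names = []
    for f in frequencies_khz:
        tag = f"{int(f)}khz" if float(f).is_integer() else f"{f}khz"
        names += [f"real_{tag}", f"imag_{tag}", f"phase_{tag}", f"magnitude_{tag}"]
    return names


#: Canonical names of the 44 raw impedance features (50–100 kHz, 5 kHz step).
IMPEDANCE_FEATURE_NAMES = _feature_names(range(50, 105, 5))


def flatten_sweeps(sweeps: list[ImpedanceSweep]) -> np.ndarray:
    """Average sweeps in the complex plane and flatten to 44 features.

    Real and imaginary parts are averaged element-wise across sweeps;
    phase and magnitude are recomputed from the averaged parts so the
    magnitude/phase consistency invariant survives averaging.
    """
    if len(sweeps) == 0:
        raise DataError("need at least one sweep")
    f0 = sweeps[0].frequency_khz
    for s in sweeps[1:]:
        if not np.array_equal(s.frequency_khz, f0):
            raise DataError("sweeps have mismatched frequency axes")
    real = np.mean([s.real_ohm for s in sweeps], axis=0)
    imag = np.mean([s.imag_ohm for s in sweeps], axis=0)
    phase = np.arctan2(imag, real)
    mag = np.hypot(real, imag)
    out = np.empty(4 * len(f0))
    out[0::4], out[1::4], out[2::4], out[3::4] = real, imag, phase, mag
    return out


@dataclass(frozen=True)
class PCAModel:
    """Standardization statistics plus the retained eigenpairs.

    ``components`` rows are unit eigenvectors of the correlation matrix
    of the training rows, sorted by non-increasing eigenvalue and
    sign-fixed so each row's largest-magnitude loading is positive.
    """

    feature_means: np.ndarray
    feature_sds: np.ndarray
    components: np.ndarray  # k x p
    eigenvalues: np.ndarray  # k
    k: int

    def transform(self, rows: np.ndarray) -> np.ndarray:
        return pca_transform(self, rows)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "k": self.k,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(feature_means=np.array(d["feature_means"]),
                   feature_sds=np.array(d["feature_sds"]),
                   components=np.array(d["components"]),
                   eigenvalues=np.array(d["eigenvalues"]),
                   k=int(d["k"]))


def pca_fit(rows: np.ndarray, k: int = 11) -> PCAModel:
    """Fit PCA by explicit eigendecomposition of the correlation matrix.

    Steps: z-score each column (population sd; a zero-variance column
    gets sd 1 with a warning), form the covariance of the standardized
    data, eigendecompose it, and retain the top-k eigenpairs with a
    deterministic sign convention.
    """
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("need a 2-D matrix with at least 2 rows")
    n, p = X.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ParameterError(f"k={k} out of range for {n}x{p} data")
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population sd
    zero = sds == 0.0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance column(s); sd set to 1",
                      stacklevel=2)
        sds = np.where(zero, 1.0, sds)
    Z = (X - means) / sds
    cov = Z.T @ Z / n
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    comps = eigvecs[:, :k].T.copy()
    # sign convention: largest-|loading| entry of each component positive
    for row in comps:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return PCAModel(feature_means=means, feature_sds=sds, components=comps,
                    eigenvalues=eigvals[:k].copy(), k=k)


def pca_transform(model: PCAModel, rows: np.ndarray) -> np.ndarray:
    """Project rows onto the retained components: ``z-score(rows) @ V.T``."""
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    if X.shape[1] != model.components.shape[1]:
        raise DataError(
            f"expected {model.components.shape[1]} columns, got {X.shape[1]}")
    Z = (X - model.feature_means) / model.feature_sds
    return Z @ model.components.T
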
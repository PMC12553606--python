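"""Relatedness kernels: symmetric PSD matrices with trace normalized to dimension.

Both genomic (additive, dominance) and environmental relationship matrices
share the same construction: a feature matrix ``W`` (rows = individuals or
environments) is turned into ``W W' / (tr(W W') / n)``, so that the average
diagonal element equals one and variance components estimated against the
kernel are on the scale of the phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Kernel", "kernel_from_features", "DegenerateKernelError"]


class DegenerateKernelError(ValueError):
    """Raised when a kernel cannot be formed (zero trace / no variation)."""


@dataclass
class Kernel:
    """A labeled, trace-normalized relatedness matrix.

    Parameters
    ----------
    values
        Square symmetric matrix, trace equal to its dimension.
    labels
        Row/column labels (accession or environment identifiers).
    """

    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match matrix dimension")
        self.labels = list(self.labels)
        self._pos = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, sym_tol: float = 1e-10, psd_tol: float = -1e-8,
                 trace_tol: float = 1e-8) -> None:
        """Check symmetry, positive semi-definiteness and trace normalization."""
        v = self.values
        if not np.all(np.abs(v - v.T) <= sym_tol * max(1.0, np.abs(v).max())):
            raise ValueError("kernel is not symmetric")
        w = np.linalg.eigvalsh((v + v.T) / 2.0)
        if w.min() < psd_tol * max(1.0, w.max()):
            raise ValueError(f"kernel is not PSD (min eigenvalue {w.min():.3g})")
        if abs(np.trace(v) - self.n) > trace_tol * self.n:
            raise ValueError(f"kernel trace {np.trace(v):.6g} != dimension {self.n}")

    def indices(self, labels) -> np.ndarray:
        """Positions of ``labels`` in this kernel; raises on unknown labels."""
        missing = [lab for lab in labels if lab not in self._pos]
        if missing:
            raise KeyError(f"labels not present in kernel: {missing[:5]}")
        return np.array([self._pos[lab] for lab in labels], dtype=np.intp)

    def subset(self, labels) -> "Kernel":
        idx = self.indices(labels)
        return Kernel(self.values[np.ix_(idx, idx)], list(labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Kernel":
        return cls(df.to_numpy(dtype=float), list(df.index))


def kernel_from_features(
    features: np.ndarray,
    labels,
    center: bool = True,
    scale: bool = False,
) -> Kernel:
    """Build ``W W' / (tr(W W')/n)`` from a rows-by-features matrix.

    ``center`` removes each column mean (the construction used for the
    additive genomic relationship matrix); ``scale`` additionally divides
    each column by its standard deviation, appropriate when features carry
    incommensurate units (environmental covariates). Constant columns are
    dropped under ``scale``.
    """
    W = np.asarray(features, dtype=float)
    if W.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if W.shape[0] < 2:
        raise DegenerateKernelError("kernel requires at least two rows")
    if center:
        W = W - W.mean(axis=0, keepdims=True)
    if scale:
        sd = W.std(axis=0, ddof=1)
        keep = sd > 0
        W = W[:, keep] / sd[keep]
    cross = W @ W.T
    tr = np.trace(cross)
    if tr <= 1e-20 * W.size:
        raise DegenerateKernelError("zero-variance feature matrix: kernel undefined")
    return Kernel(cross / (tr / W.shape[0]), list(labels))
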
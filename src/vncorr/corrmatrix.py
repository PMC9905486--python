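"""Intra- and inter-embryo correlation matrices over AP bin pairs.

Entry (i, j) of a self-matrix is the post-registration correlation score of
transverse sections i and j; a 50-bin series yields the published
50 × 50 = 2500-correlation matrix.  Only the upper triangle is computed and
mirrored, which both halves the cost and enforces the symmetry the score
has up to registration asymmetry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SlabSeries
from .register import RegistrationOptions, correlation_score, register_rigid

__all__ = [
    "CorrelationMatrix",
    "self_correlation_matrix",
    "cross_correlation_matrix",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Registered-correlation scores between AP bins, axis-calibrated in μm.

    ``values`` holds scores in [0, 1] with NaN as the missing-value
    sentinel (insufficient overlap or zero variance).  ``metric_values``
    optionally carries the optimizer's final MI metric per pair for
    comparison with the correlation reading.
    """

    values: np.ndarray
    bin_length: float
    labels: tuple[str, str] = ("self", "self")
    convergence_flags: np.ndarray | None = None
    metric_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError("values must be a 2D matrix")
        defined = v[~np.isnan(v)]
        if defined.size and (defined.min() < 0 or defined.max() > 1):
            raise ValueError("defined correlation values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def is_self(self) -> bool:
        return self.labels[0] == self.labels[1] and self.values.shape[0] == self.values.shape[1]

    def positions(self, axis: int = 0) -> np.ndarray:
        """Bin-centre AP positions (μm) along the requested axis."""
        return (np.arange(self.values.shape[axis]) + 0.5) * self.bin_length

    def save(self, path: str | Path) -> None:
        """Persist as CSV (rows/cols = bin indices) with a JSON sidecar."""
        path = Path(path)
        pd.DataFrame(self.values).to_csv(path, index_label="bin")
        meta = {"bin_length_um": self.bin_length, "labels": list(self.labels)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CorrelationMatrix":
        path = Path(path)
        values = pd.read_csv(path, index_col="bin").to_numpy(dtype=float)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(values=values, bin_length=meta["bin_length_um"], labels=tuple(meta["labels"]))


def _pair_score(
    fixed: np.ndarray, moving: np.ndarray, opts: RegistrationOptions, pitch: float
) -> tuple[float, bool, float]:
    try:
        tf = register_rigid(fixed, moving, opts, pitch=pitch)
    except ValueError:  # e.g. an all-zero section: no centre of mass
        return float("nan"), False, float("nan")
    score = correlation_score(
        fixed, moving, tf, pitch=pitch, min_overlap_fraction=opts.min_overlap_fraction
    )
    return score, tf.converged, float("nan") if tf.metric is None else tf.metric


def self_correlation_matrix(
    slabs: SlabSeries,
    opts: RegistrationOptions | None = None,
    label: str = "self",
) -> CorrelationMatrix:
    """All-pairs registered correlation of one section series with itself.

    The diagonal is 1 by definition; pairs failing registration or overlap
    checks get the NaN sentinel without aborting the matrix.
    """
    if opts is None:
        opts = RegistrationOptions()
    n = len(slabs)
    values = np.full((n, n), np.nan)
    flags = np.ones((n, n), dtype=bool)
    metrics = np.full((n, n), np.nan)
    np.fill_diagonal(values, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            s, ok, mv = _pair_score(slabs.sections[i], slabs.sections[j], opts, slabs.pitch)
            values[i, j] = values[j, i] = s
            flags[i, j] = flags[j, i] = ok
            metrics[i, j] = metrics[j, i] = mv
    return CorrelationMatrix(
        values=values,
        bin_length=slabs.bin_length,
        labels=(label, label),
        convergence_flags=flags,
        metric_values=metrics,
    )


def cross_correlation_matrix(
    slabs_a: SlabSeries,
    slabs_b: SlabSeries,
    opts: RegistrationOptions | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> CorrelationMatrix:
    """Rectangular correlation matrix between two embryos' section series."""
    if opts is None:
        opts = RegistrationOptions()
    if not np.isclose(slabs_a.bin_length, slabs_b.bin_length):
        raise ValueError(
            f"bin lengths differ: {slabs_a.bin_length} vs {slabs_b.bin_length} μm"
        )
    na, nb = len(slabs_a), len(slabs_b)
    values = np.full((na, nb), np.nan)
    flags = np.ones((na, nb), dtype=bool)
    metrics = np.full((na, nb), np.nan)
    for i in range(na):
        for j in range(nb):
            s, ok, mv = _pair_score(slabs_a.sections[i], slabs_b.sections[j], opts, slabs_a.pitch)
            values[i, j] = s
            flags[i, j] = ok
            metrics[i, j] = mv
    return CorrelationMatrix(
        values=values,
        bin_length=slabs_a.bin_length,
        labels=labels,
        convergence_flags=flags,
        metric_values=metrics,
    )
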
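"""ROI-, segment- and mask-based fluorescence quantification.

Implements the Average Integrated Density readout (the Fiji "IntDen"
convention: sum of pixel intensities × pixel area, averaged over ROIs of a
kind) on 2D projections, plus segment-spanning ROIs and thresholded 3D
binary-mask quantification for autonomous vs non-autonomous signal
comparisons.  Images are indexed (AP, ML) for 2D and (AP, DV, ML) for 3D,
with the usual ``(index + 0.5) * pitch`` physical convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "ROISpec",
    "DensityResult",
    "integrated_density",
    "segment_density",
    "masked_density",
    "normalize_to_reference",
]


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangular ROI in physical coordinates.

    ``center`` and ``size`` are (AP, ML) in μm; ``kind`` groups ROIs for
    the summary statistics (node / internode / segment / ...).
    """

    center: tuple[float, float]
    size: tuple[float, float]
    kind: str = "roi"
    name: str | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError(f"ROI {self.label} size must be positive, got {self.size}")

    @property
    def label(self) -> str:
        return self.name or f"{self.kind}@({self.center[0]:.1f},{self.center[1]:.1f})"

    def to_slices(self, shape: tuple[int, int], pitch: float) -> tuple[slice, slice]:
        """Voxel slices covering the ROI; raises when out of bounds.

        The pixel footprint is fixed by the ROI size alone (every ROI of
        one size covers the same number of pixels), then centred to the
        nearest pixel — ROIs of fixed physical size stay comparable.
        """
        slices = []
        for c, s, n in zip(self.center, self.size, shape):
            n_pix = max(1, int(round(s / pitch)))
            lo = int(round(c / pitch - n_pix / 2))
            hi = lo + n_pix
            if lo < 0 or hi > n:
                raise ValueError(
                    f"ROI {self.label} spans voxels [{lo}, {hi}) outside axis extent {n}"
                )
            slices.append(slice(lo, hi))
        return tuple(slices)


@dataclass(frozen=True)
class DensityResult:
    """Per-ROI integrated densities with per-kind summary statistics.

    ``per_roi`` rows are (ROISpec, integrated_density, mean_density);
    group statistics are recomputable from ``per_roi`` exactly (sample SD,
    NaN for singleton groups).
    """

    per_roi: tuple[tuple[ROISpec, float, float], ...]
    group_means: dict[str, float]
    group_sd: dict[str, float]
    normalization_ref: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": roi.kind,
                    "name": roi.label,
                    "center_ap_um": roi.center[0],
                    "center_ml_um": roi.center[1],
                    "integrated_density": intden,
                    "mean_density": meanden,
                }
                for roi, intden, meanden in self.per_roi
            ]
        )

    def total(self) -> float:
        return float(sum(v for _, v, _ in self.per_roi))


def _summarize(rows: list[tuple[ROISpec, float, float]]) -> DensityResult:
    kinds = sorted({roi.kind for roi, _, _ in rows})
    means, sds = {}, {}
    for kind in kinds:
        vals = np.array([v for roi, v, _ in rows if roi.kind == kind])
        means[kind] = float(vals.mean())
        sds[kind] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return DensityResult(per_roi=tuple(rows), group_means=means, group_sd=sds)


def integrated_density(
    image: np.ndarray,
    rois: list[ROISpec],
    pitch: float = 1.0,
    background: float = 0.0,
) -> DensityResult:
    """Integrated density (sum × pixel area) of each ROI on a 2D projection.

    ``background`` is an optional per-pixel value subtracted before
    integration (none by default).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("integrated_density expects a 2D projection (AP, ML)")
    area = pitch * pitch
    rows = []
    for roi in rois:
        sl = roi.to_slices(img.shape, pitch)
        patch = img[sl] - background
        intden = float(patch.sum() * area)
        rows.append((roi, intden, float(patch.mean())))
    if not rows:
        return DensityResult(per_roi=(), group_means={}, group_sd={})
    return _summarize(rows)


def segment_density(
    image: np.ndarray,
    boundaries: list[float],
    pitch: float = 1.0,
) -> DensityResult:
    """One whole-segment ROI per span between successive AP boundaries."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_density expects a 2D projection (AP, ML)")
    b = np.asarray(boundaries, dtype=float)
    if b.size < 2:
        raise ValueError("need at least two boundaries")
    if (np.diff(b) <= 0).any():
        raise ValueError("boundaries must be strictly increasing")
    ml_extent = img.shape[1] * pitch
    rois = [
        ROISpec(
            center=((lo + hi) / 2, ml_extent / 2),
            size=(hi - lo, ml_extent),
            kind="segment",
            name=f"segment{k}",
        )
        for k, (lo, hi) in enumerate(zip(b[:-1], b[1:]))
    ]
    return integrated_density(img, rois, pitch=pitch)


def _mask_result(signal: np.ndarray, mask: np.ndarray, kind: str, unit_vol: float) -> DensityResult:
    vals = signal[mask]
    intden = float(vals.sum() * unit_vol)
    meanden = float(vals.mean()) if vals.size else float("nan")
    roi = ROISpec(center=(0.0, 0.0), size=(1.0, 1.0), kind=kind, name=kind)
    return DensityResult(
        per_roi=((roi, intden, meanden),),
        group_means={kind: intden},
        group_sd={kind: float("nan")},
    )


def masked_density(
    signal: np.ndarray,
    mask_channel: np.ndarray,
    threshold_method: str | float = "otsu",
    pitch: float = 1.0,
) -> tuple[DensityResult, DensityResult]:
    """Quantify ``signal`` inside vs outside a thresholded binary mask.

    ``mask_channel`` (e.g. a GFP reporter) is thresholded (Otsu by default,
    or a fixed value) into a binary mask co-registered with the signal;
    inside + outside integrated densities always sum to the whole-image
    total exactly.
    """
    sig = np.asarray(signal, dtype=float)
    mc = np.asarray(mask_channel, dtype=float)
    if sig.shape != mc.shape:
        raise ValueError(f"signal {sig.shape} and mask channel {mc.shape} must be co-registered")
    if threshold_method == "otsu":
        thr = threshold_otsu(mc)
    else:
        thr = float(threshold_method)
    mask = mc > thr
    unit = pitch ** sig.ndim
    return _mask_result(sig, mask, "inside", unit), _mask_result(sig, ~mask, "outside", unit)


def normalize_to_reference(
    result: DensityResult,
    reference: DensityResult,
    kind: str | None = None,
    label: str = "reference",
) -> DensityResult:
    """Divide all densities by the reference's group mean.

    ``kind`` selects which reference group supplies the normalizer; by
    default the mean over all reference ROIs is used.
    """
    if kind is not None:
        ref_mean = reference.group_means.get(kind)
        if ref_mean is None:
            raise ValueError(f"reference has no group {kind!r}")
    else:
        vals = [v for _, v, _ in reference.per_roi]
        ref_mean = float(np.mean(vals)) if vals else 0.0
    if not ref_mean > 0:
        raise ValueError(f"reference group mean must be > 0, got {ref_mean}")
    rows = [(roi, v / ref_mean, m / ref_mean) for roi, v, m in result.per_roi]
    out = _summarize(rows) if rows else result
    return replace(out, normalization_ref=label)
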
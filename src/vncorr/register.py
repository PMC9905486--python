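"""Rigid registration of transverse sections and the correlation score.

Each pair of transverse (DV × ML) sections is aligned by a centre-of-mass
translation followed by local optimization of the Mattes mutual-information
metric (the multimodal metric of Matlab's ``imregister``, here through
SimpleITK) with a convergence tolerance of 1e-6 and up to 500 iterations.
The similarity entered into the correlation matrices is the Pearson
correlation of the fixed section against the resampled moving section over
their overlap, clipped to [0, 1].

Conventions: images are indexed (DV, ML); physical positions are
``(index + 0.5) * pitch`` μm; a transform maps moving-image coordinates onto
fixed-image coordinates (rotation about the section centre, then
translation), so a moving image whose content sits +3 voxels from the fixed
content is aligned by a translation of −3 voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

__all__ = [
    "RigidTransform",
    "RegistrationOptions",
    "com_prealign",
    "register_rigid",
    "correlation_score",
]


@dataclass(frozen=True)
class RigidTransform:
    """2D rigid transform: rotation about the section centre, then translation.

    ``translation`` is (DV, ML) in μm; ``rotation`` in radians.  ``metric``
    carries the optimizer's final metric value when produced by
    :func:`register_rigid` (negated Mattes MI, lower = better).
    """

    translation: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0
    converged: bool = True
    metric: float | None = None

    def _rot(self, angle: float) -> np.ndarray:
        c, s = np.cos(angle), np.sin(angle)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Map moving-space physical points (rows of (dv, ml)) to fixed space."""
        pts = np.atleast_2d(points)
        return (pts - center) @ self._rot(self.rotation).T + center + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        t = np.asarray(self.translation)
        return RigidTransform(
            translation=tuple(-(self._rot(-self.rotation) @ t)),
            rotation=-self.rotation,
            converged=self.converged,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``.

        Valid when both share the same rotation centre.
        """
        t_o = np.asarray(other.translation)
        t_s = np.asarray(self.translation)
        return RigidTransform(
            translation=tuple(self._rot(self.rotation) @ t_o + t_s),
            rotation=self.rotation + other.rotation,
        )


@dataclass(frozen=True)
class RegistrationOptions:
    """Knobs of the pairwise registration.

    ``tolerance`` is the optimizer's minimum step / convergence criterion
    and ``max_iterations`` its iteration cap (defaults follow the published
    protocol: 1e-6 and 500).  ``metric`` currently admits only the
    multimodal mutual-information metric.  All sampling is dense, so results
    are deterministic; ``seed`` covers any stochastic optimizer internals.
    """

    metric: str = "mutual_information"
    tolerance: float = 1e-6
    max_iterations: int = 500
    allow_rotation: bool = True
    min_overlap_fraction: float = 0.5
    histogram_bins: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metric != "mutual_information":
            raise ValueError(f"unsupported metric {self.metric!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must lie in (0, 1]")


def _centroid(img: np.ndarray, pitch: float) -> np.ndarray:
    total = img.sum()
    if total <= 0:
        raise ValueError("cannot compute a centre of mass: image has no intensity")
    idx = np.indices(img.shape, dtype=float)
    return np.array([((ax * img).sum() / total + 0.5) * pitch for ax in idx])


def com_prealign(fixed: np.ndarray, moving: np.ndarray, pitch: float = 1.0) -> RigidTransform:
    """Translation aligning the intensity centroid of ``moving`` onto ``fixed``."""
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    t = _centroid(fixed, pitch) - _centroid(moving, pitch)
    return RigidTransform(translation=tuple(t), rotation=0.0)


def _to_sitk(img: np.ndarray, pitch: float) -> sitk.Image:
    out = sitk.GetImageFromArray(np.ascontiguousarray(img, dtype=np.float32))
    out.SetSpacing((pitch, pitch))
    out.SetOrigin((0.5 * pitch, 0.5 * pitch))  # voxel centres at (i + 0.5) * pitch
    return out


def register_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    opts: RegistrationOptions | None = None,
    pitch: float = 1.0,
) -> RigidTransform:
    """Rigidly register ``moving`` onto ``fixed`` by mutual information.

    Starts from the centre-of-mass prealignment and refines translation
    (and rotation when allowed) with a regular-step gradient descent on the
    dense Mattes MI metric.  Never raises on non-convergence: the best
    transform found so far is returned with ``converged=False``.  As a
    safeguard against metric divergence on poorly matched pairs, the result
    falls back to the prealignment whenever the optimized transform scores a
    lower overlap Pearson correlation than the start.
    """
    if opts is None:
        opts = RegistrationOptions()
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError(f"images must share a shape, got {fixed.shape} vs {moving.shape}")

    pre = com_prealign(fixed, moving, pitch=pitch)
    center_phys = np.array(fixed.shape, dtype=float) / 2.0 * pitch  # (dv, ml)

    f_img = _to_sitk(fixed, pitch)
    m_img = _to_sitk(moving, pitch)
    # SimpleITK transforms map fixed-space points into moving space (the
    # resampling direction), i.e. the inverse of this module's convention.
    if opts.allow_rotation:
        init = sitk.Euler2DTransform()
        init.SetCenter((center_phys[1], center_phys[0]))  # (x=ML, y=DV)
        init.SetTranslation((-pre.translation[1], -pre.translation[0]))
    else:
        init = sitk.TranslationTransform(2, (-pre.translation[1], -pre.translation[0]))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=opts.histogram_bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=opts.tolerance,
        numberOfIterations=opts.max_iterations,
        relaxationFactor=0.5,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(init, inPlace=True)

    try:
        out = reg.Execute(f_img, m_img)
        converged = reg.GetOptimizerIteration() < opts.max_iterations
        metric_value = float(reg.GetMetricValue())
    except RuntimeError:
        return replace(pre, converged=False)

    if opts.allow_rotation:
        phi = float(out.GetParameters()[0])
        tau = np.array([out.GetParameters()[2], out.GetParameters()[1]])  # (dv, ml)
    else:
        phi = 0.0
        tau = np.array([out.GetParameters()[1], out.GetParameters()[0]])
    # invert: ours maps moving -> fixed; note the (x, y) -> (DV, ML) axis
    # swap conjugates the rotation, so sitk's angle carries over unchanged
    theta = phi
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    fit = RigidTransform(
        translation=tuple(-(rot @ tau)),
        rotation=theta,
        converged=bool(converged),
        metric=metric_value,
    )

    s_pre = correlation_score(fixed, moving, pre, pitch=pitch, min_overlap_fraction=0.0)
    s_fit = correlation_score(fixed, moving, fit, pitch=pitch, min_overlap_fraction=0.0)
    if np.isnan(s_fit) or (not np.isnan(s_pre) and s_fit < s_pre):
        return replace(pre, converged=False, metric=metric_value)
    return fit


def resample_moving(
    moving: np.ndarray,
    transform: RigidTransform,
    out_shape: tuple[int, int],
    pitch: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``moving`` onto the fixed grid under ``transform``.

    Returns the resampled image and a boolean validity mask; out-of-field
    pixels are zero-filled and masked out (never wrapped), so they cannot
    contribute spurious correlation.
    """
    center = np.array(out_shape, dtype=float) / 2.0 * pitch
    ii, jj = np.indices(out_shape, dtype=float)
    pts_fixed = np.stack([(ii + 0.5) * pitch, (jj + 0.5) * pitch], axis=-1)
    pts_moving = transform.inverse().apply(pts_fixed.reshape(-1, 2), center)
    coords = pts_moving.reshape(*out_shape, 2) / pitch - 0.5
    ci, cj = coords[..., 0], coords[..., 1]
    valid = (
        (ci >= 0) & (ci <= moving.shape[0] - 1) & (cj >= 0) & (cj <= moving.shape[1] - 1)
    )
    res = map_coordinates(np.asarray(moving, dtype=float), [ci, cj], order=1, cval=0.0)
    return res, valid


def correlation_score(
    fixed: np.ndarray,
    moving: np.ndarray,
    transform: RigidTransform,
    pitch: float = 1.0,
    min_overlap_fraction: float = 0.5,
) -> float:
    """Pearson correlation of ``fixed`` vs the registered ``moving``, in [0, 1].

    Computed over the overlap of the two fields after resampling; clipped
    below at zero (the published matrices use a 0–1 scale).  Returns NaN
    when the overlap falls below ``min_overlap_fraction`` of the field or
    is intensity-constant.
    """
    fixed = np.asarray(fixed, dtype=float)
    res, valid = resample_moving(moving, transform, fixed.shape, pitch=pitch)
    if valid.mean() < max(min_overlap_fraction, 1e-12) or valid.sum() < 3:
        return float("nan")
    a = fixed[valid]
    b = res[valid]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return float(np.clip(r, 0.0, 1.0))
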
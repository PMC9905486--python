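"""Synthetic fluorescence phantoms of the embryonic ventral nerve cord.

The late-stage *Drosophila* VNC carries three bilateral pairs of Fasciclin
2-positive longitudinal fascicles (medial, intermediate, lateral).  Along the
anterior-posterior (AP) axis the fascicles adopt, once per segment, a compact
stereotyped transverse configuration (a "3D node") and disperse laterally in
between.  The dispersion is AP-asymmetric: it grows steeply just posterior to
the node, peaks, and relaxes slowly toward the next node.  Node regions are
also brighter (adhesion-molecule enrichment).

This module renders that architecture as a calibrated 3D intensity volume
with fully known ground truth, so every downstream stage of the correlation
pipeline (binning, registration, matrices, traces, metrics) can be validated
without access to confocal data.

Geometry conventions
--------------------
Axes are ordered (AP, DV, ML).  Voxel centres sit at ``(index + 0.5) * pitch``
micrometres; AP increases anterior to posterior.  Nodes are centred at
``(k + 0.5) * period`` so that segment boundaries fall on multiples of the
period.  One hemiside is generated and mirrored about the ML midline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import VolumeStack

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "generate_phantom",
    "expected_trace",
    "preset",
    "PRESET_NAMES",
]

#: photons per intensity unit when Poisson shot noise is enabled
_PHOTON_SCALE = 100.0


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of a VNC phantom.

    Distances are in micrometres unless stated otherwise.

    Parameters
    ----------
    n_segments : int
        Number of abdominal segments (one node each).
    period : float
        AP node-to-node spacing.
    min_offset : float
        AP distance from a node to the dispersion maximum (= the internodal
        correlation minimum), measured posteriorly.
    voxel_pitch : float
        Isotropic voxel size of the rendered volume.
    cross_section : (int, int)
        Transverse extent in voxels, ordered (ML, DV).
    fascicle_positions : tuple of (float, float)
        Per-hemiside fascicle anchor coordinates (ML offset from the
        midline, DV position), default medial / intermediate / lateral.
    fascicle_radius : float
        Gaussian tube radius of a rendered fascicle.
    dispersion_amp : float
        Peak lateral wander of a fascicle centerline between nodes.
    dispersion_asymmetry : float in [0, 1]
        0 places the wander maximum at the internode midpoint (symmetric
        triangular envelope); 1 places it at ``min_offset`` after the node.
    node_enrichment : float >= 1
        Intensity multiplier applied inside node windows.
    node_halfwidth : float
        AP half-extent of the node window.
    psf_sigma : float
        Isotropic Gaussian PSF sigma applied after rendering.
    noise_gaussian_sd : float
        Additive Gaussian (read) noise, in intensity units.
    noise_poisson : bool
        Apply Poisson (shot) noise before the Gaussian noise.
    lateral_dropout : float in [0, 1]
        Per-internode probability that the lateral fascicle is absent
        (mutant-like incompleteness).
    seed : int
        Seed for every stochastic element; identical params give a
        bit-identical volume.
    """

    n_segments: int = 6
    period: float = 28.0
    min_offset: float = 9.0
    voxel_pitch: float = 0.6
    cross_section: tuple[int, int] = (48, 26)
    fascicle_positions: tuple[tuple[float, float], ...] = (
        (2.4, 8.4),   # medial
        (5.2, 9.6),   # intermediate
        (8.4, 7.8),   # lateral
    )
    fascicle_radius: float = 1.0
    dispersion_amp: float = 3.4
    dispersion_asymmetry: float = 1.0
    node_enrichment: float = 1.5
    node_halfwidth: float = 1.5
    psf_sigma: float = 0.35
    noise_gaussian_sd: float = 0.02
    noise_poisson: bool = False
    lateral_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        validate_params(self)

    @property
    def ap_length(self) -> float:
        """Total AP extent of the phantom in micrometres."""
        return self.n_segments * self.period

    @property
    def node_positions(self) -> np.ndarray:
        """AP coordinates of the node centres, one per segment."""
        return (np.arange(self.n_segments) + 0.5) * self.period


@dataclass(frozen=True)
class GroundTruth:
    """Planted architecture of a generated phantom (the test oracle)."""

    node_positions: tuple[float, ...]
    segment_boundaries: tuple[float, ...]
    expected_min_positions: tuple[float, ...]
    enrichment_factor: float


class PhantomParameterError(ValueError):
    """A phantom parameter violates its documented constraint."""


def validate_params(p: PhantomParams) -> None:
    """Raise :class:`PhantomParameterError` naming the first offending field."""

    def _fail(name: str, why: str) -> None:
        raise PhantomParameterError(f"invalid PhantomParams.{name}: {why}")

    if p.n_segments < 1:
        _fail("n_segments", f"must be >= 1, got {p.n_segments}")
    for name in ("period", "voxel_pitch", "fascicle_radius"):
        if getattr(p, name) <= 0:
            _fail(name, f"must be > 0, got {getattr(p, name)}")
    for name in (
        "min_offset",
        "dispersion_amp",
        "node_enrichment",
        "node_halfwidth",
        "psf_sigma",
        "noise_gaussian_sd",
    ):
        if getattr(p, name) < 0:
            _fail(name, f"must be >= 0, got {getattr(p, name)}")
    if p.node_enrichment < 1:
        _fail("node_enrichment", f"must be >= 1, got {p.node_enrichment}")
    if not 0 < p.min_offset < p.period:
        _fail("min_offset", f"must lie strictly inside (0, period), got {p.min_offset}")
    if p.period <= 2 * p.node_halfwidth:
        _fail("node_halfwidth", "period must exceed twice the node halfwidth")
    for name in ("dispersion_asymmetry", "lateral_dropout"):
        if not 0 <= getattr(p, name) <= 1:
            _fail(name, f"must lie in [0, 1], got {getattr(p, name)}")
    if len(p.cross_section) != 2 or any(int(c) < 2 for c in p.cross_section):
        _fail("cross_section", f"needs two extents >= 2 voxels, got {p.cross_section}")
    if not p.fascicle_positions:
        _fail("fascicle_positions", "at least one fascicle anchor required")
    ml_half = p.cross_section[0] * p.voxel_pitch / 2.0
    dv_ext = p.cross_section[1] * p.voxel_pitch
    for ml, dv in p.fascicle_positions:
        if not 0 <= ml <= ml_half:
            _fail("fascicle_positions", f"ML anchor {ml} outside hemiside [0, {ml_half:.2f}]")
        if not 0 <= dv <= dv_ext:
            _fail("fascicle_positions", f"DV anchor {dv} outside [0, {dv_ext:.2f}]")


def _envelope_peak(p: PhantomParams) -> float:
    """AP offset (after a node) of the dispersion-envelope maximum.

    Blends the symmetric internode midpoint toward ``min_offset`` with
    ``dispersion_asymmetry``; clamped into the open internodal span.
    """
    a = p.dispersion_asymmetry
    peak = (1.0 - a) * (p.period / 2.0) + a * p.min_offset
    lo = p.node_halfwidth + p.voxel_pitch
    hi = p.period - p.node_halfwidth - p.voxel_pitch
    return float(np.clip(peak, lo, hi))


def dispersion_envelope(p: PhantomParams, ap: np.ndarray) -> np.ndarray:
    """Wander amplitude (μm) of fascicle centerlines at AP positions ``ap``.

    Periodic with ``p.period``; zero inside node windows; piecewise-linear
    rise to ``dispersion_amp`` at the envelope peak, then linear decay.
    """
    ap = np.asarray(ap, dtype=float)
    phase = np.mod(ap - p.node_positions[0], p.period)
    hw, peak, per = p.node_halfwidth, _envelope_peak(p), p.period
    env = np.zeros_like(phase)
    rising = (phase > hw) & (phase <= peak)
    falling = (phase > peak) & (phase < per - hw)
    env[rising] = (phase[rising] - hw) / (peak - hw)
    env[falling] = (per - hw - phase[falling]) / (per - hw - peak)
    return env * p.dispersion_amp


def _node_window(p: PhantomParams, ap: np.ndarray) -> np.ndarray:
    """Boolean mask of AP positions lying inside a node window."""
    phase = np.mod(np.asarray(ap, dtype=float) - p.node_positions[0], p.period)
    return (phase <= p.node_halfwidth) | (phase >= p.period - p.node_halfwidth)


def generate_phantom(params: PhantomParams) -> tuple[VolumeStack, GroundTruth]:
    """Render a phantom volume and its ground truth.

    The volume is built in four stages: (1) fascicle centerlines — anchors
    plus a per-internode random wander direction scaled by the dispersion
    envelope — rasterized as Gaussian tubes, one hemiside mirrored about the
    midline; (2) node-window intensity enrichment; (3) PSF blur; (4) shot
    then read noise.  Everything stochastic derives from ``params.seed``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    pitch = p.voxel_pitch
    n_ml, n_dv = (int(c) for c in p.cross_section)
    n_ap = int(round(p.ap_length / pitch))

    ap = (np.arange(n_ap) + 0.5) * pitch
    dv = (np.arange(n_dv) + 0.5) * pitch
    ml = (np.arange(n_ml) + 0.5) * pitch
    ml_mid = n_ml * pitch / 2.0

    env = dispersion_envelope(p, ap)
    # internode index of every AP plane (nodes delimit internodes; planes
    # anterior to the first node get index -1)
    inode = np.floor((ap - p.node_positions[0]) / p.period).astype(int)
    n_internodes = p.n_segments + 1  # includes the two half-spans at the ends
    n_fasc = len(p.fascicle_positions)

    # one random wander direction per (fascicle, internode); the envelope is
    # zero at nodes so direction switches are continuous
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_fasc, n_internodes))
    # per-internode lateral-fascicle dropout (lateral = largest ML anchor)
    lateral_idx = int(np.argmax([ml_ for ml_, _ in p.fascicle_positions]))
    dropped = rng.random(n_internodes) < p.lateral_dropout

    vol = np.zeros((n_ap, n_dv, n_ml), dtype=np.float64)
    sig2 = 2.0 * p.fascicle_radius**2
    inode_col = np.clip(inode + 1, 0, n_internodes - 1)  # map -1.. to 0..
    for f, (ml_anchor, dv_anchor) in enumerate(p.fascicle_positions):
        wander_ml = env * np.cos(theta[f, inode_col])
        wander_dv = env * np.sin(theta[f, inode_col])
        amp = np.ones(n_ap)
        if f == lateral_idx and p.lateral_dropout > 0:
            gone = dropped[inode_col] & ~_node_window(p, ap)
            amp[gone] = 0.0
        for side in (+1.0, -1.0):
            c_ml = ml_mid + side * (ml_anchor + wander_ml)
            c_dv = dv_anchor + wander_dv
            g_dv = np.exp(-((dv[None, :] - c_dv[:, None]) ** 2) / sig2)
            g_ml = np.exp(-((ml[None, :] - c_ml[:, None]) ** 2) / sig2)
            vol += amp[:, None, None] * g_dv[:, :, None] * g_ml[:, None, :]

    if p.node_enrichment != 1.0:
        gain = np.where(_node_window(p, ap), p.node_enrichment, 1.0)
        vol *= gain[:, None, None]

    if p.psf_sigma > 0:
        vol = gaussian_filter(vol, sigma=p.psf_sigma / pitch, mode="nearest")

    if p.noise_poisson:
        vol = rng.poisson(np.clip(vol, 0, None) * _PHOTON_SCALE) / _PHOTON_SCALE
    if p.noise_gaussian_sd > 0:
        vol = vol + rng.normal(0.0, p.noise_gaussian_sd, size=vol.shape)
    vol = np.clip(vol, 0.0, None)

    stack = VolumeStack(intensities=vol, voxel_pitch=(pitch, pitch, pitch))
    truth = GroundTruth(
        node_positions=tuple(p.node_positions.tolist()),
        segment_boundaries=tuple((np.arange(p.n_segments + 1) * p.period).tolist()),
        expected_min_positions=tuple((p.node_positions + _envelope_peak(p)).tolist()),
        enrichment_factor=p.node_enrichment,
    )
    return stack, truth


def expected_trace(params: PhantomParams):
    """Analytic noiseless correlation profile implied by the dispersion envelope.

    For Gaussian tubes of radius ``a`` blurred by a PSF of sigma ``s``, the
    normalized overlap between a node section and a section whose fascicles
    are displaced by ``d`` is ``exp(-d**2 / (4 * (a**2 + s**2)))``; with
    ``d = envelope(ap)`` this gives the expected node-anchored trace:
    maximal (1) at nodes, minimal at ``min_offset`` posterior to each node,
    periodic with the segmental period.
    """
    from .traces import NodeTrace  # local import to avoid a cycle

    p = params
    n_ap = int(round(p.ap_length / p.voxel_pitch))
    ap = (np.arange(n_ap) + 0.5) * p.voxel_pitch
    env = dispersion_envelope(p, ap)
    sigma2 = p.fascicle_radius**2 + p.psf_sigma**2
    values = np.exp(-(env**2) / (4.0 * sigma2))
    return NodeTrace(positions=ap, values=values, sd=None, reference_bin=0)


#: calibrated parameter sets reproducing the published architecture metrics
_PRESETS: dict[str, PhantomParams] = {
    # wild type: nodes 28 μm apart, correlation minimum 9 μm posterior to
    # the node, steep descent then shallow recovery
    "wildtype": PhantomParams(
        period=28.0,
        min_offset=9.0,
        dispersion_asymmetry=1.0,
        dispersion_amp=3.4,
        node_enrichment=1.5,
        noise_gaussian_sd=0.02,
    ),
    # puc-like hyperfasciculation mutant: nodes spread to 33 μm, raised
    # dispersion, incompletely formed lateral fascicle, noisier matrices
    "puc_like": PhantomParams(
        period=33.0,
        min_offset=9.0,
        dispersion_asymmetry=0.5,
        dispersion_amp=3.2,
        node_enrichment=1.3,
        noise_gaussian_sd=0.05,
        lateral_dropout=0.5,
    ),
    # zfh1-like mutant: nodes at 33 μm, internodal profile flattened
    # (symmetric dispersion), weaker enrichment, noisier
    "zfh1_like": PhantomParams(
        period=33.0,
        min_offset=16.5,
        dispersion_asymmetry=0.0,
        dispersion_amp=2.6,
        node_enrichment=1.3,
        noise_gaussian_sd=0.05,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> PhantomParams:
    """Return a named phantom preset, optionally overriding fields.

    ``wildtype`` reproduces the published wild-type architecture (28 μm
    internodal distance, 9 μm posterior minimum); ``puc_like`` and
    ``zfh1_like`` the two mutant classes (33 μm internodal distance with
    raised dispersion / lateral dropout, and flattened internodal
    dispersion, respectively).
    """
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(_PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base
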
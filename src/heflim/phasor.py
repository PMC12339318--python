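"""Frequency-domain phasor analysis of FLIM data.

Every pixel's decay I(t) maps to a point in the phasor plane,

    G = integral I(t) cos(n*w*t) dt / integral I(t) dt
    S = integral I(t) sin(n*w*t) dt / integral I(t) dt

with w = 2*pi*f the laser angular repetition frequency (f = 76 MHz here) and
n the harmonic order (default 1).  Single-exponential decays fall on the
"universal circle" — the semicircle of radius 1/2 centered at (0.5, 0) running
from (1, 0), i.e. tau = 0, to (0, 0), i.e. tau = infinity — and mixtures of
two components fall inside it, on the chord joining the component phasors at
their intensity-fraction weights.  This geometry makes the plot a fit-free way
to separate pixel populations: here pixels are grouped by k-means clustering
on (G, S) and the clusters mapped back to the image as a segmentation.

Discrete histograms evaluate the integrals as sums over bin centers; the
resulting O(bin_width/tau) bias can be removed by calibrating against a
reference of known lifetime (a rotation/scaling in the phasor plane).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import CalibrationError, InvalidParameterError
from .fitting import DecayHistogram, LifetimeImage
from .synth import TCSPCCube

__all__ = [
    "PhasorMap",
    "PhasorCalibration",
    "ClusterAssignment",
    "phasor_transform",
    "phasor_point",
    "single_exp_phasor",
    "calibrate",
    "phasor_to_lifetime",
    "cluster_phasor",
    "segment_image",
]

OMEGA_76MHZ = 2.0 * np.pi * 76e6  # rad/s, the default laser repetition frequency

#: Conversion: omega [rad/s] * tau [ps] needs 1e-12.
_PS = 1e-12


@dataclass
class PhasorMap:
    """Per-pixel (G, S) phasor coordinates at one harmonic."""

    G: np.ndarray
    S: np.ndarray
    harmonic: int
    angular_frequency: float  # rad/s
    mask: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        if not (self.G.shape == self.S.shape == self.mask.shape):
            raise InvalidParameterError("G, S and mask must share one shape")
        if self.harmonic < 1:
            raise InvalidParameterError("harmonic must be a positive integer")

    def masked_points(self) -> np.ndarray:
        """(n_pixels, 2) array of (G, S) for masked-in pixels."""
        return np.column_stack([self.G[self.mask], self.S[self.mask]])


@dataclass(frozen=True)
class PhasorCalibration:
    """Rotation/scaling correction derived from a reference fluorophore."""

    reference_lifetime: float  # ps
    phase_correction: float  # radians
    modulation_correction: float

    def __post_init__(self) -> None:
        if self.modulation_correction <= 0:
            raise InvalidParameterError("modulation_correction must be > 0")


@dataclass
class ClusterAssignment:
    """Pixel clusters in phasor space, ordered by descending mean lifetime."""

    labels: np.ndarray  # 2-D int grid; -1 where masked out
    cluster_centers: np.ndarray  # (k, 2) of (G, S)
    cluster_mean_tau_m: np.ndarray  # ps, descending
    k: int


def single_exp_phasor(
    tau: float, n: int = 1, omega: float = OMEGA_76MHZ
) -> tuple[float, float]:
    """Closed-form phasor of a single-exponential decay of lifetime ``tau``.

    G = 1/(1 + (n*w*tau)^2),  S = n*w*tau/(1 + (n*w*tau)^2); the point lies
    exactly on the universal circle for every tau >= 0, with tau=0 at (1, 0)
    and tau -> infinity approaching (0, 0).
    """
    if tau < 0:
        raise InvalidParameterError("tau must be >= 0")
    x = n * omega * tau * _PS
    denom = 1.0 + x * x
    return 1.0 / denom, x / denom


def phasor_point(
    decay: DecayHistogram, n: int = 1, omega: float = OMEGA_76MHZ
) -> tuple[float, float]:
    """Discrete phasor of a single histogram (sums over bin centers)."""
    counts = np.asarray(decay.counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise InvalidParameterError("total counts must be positive")
    t = decay.bin_centers() * _PS
    phase = n * omega * t
    g = float(np.sum(counts * np.cos(phase)) / total)
    s = float(np.sum(counts * np.sin(phase)) / total)
    return g, s


def phasor_transform(
    cube: TCSPCCube, n: int = 1, omega: float | None = None
) -> PhasorMap:
    """Per-pixel phasor map of a TCSPC cube.

    Pixels with zero total counts are masked.  The transform is invariant to
    overall intensity scaling of each pixel's decay.
    """
    if omega is None:
        omega = cube.config.angular_frequency
    counts = cube.counts.astype(float)
    total = counts.sum(axis=0)
    mask = total > 0
    t = cube.config.bin_centers() * _PS
    phase = n * omega * t
    cosw = np.cos(phase)[:, None, None]
    sinw = np.sin(phase)[:, None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.where(mask, (counts * cosw).sum(axis=0) / total, np.nan)
        S = np.where(mask, (counts * sinw).sum(axis=0) / total, np.nan)
    return PhasorMap(G=G, S=S, harmonic=n, angular_frequency=omega, mask=mask)


def derive_calibration(
    reference_measured: tuple[float, float],
    reference_lifetime: float,
    n: int = 1,
    omega: float = OMEGA_76MHZ,
) -> PhasorCalibration:
    """Phase/modulation correction mapping a measured reference onto theory."""
    g_m, s_m = reference_measured
    mod_m = float(np.hypot(g_m, s_m))
    if mod_m == 0:
        raise CalibrationError("reference phasor has zero modulus")
    g_t, s_t = single_exp_phasor(reference_lifetime, n, omega)
    phi = float(np.arctan2(s_t, g_t) - np.arctan2(s_m, g_m))
    mod_ratio = float(np.hypot(g_t, s_t) / mod_m)
    return PhasorCalibration(
        reference_lifetime=reference_lifetime,
        phase_correction=phi,
        modulation_correction=mod_ratio,
    )


def calibrate(
    pmap: PhasorMap,
    reference_measured: tuple[float, float],
    reference_lifetime: float,
) -> PhasorMap:
    """Apply the rotation/scaling that moves the reference onto its
    theoretical universal-circle position; returns a calibrated copy."""
    cal = derive_calibration(
        reference_measured, reference_lifetime, pmap.harmonic, pmap.angular_frequency
    )
    z = (pmap.G + 1j * pmap.S) * cal.modulation_correction * np.exp(
        1j * cal.phase_correction
    )
    return replace(pmap, G=np.real(z), S=np.imag(z), calibrated=True)


def phasor_to_lifetime(
    G: float, S: float, n: int = 1, omega: float = OMEGA_76MHZ
) -> tuple[float, float]:
    """Phase and modulation lifetimes of a phasor point, in ps.

    tau_phase = S / (G * n * w);  tau_mod = (1/(n*w)) * sqrt(1/(G^2+S^2) - 1).
    The two agree exactly on the universal circle; for mixtures (inside the
    circle) tau_phase < tau_mod.
    """
    if G <= 0:
        raise InvalidParameterError("phase lifetime requires G > 0")
    m2 = G * G + S * S
    if not 0 < m2 <= 1:
        raise InvalidParameterError("modulation lifetime requires 0 < G^2+S^2 <= 1")
    nw = n * omega * _PS  # per ps
    tau_phase = S / (G * nw)
    tau_mod = np.sqrt(max(1.0 / m2 - 1.0, 0.0)) / nw
    return float(tau_phase), float(tau_mod)


def cluster_phasor(
    pmap: PhasorMap,
    k: int = 3,
    seed: int = 0,
    lifetime_image: LifetimeImage | None = None,
) -> ClusterAssignment:
    """Group pixels by k-means on their (G, S) position.

    Clusters are relabelled so that cluster 0 has the longest mean lifetime
    (descending order).  Mean lifetime per cluster comes from the paired
    ``lifetime_image`` when given, otherwise from each center's phase
    lifetime.

    Raises
    ------
    InvalidParameterError
        If fewer than ``k`` masked-in pixels are available.
    """
    pts = pmap.masked_points()
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if pts.shape[0] < k:
        raise InvalidParameterError(
            f"only {pts.shape[0]} pixels available for k={k} clusters"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    raw = km.fit_predict(pts)

    # mean lifetime per raw cluster
    tau_means = np.empty(k)
    if lifetime_image is not None:
        tau_vals = lifetime_image.tau_m_map[pmap.mask]
        for j in range(k):
            sel = raw == j
            tau_means[j] = np.nanmean(tau_vals[sel]) if sel.any() else np.nan
    else:
        for j, (g, s) in enumerate(km.cluster_centers_):
            try:
                tau_means[j] = phasor_to_lifetime(
                    g, s, pmap.harmonic, pmap.angular_frequency
                )[0]
            except InvalidParameterError:
                tau_means[j] = np.nan

    order = np.argsort(-tau_means)  # descending lifetime
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)

    labels = np.full(pmap.mask.shape, -1, dtype=int)
    labels[pmap.mask] = relabel[raw]
    return ClusterAssignment(
        labels=labels,
        cluster_centers=km.cluster_centers_[order],
        cluster_mean_tau_m=tau_means[order],
        k=k,
    )


#: Distinct colors cycled for segmentation rendering (RGB, 0-255).
_SEGMENT_PALETTE = np.array(
    [
        [230, 25, 75],
        [60, 180, 75],
        [0, 130, 200],
        [255, 225, 25],
        [145, 30, 180],
        [70, 240, 240],
        [245, 130, 48],
        [240, 50, 230],
    ],
    dtype=np.uint8,
)


def segment_image(assignment: ClusterAssignment) -> np.ndarray:
    """Render a cluster assignment as an RGB label image.

    One distinct color per cluster; pixels outside the mask are black.
    """
    h, w = assignment.labels.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for j in range(assignment.k):
        rgb[assignment.labels == j] = _SEGMENT_PALETTE[j % len(_SEGMENT_PALETTE)]
    return rgb
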
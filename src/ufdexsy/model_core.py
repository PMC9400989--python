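"""Physical constants, instrument/sequence/sample descriptions and the
two-site exchange rate matrix.

All quantities are SI internally (tesla, seconds, metres, hertz).  The
instrument modelled is a single-sided permanent magnet (0.3 T, ~13 MHz for
protons) whose strong built-in constant gradient (7.28 T m^-1) provides both
diffusion weighting and the spatial axis of the single-scan 2D acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GAMMABAR_1H",
    "CoilProfile",
    "InstrumentSpec",
    "EncodingSpec",
    "CpmgSpec",
    "ExchangeSite",
    "TwoSiteSample",
    "larmor_frequency",
    "encoding_extent",
    "rate_matrix",
    "build_coil_profile",
]

#: Proton gyromagnetic ratio over 2*pi, CODATA value [Hz/T].
GAMMABAR_1H = 42.577478461e6


def larmor_frequency(B0: float, gammabar: float = GAMMABAR_1H) -> float:
    """Proton resonance frequency [Hz] in a static field ``B0`` [T].

    At 0.3 T this is 12.77 MHz, commonly quoted as 13 MHz.
    """
    if B0 < 0:
        raise ValueError(f"B0 must be nonnegative, got {B0}")
    return gammabar * B0


def encoding_extent(bandwidth: float, G: float, gammabar: float = GAMMABAR_1H) -> float:
    """Spatial extent [m] addressed by a chirp of the given bandwidth [Hz]
    in a constant gradient ``G`` [T/m].

    A 93 kHz chirp in 7.28 T/m covers 300 um of sample depth.
    """
    if bandwidth <= 0 or G <= 0 or gammabar <= 0:
        raise ValueError("bandwidth, G and gammabar must be positive")
    return bandwidth / (gammabar * G)


@dataclass(frozen=True)
class CoilProfile:
    """Relative excitation/detection sensitivity of the surface coil vs depth.

    Piecewise-linear through ``(depth, sensitivity)`` nodes, normalized so
    the peak sensitivity is 1, clamped to the boundary node values outside
    the node range.
    """

    depths: np.ndarray
    sensitivities: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        s = np.asarray(self.sensitivities, dtype=float)
        if d.ndim != 1 or d.size < 2 or d.shape != s.shape:
            raise ValueError("profile needs >=2 matching (depth, sensitivity) nodes")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(s < 0) or not np.any(s > 0):
            raise ValueError("sensitivities must be nonnegative and not all zero")
        if self.interpolation != "linear":
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "sensitivities", s / s.max())

    def __call__(self, z: np.ndarray | float) -> np.ndarray:
        """Evaluate the normalized sensitivity at depth(s) ``z`` [m]."""
        return np.interp(z, self.depths, self.sensitivities)

    @classmethod
    def flat(cls) -> "CoilProfile":
        """Uniform unit sensitivity (idealized coil)."""
        return cls(np.array([-1.0, 1.0]), np.array([1.0, 1.0]))


def build_coil_profile(image: Sequence[tuple[float, float]] | np.ndarray) -> CoilProfile:
    """Turn a 1D depth image of a homogeneous sample into a sensitivity profile.

    The image intensity of a homogeneous water sample is proportional to the
    combined excitation/detection sensitivity of the coil, so after peak
    normalization it can be used directly as the coil profile.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("image must be an (n, 2) array of (depth, intensity)")
    return CoilProfile(arr[:, 0], arr[:, 1])


def default_coil_profile(extent: float, n_nodes: int = 33) -> CoilProfile:
    """Synthetic bell-shaped sensitivity over the encoding region.

    A stand-in for a measured coil image: a raised Gaussian peaked at
    mid-depth, falling to ~0.3 at the region edges, qualitatively matching
    the bell-shaped depth response of a single-sided surface coil.
    """
    z = np.linspace(-0.1 * extent, 1.1 * extent, n_nodes)
    bump = 0.3 + 0.7 * np.exp(-((z - 0.5 * extent) ** 2) / (2 * (0.35 * extent) ** 2))
    return CoilProfile(z, bump)


@dataclass(frozen=True)
class InstrumentSpec:
    """Static field, constant gradient and coil of the single-sided magnet."""

    B0: float = 0.3
    G: float = 7.28
    gammabar: float = GAMMABAR_1H
    coil: CoilProfile = field(default_factory=CoilProfile.flat)

    def __post_init__(self) -> None:
        if self.B0 <= 0 or self.G <= 0 or self.gammabar <= 0:
            raise ValueError("B0, G and gammabar must be positive")

    @property
    def larmor(self) -> float:
        return larmor_frequency(self.B0, self.gammabar)


@dataclass(frozen=True)
class EncodingSpec:
    """Stimulated-echo spatial-encoding block.

    The chirp refocusing pulse makes the effective gradient-pulse length
    grow linearly with depth across the region it addresses, so depth plays
    the role the gradient amplitude plays in a conventional pulsed-gradient
    diffusion experiment.

    Parameters
    ----------
    bandwidth
        Chirp bandwidth [Hz]; with the gradient it fixes the encoded extent.
    delta_max
        Effective gradient-pulse length at the deepest encoded layer [s].
    storage_interval
        Diffusion (storage) interval of the stimulated echo [s].
    edge_depth, edge_width_frac
        Amplitude ``a`` and width (as a fraction of the extent) of the two
        Gaussian sensitivity dips at the chirp sweep edges, where the swept
        pulse acts non-ideally.
    """

    bandwidth: float = 93e3
    delta_max: float = 160e-6
    storage_interval: float = 5e-3
    edge_depth: float = 1.0
    edge_width_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.bandwidth <= 0 or self.delta_max <= 0 or self.storage_interval <= 0:
            raise ValueError("bandwidth, delta_max and storage_interval must be positive")
        if not self.delta_max < self.storage_interval:
            raise ValueError("delta_max must be shorter than the storage interval")
        if not 0.0 <= self.edge_depth <= 1.0:
            raise ValueError("edge_depth must lie in [0, 1]")
        if self.edge_width_frac <= 0:
            raise ValueError("edge_width_frac must be positive")

    def extent(self, instrument: InstrumentSpec) -> float:
        """Encoded region thickness L [m] for a given instrument."""
        return encoding_extent(self.bandwidth, instrument.G, instrument.gammabar)


@dataclass(frozen=True)
class CpmgSpec:
    """Single-scan CPMG readout under the constant gradient."""

    echo_time: float = 150e-6
    n_echoes: int = 256
    points_per_echo: int = 128
    dwell_time: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.echo_time, self.dwell_time) <= 0:
            raise ValueError("echo_time and dwell_time must be positive")
        if self.n_echoes < 1 or self.points_per_echo < 1:
            raise ValueError("n_echoes and points_per_echo must be >= 1")

    @property
    def bandwidth(self) -> float:
        """Acquisition bandwidth [Hz]."""
        return 1.0 / self.dwell_time


@dataclass(frozen=True)
class ExchangeSite:
    """One exchange pool: a diffusion environment with relaxation times."""

    label: str
    D: float
    p: float
    T1: float = math.inf
    T2: float = math.inf

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"population must lie in (0, 1), got {self.p}")
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("relaxation times must be positive (may be inf)")


@dataclass(frozen=True)
class TwoSiteSample:
    """Two exchanging water pools with an overall exchange rate ``k``.

    ``k`` is the sum of the forward and backward first-order rate constants,
    i.e. the rate of the single decaying eigenmode of the exchange kinetics.
    """

    sites: tuple[ExchangeSite, ExchangeSite]
    k: float

    def __post_init__(self) -> None:
        if len(self.sites) != 2:
            raise ValueError("exactly two sites required")
        psum = self.sites[0].p + self.sites[1].p
        if abs(psum - 1.0) > 1e-9:
            raise ValueError(f"populations must sum to 1, got {psum}")
        if self.k < 0:
            raise ValueError("exchange rate k must be nonnegative")

    @property
    def populations(self) -> np.ndarray:
        return np.array([self.sites[0].p, self.sites[1].p])

    @property
    def diffusivities(self) -> np.ndarray:
        return np.array([self.sites[0].D, self.sites[1].D])

    @classmethod
    def yeast_water(
        cls,
        k: float = 14.0,
        p_intra: float = 0.24,
        D_intra: float = 1.4e-9,
        D_extra: float = 3.6e-9,
        T1: float = math.inf,
        T2: float = math.inf,
    ) -> "TwoSiteSample":
        """Intra/extracellular water in a yeast suspension (hyperpolarized,
        ~40 C after dissolution, hence the elevated D values)."""
        return cls(
            sites=(
                ExchangeSite("intra", D_intra, p_intra, T1, T2),
                ExchangeSite("extra", D_extra, 1.0 - p_intra, T1, T2),
            ),
            k=k,
        )


def rate_matrix(k: float, p: Sequence[float]) -> np.ndarray:
    """First-order two-site exchange rate matrix K [1/s].

    Convention: ``dm/dt = K m`` with ``m`` the per-site magnetization
    (column) vector.  ``K = [[-k_ab, k_ba], [k_ab, -k_ba]]`` with detailed
    balance ``p_a k_ab = p_b k_ba`` and overall rate ``k = k_ab + k_ba``.
    Column sums are zero (conservation), the stationary vector is ``p`` and
    the nonzero eigenvalue is ``-k``.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (2,) or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"p must be two positive fractions summing to 1, got {p}")
    if k < 0:
        raise ValueError("k must be nonnegative")
    k_ab = k * p[1]  # rate out of site a; detailed balance p_a*k_ab = p_b*k_ba
    k_ba = k * p[0]
    return np.array([[-k_ab, k_ba], [k_ab, -k_ba]])
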
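"""Exchange-map inversion of a raw 2D matrix.

The raw matrix of a two-pool sample is, to good approximation, a linear
combination of four basis surfaces indexed by (start pool, end pool): each
basis carries the spatial diffusion encoding of the start pool's D, the
mixing-time blurring, and the CPMG decay of the end pool's D.  With the two
D values fixed from reference measurements, the four pool weights enter the
model linearly and are recovered by nonnegative least squares; normalizing
them to unit sum removes the (hyperpolarization-dependent) absolute
amplitude and yields the 2x2 exchange map — the diagonal and cross-peak
intensities of the experiment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .encoding import b_value_profile, default_grid, edge_attenuation
from .mixing import diffusion_blur, guard_band
from .model_core import CpmgSpec, EncodingSpec, InstrumentSpec, TwoSiteSample
from .readout import RawData2D, cpmg_attenuation

__all__ = ["ExchangeMap", "basis_surfaces", "fit_map"]

SITE_PAIRS = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class ExchangeMap:
    """Normalized 2x2 pool-to-pool intensities at one mixing time.

    ``weights[j, k]`` is the relative intensity of magnetization that was in
    pool j during the spatial encoding and in pool k during the readout;
    diagonal entries are the DEXSY diagonal peaks, off-diagonal entries the
    exchange cross peaks.  Entries are nonnegative and sum to one.
    """

    tau_M: float
    weights: np.ndarray
    residual: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (2, 2):
            raise ValueError("weights must be 2x2")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be normalized to unit sum")
        object.__setattr__(self, "weights", w)


def basis_surfaces(sample: TwoSiteSample, encoding_spec: EncodingSpec,
                   cpmg: CpmgSpec, instrument: InstrumentSpec, tau_M: float,
                   z_grid: np.ndarray | None = None) -> dict[tuple[int, int], np.ndarray]:
    """Unit-amplitude model surfaces for the four (start, end) pool pairs.

    surface(j, k) = [encode with D_j] -> [blur over tau_M with D_j for
    diagonal bases, (D_j + D_k)/2 for cross bases, unit unencoded
    reservoir] -> [detect with D_k, T2_k], evaluated on the depth grid.
    Deterministic given the specs; the D values are fixed inputs, not
    fitted.
    """
    if z_grid is None:
        z_grid = default_grid(encoding_spec, instrument, cpmg.points_per_echo)
    D = sample.diffusivities
    if math.isclose(D[0], D[1], rel_tol=1e-6):
        warnings.warn("degenerate D values: basis surfaces are rank deficient",
                      RuntimeWarning, stacklevel=2)
    dz = z_grid[1] - z_grid[0]
    b = b_value_profile(z_grid, encoding_spec, instrument)
    excite = instrument.coil(z_grid) * edge_attenuation(z_grid, encoding_spec, instrument)
    detect = instrument.coil(z_grid)
    echoes = np.arange(1, cpmg.n_echoes + 1)
    g = guard_band(float(D.max()), tau_M, dz)
    sl = slice(g, g + z_grid.size)
    surfaces: dict[tuple[int, int], np.ndarray] = {}
    for j, k in SITE_PAIRS:
        # unit-amplitude encoded profile on the extended grid: unencoded
        # reservoir (value 1) outside the encoded region, so the basis
        # carries the same free in/outflow as the forward model
        prof = np.ones(z_grid.size + 2 * g)
        prof[sl] = np.exp(-b * D[j]) * excite
        # a molecule detected in a different pool than it started in spends,
        # on average, about half the mixing time in each pool (k tau ~ 1
        # regime), so cross bases blur with the mean diffusivity
        D_blur = D[j] if j == k else 0.5 * (D[j] + D[k])
        prof = diffusion_blur(prof, D_blur, tau_M, 1.0, dz)[sl]
        A = cpmg_attenuation(D[k], sample.sites[k].T2, cpmg.echo_time, echoes, instrument)
        surfaces[(j, k)] = np.outer(detect * prof, A)
    return surfaces


def fit_map(data: RawData2D, bases: dict[tuple[int, int], np.ndarray],
            tau_M: float | None = None) -> ExchangeMap:
    """Nonnegative least-squares decomposition of a raw matrix.

    Minimizes ``|| S - sum_jk w_jk B_jk ||`` over ``w >= 0`` and normalizes
    the weights to unit sum.  Scaling the data by any positive constant
    leaves the map unchanged.
    """
    S = data.matrix
    if not np.any(S):
        raise ValueError("all-zero data cannot be decomposed")
    shapes = {b.shape for b in bases.values()}
    if shapes != {S.shape}:
        raise ValueError(f"basis shapes {shapes} do not match data shape {S.shape}")
    A = np.column_stack([bases[pair].ravel() for pair in SITE_PAIRS])
    gram = A.T @ A
    cond = float(np.linalg.cond(gram))
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"basis surfaces are rank deficient (Gram condition {cond:.3g})"
        )
    w, rnorm = nnls(A, S.ravel())
    total = w.sum()
    if total <= 0:
        raise ValueError("nonnegative fit assigned zero weight to every basis")
    weights = np.array([[w[0], w[1]], [w[2], w[3]]]) / total
    if tau_M is None:
        tau_M = float(data.provenance.get("tau_M_s", float("nan")))
    return ExchangeMap(
        tau_M=tau_M,
        weights=weights,
        residual=float(rnorm),
        diagnostics={
            "gram_condition": cond,
            "raw_weights": w,
            "relative_residual": float(rnorm / np.linalg.norm(S)),
        },
    )
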
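"""Two-site exchange kinetics of the normalized peak intensities.

For first-order exchange between pools a and b with overall rate k and
equilibrium populations (p_a, p_b), the joint probability that a molecule
is in pool j during the first encoding and pool k during the readout after
a mixing time tau is

    I_jj(tau) = p_j (p_j + (1 - p_j) e^{-k tau})
    I_jk(tau) = p_j p_k (1 - e^{-k tau}),   j != k,

which sums to one identically and has symmetric cross terms.  Fitting these
curves to the normalized exchange maps at several mixing times yields
(k, p_intra); the per-pool rate constants and the intracellular residence
time follow as k_intra = p_intra k, k_extra = p_extra k and
tau_intra = 1 / k_intra.  T1 is taken as infinite inside the fit: the
per-experiment normalization removes overall longitudinal decay along with
the varying hyperpolarization level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .inversion import ExchangeMap

__all__ = [
    "ExchangeFitResult",
    "model_intensities",
    "fit_exchange",
    "derive_rates",
    "plot_fit",
]

K_MAX = 1e3  # fit bound on the overall exchange rate [1/s]


def model_intensities(k: float, p_intra: float, tau_M: float | np.ndarray) -> np.ndarray:
    """Normalized 2x2 intensities at mixing time(s) ``tau_M``.

    Row = start pool (0 = intra), column = end pool.  For scalar ``tau_M``
    the result is (2, 2); for an array it is (n, 2, 2).
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    if not 0.0 < p_intra < 1.0:
        raise ValueError("p_intra must lie in (0, 1)")
    tau = np.asarray(tau_M, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau_M must be nonnegative")
    p = np.array([p_intra, 1.0 - p_intra])
    E = np.exp(-k * tau)[..., None, None]
    P_inf = np.outer(p, p)[None] if tau.ndim else np.outer(p, p)
    diag = (np.eye(2) * p[None, :])[None] if tau.ndim else np.eye(2) * p[None, :]
    out = P_inf + E * (diag - P_inf)
    return out if tau.ndim else out.reshape(2, 2)


@dataclass(frozen=True)
class ExchangeFitResult:
    """Fitted exchange parameters with delta-method uncertainties."""

    k: float
    p_intra: float
    k_err: float
    p_err: float
    covariance: np.ndarray | None
    k_intra: float
    k_extra: float
    tau_intra: float
    k_intra_err: float
    k_extra_err: float
    tau_intra_err: float
    residuals: np.ndarray
    tau_values: np.ndarray
    n_points: int
    identifiable: bool
    diagnostics: dict = field(default_factory=dict)


def derive_rates(k: float, p_intra: float,
                 covariance: np.ndarray | None = None
                 ) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Per-pool rate constants and intracellular lifetime from (k, p_intra).

    k_intra = p_intra k is the apparent rate constant associated with the
    intracellular pool, k_extra = (1 - p_intra) k with the extracellular
    one, and tau_intra = 1/k_intra is the intracellular residence time.
    Uncertainties propagate to first order from the (k, p_intra) covariance
    (pass None for point values only; errors are then nan).
    """
    if k <= 0:
        raise ValueError("k must be positive to derive rates and lifetime")
    if not 0.0 < p_intra < 1.0:
        raise ValueError("p_intra must lie in (0, 1)")
    k_intra = p_intra * k
    k_extra = (1.0 - p_intra) * k
    tau_intra = 1.0 / k_intra
    if covariance is None:
        return (k_intra, k_extra, tau_intra), (math.nan, math.nan, math.nan)
    C = np.asarray(covariance, dtype=float)
    g_intra = np.array([p_intra, k])            # d(k p)/d(k, p)
    g_extra = np.array([1.0 - p_intra, -k])
    var_intra = g_intra @ C @ g_intra
    var_extra = g_extra @ C @ g_extra
    k_intra_err = math.sqrt(max(var_intra, 0.0))
    k_extra_err = math.sqrt(max(var_extra, 0.0))
    tau_intra_err = k_intra_err / k_intra**2
    return (k_intra, k_extra, tau_intra), (k_intra_err, k_extra_err, tau_intra_err)


def plot_fit(maps: list[ExchangeMap], fit: ExchangeFitResult, path) -> None:
    """Peak intensities vs mixing time with the fitted model curves.

    Requires matplotlib (optional dependency).  Diagonal and cross
    intensities of each map are drawn as points, the fitted two-site model
    as solid lines, with a shaded first-order confidence band on the
    curves where the fit covariance is available.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    taus = np.array([m.tau_M for m in maps])
    pts = np.stack([m.weights for m in maps])
    grid = np.linspace(0.0, 1.15 * taus.max(), 200)
    curves = model_intensities(fit.k, fit.p_intra, grid)

    labels = [("intra-intra", (0, 0)), ("intra-extra", (0, 1)),
              ("extra-intra", (1, 0)), ("extra-extra", (1, 1))]
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, (j, kk) in labels:
        line, = ax.plot(grid * 1e3, curves[:, j, kk], label=label)
        ax.plot(taus * 1e3, pts[:, j, kk], "o", color=line.get_color())
        if fit.covariance is not None:
            # first-order band from the (k, p) covariance
            eps_k, eps_p = 1e-4 * max(fit.k, 1.0), 1e-5
            dk = (model_intensities(fit.k + eps_k, fit.p_intra, grid)[:, j, kk]
                  - curves[:, j, kk]) / eps_k
            dp = (model_intensities(fit.k, fit.p_intra + eps_p, grid)[:, j, kk]
                  - curves[:, j, kk]) / eps_p
            J = np.column_stack([dk, dp])
            band = np.sqrt(np.einsum("ni,ij,nj->n", J, fit.covariance, J))
            ax.fill_between(grid * 1e3, curves[:, j, kk] - band,
                            curves[:, j, kk] + band,
                            color=line.get_color(), alpha=0.2, lw=0)
    ax.set_xlabel("mixing time [ms]")
    ax.set_ylabel("relative peak intensity")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _residual(params: Parameters, taus: np.ndarray, intensities: np.ndarray) -> np.ndarray:
    model = model_intensities(params["k"].value, params["p_intra"].value, taus)
    return (intensities - model).ravel()


def fit_exchange(maps: list[ExchangeMap], k_init: float = 10.0,
                 p_init: float = 0.5) -> ExchangeFitResult:
    """Least-squares fit of the two-site model to exchange maps.

    All four intensities of every map are fitted jointly with equal weight
    (each experiment is separately normalized, so the maps are directly
    comparable).  Bounds: k in [0, 1e3] 1/s, p_intra in (0, 1).
    Uncertainties come from the Jacobian-based covariance at the optimum;
    if the design cannot constrain k (e.g. all maps at the fully mixed
    limit) the result is flagged non-identifiable.
    """
    if len(maps) < 2:
        raise ValueError("at least 2 maps at distinct mixing times are required")
    taus = np.array([m.tau_M for m in maps], dtype=float)
    if np.any(~np.isfinite(taus)) or len(np.unique(taus)) < 2:
        raise ValueError("mixing times must be finite and distinct")
    intensities = np.stack([m.weights for m in maps])
    sums = intensities.reshape(len(maps), 4).sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("maps must be normalized to unit total intensity")

    params = Parameters()
    params.add("k", value=k_init, min=0.0, max=K_MAX)
    params.add("p_intra", value=p_init, min=1e-6, max=1.0 - 1e-6)
    out = minimize(_residual, params, args=(taus, intensities), method="leastsq")

    k_hat = float(out.params["k"].value)
    p_hat = float(out.params["p_intra"].value)
    k_err = out.params["k"].stderr
    p_err = out.params["p_intra"].stderr
    cov = out.covar if out.covar is not None else None
    identifiable = (
        out.errorbars and k_err is not None and np.isfinite(k_err) and k_err < K_MAX
    )
    k_err = float(k_err) if k_err is not None else math.inf
    p_err = float(p_err) if p_err is not None else math.inf
    rates, rate_errs = derive_rates(max(k_hat, np.finfo(float).tiny), p_hat,
                                    cov if identifiable else None)
    return ExchangeFitResult(
        k=k_hat, p_intra=p_hat, k_err=k_err, p_err=p_err, covariance=cov,
        k_intra=rates[0], k_extra=rates[1], tau_intra=rates[2],
        k_intra_err=rate_errs[0], k_extra_err=rate_errs[1], tau_intra_err=rate_errs[2],
        residuals=np.asarray(out.residual), tau_values=taus,
        n_points=int(out.ndata), identifiable=bool(identifiable),
        diagnostics={"redchi": float(out.redchi), "nfev": int(out.nfev),
                     "success": bool(out.success)},
    )
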
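"""Multimodality detection for log body-size and log size-ratio distributions.

Body-size distributions of species-rich clades are often "lumpy": species
cluster around a few preferred sizes with regular spacing between clusters.
This module quantifies that structure on the natural-log length scale with
two complementary tools:

* finite Gaussian mixtures ("latent class analysis"): models with 1..kmax
  components are fitted by EM and the best class count is chosen by an
  information criterion (BIC by default);
* Gaussian kernel density estimates with peak finding, for a
  smoothing-based view of the same modes.

Adjacent mode locations ``m_i < m_{i+1}`` on the log scale translate into
dimensionless peak-to-peak body-length ratios ``exp(m_{i+1} - m_i) >= 1``,
the quantity used to compare lump spacing across regions and data sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from ._rng import substream_seed

#: Lower bound for component standard deviations on the log scale.  Catalogue
#: lengths are rounded, so exact ties are common; without a floor EM can
#: collapse a component onto a tied value with zero variance.
SD_FLOOR = 1e-4

__all__ = [
    "MixtureFit",
    "ModeAnalysisResult",
    "DensityCurve",
    "fit_gaussian_mixture",
    "select_best_mixture",
    "kernel_density",
    "find_density_peaks",
    "peak_to_peak_ratios",
    "SD_FLOOR",
]


@dataclass(frozen=True)
class MixtureFit:
    """A fitted univariate Gaussian mixture with k components.

    Components are stored sorted by mean.  ``means`` and ``sds`` are on the
    natural-log length scale; ``weights`` lie on the simplex.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    aic: float
    converged: bool
    n_obs: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sds < SD_FLOOR - 1e-12):
            raise ValueError("component sd below variance floor")
        if not np.all(np.isfinite(self.means)):
            raise ValueError("non-finite component means")


@dataclass(frozen=True)
class ModeAnalysisResult:
    """Outcome of mixture-based mode detection over a range of class counts.

    ``modes`` are the component means of the selected fit, on the log scale,
    after merging near-duplicate components; ``peak_to_peak_ratios`` are the
    back-transformed spacings between consecutive modes.
    """

    fits: tuple[MixtureFit, ...]
    best_k: int
    modes: np.ndarray
    peak_to_peak_ratios: np.ndarray
    criterion: str = "bic"
    skipped_k: tuple[int, ...] = field(default_factory=tuple)

    @property
    def best_fit(self) -> MixtureFit:
        for f in self.fits:
            if f.k == self.best_k:
                return f
        raise RuntimeError("best_k not among fitted class counts")

    @property
    def modes_linear(self) -> np.ndarray:
        """Mode locations back-transformed from log scale (mm or ratio)."""
        return np.exp(self.modes)


@dataclass(frozen=True)
class DensityCurve:
    """A kernel density estimate evaluated on an even log-scale grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def _validate_values(values: np.ndarray, k: int) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("input values must be finite")
    if values.size < 2 * k:
        raise ValueError(
            f"insufficient observations for {k} classes: "
            f"need >= {2 * k}, got {values.size}"
        )
    if np.ptp(values) == 0.0:
        raise ValueError("all values identical: zero-variance input is degenerate")
    return values


def _fit_to_mixturefit(gm: GaussianMixture, X: np.ndarray) -> MixtureFit:
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    return MixtureFit(
        k=gm.n_components,
        weights=gm.weights_[order].copy(),
        means=means[order].copy(),
        sds=np.maximum(sds[order], SD_FLOOR),
        loglik=float(gm.score(X) * X.shape[0]),
        bic=float(gm.bic(X)),
        aic=float(gm.aic(X)),
        converged=bool(gm.converged_),
        n_obs=X.shape[0],
    )


def fit_gaussian_mixture(
    values: np.ndarray,
    k: int,
    n_init: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> MixtureFit:
    """EM-fit a k-component univariate Gaussian mixture to log lengths.

    The best of ``n_init`` seeded k-means restarts (by log-likelihood) is
    returned.  Requires at least ``2 * k`` observations and non-degenerate
    (not all-identical) input.

    Parameters
    ----------
    values : array-like
        Observations on the natural-log scale.
    k : int
        Number of mixture components (latent classes).
    n_init, seed, tol, max_iter :
        EM restart count, restart seed, relative log-likelihood convergence
        tolerance, and iteration cap.
    """
    values = _validate_values(values, k)
    X = values.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=SD_FLOOR**2,
        tol=tol,
        max_iter=max_iter,
        n_init=n_init,
        init_params="kmeans",
        random_state=substream_seed(seed, f"gmm-k{k}"),
    )
    with warnings.catch_warnings():
        # non-convergence within max_iter is reported via the converged flag
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(X)
    return _fit_to_mixturefit(gm, X)


def _refit_from_parent(
    values: np.ndarray, parent: MixtureFit, tol: float, max_iter: int
) -> MixtureFit:
    """Refit k = parent.k + 1 starting from the parent solution.

    The parent's widest component is split into two half-weight copies offset
    by one parent sd.  Guarantees (up to EM monotonicity) that the child's
    likelihood is at least the parent's, which keeps the fitted
    log-likelihood non-decreasing in k even when independent restarts miss
    the nested optimum.
    """
    X = values.reshape(-1, 1)
    j = int(np.argmax(parent.sds))
    means = np.concatenate(
        [
            np.delete(parent.means, j),
            [parent.means[j] - parent.sds[j], parent.means[j] + parent.sds[j]],
        ]
    )
    weights = np.concatenate(
        [np.delete(parent.weights, j), [parent.weights[j] / 2] * 2]
    )
    sds = np.concatenate([np.delete(parent.sds, j), [parent.sds[j]] * 2])
    gm = GaussianMixture(
        n_components=parent.k + 1,
        covariance_type="full",
        reg_covar=SD_FLOOR**2,
        tol=tol,
        max_iter=max_iter,
        n_init=1,
        weights_init=weights / weights.sum(),
        means_init=means.reshape(-1, 1),
        precisions_init=(1.0 / sds**2).reshape(-1, 1, 1),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(X)
    return _fit_to_mixturefit(gm, X)


def _merge_close_modes(fit: MixtureFit) -> np.ndarray:
    """Collapse components whose means are closer than half their pooled sd.

    Mixtures often model one physical lump with two heavily overlapping
    components; reporting both as modes would fabricate ratios near 1.
    Components with ``|mu_a - mu_b| < 0.5 * (sd_a + sd_b)`` are merged into
    their weight-weighted mean until all survivors are separated.
    """
    weights = fit.weights.copy()
    means = fit.means.copy()
    sds = fit.sds.copy()
    while len(means) > 1:
        gaps = np.diff(means)
        limits = 0.5 * (sds[:-1] + sds[1:])
        viol = np.where(gaps < limits)[0]
        if viol.size == 0:
            break
        i = int(viol[np.argmin(gaps[viol] - limits[viol])])
        w = weights[i] + weights[i + 1]
        m = (weights[i] * means[i] + weights[i + 1] * means[i + 1]) / w
        s = (weights[i] * sds[i] + weights[i + 1] * sds[i + 1]) / w
        weights = np.concatenate([weights[:i], [w], weights[i + 2 :]])
        means = np.concatenate([means[:i], [m], means[i + 2 :]])
        sds = np.concatenate([sds[:i], [s], sds[i + 2 :]])
        order = np.argsort(means)
        weights, means, sds = weights[order], means[order], sds[order]
    return means


def select_best_mixture(
    values: np.ndarray,
    kmin: int = 1,
    kmax: int = 10,
    criterion: str = "bic",
    n_init: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> ModeAnalysisResult:
    """Fit mixtures with kmin..kmax classes and select the best class count.

    Class counts with fewer than ``2 * k`` observations are skipped and
    recorded.  Selection minimizes the stated criterion ("bic" default,
    "aic" selectable); ties go to the smaller k.  Modes of the winning fit
    are merged (see :func:`_merge_close_modes`) before peak-to-peak ratios
    are computed.
    """
    if kmin < 1 or kmax < kmin:
        raise ValueError(f"need kmax >= kmin >= 1, got kmin={kmin}, kmax={kmax}")
    if criterion not in ("bic", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    values = _validate_values(np.asarray(values, dtype=float), kmin)

    fits: list[MixtureFit] = []
    skipped: list[int] = []
    for k in range(kmin, kmax + 1):
        if values.size < 2 * k:
            skipped.append(k)
            continue
        fit = fit_gaussian_mixture(
            values, k, n_init=n_init, seed=seed, tol=tol, max_iter=max_iter
        )
        # keep the maximized log-likelihood non-decreasing in k: if random
        # restarts did worse than the nested (k-1)-solution allows, refit
        # from a split of the previous best.
        if fits and fits[-1].k == k - 1 and fit.loglik < fits[-1].loglik:
            nested = _refit_from_parent(values, fits[-1], tol, max_iter)
            if nested.loglik > fit.loglik:
                fit = nested
        fits.append(fit)
    if not fits:
        raise ValueError("no feasible class count for the given data")

    scores = [getattr(f, criterion) for f in fits]
    best_fit = fits[int(np.argmin(scores))]
    modes = _merge_close_modes(best_fit)
    return ModeAnalysisResult(
        fits=tuple(fits),
        best_k=best_fit.k,
        modes=modes,
        peak_to_peak_ratios=peak_to_peak_ratios(modes),
        criterion=criterion,
        skipped_k=tuple(skipped),
    )


def kernel_density(
    values: np.ndarray,
    bandwidth_rule: str | float = "silverman",
    grid_size: int = 512,
) -> DensityCurve:
    """Gaussian-kernel density of log lengths on an even grid.

    The grid spans ``[min - 3h, max + 3h]`` where ``h`` is the realized
    bandwidth; the returned curve integrates to 1 within 1%.
    ``bandwidth_rule`` is either a scipy rule name ("silverman", "scott")
    or a numeric bandwidth in log units.
    """
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise ValueError("kernel density needs at least 2 distinct values")
    if isinstance(bandwidth_rule, str):
        kde = gaussian_kde(values, bw_method=bandwidth_rule)
    else:
        h = float(bandwidth_rule)
        if h <= 0:
            raise ValueError("numeric bandwidth must be > 0")
        kde = gaussian_kde(values, bw_method=h / values.std(ddof=1))
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_size)
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=h)


def find_density_peaks(
    curve: DensityCurve, min_prominence: float = 0.05
) -> np.ndarray:
    """Interior local maxima of a density curve, filtered by prominence.

    ``min_prominence`` is a fraction of the curve's maximum density.
    Returns peak locations (log scale) sorted ascending; may be empty.
    """
    idx, _ = find_peaks(
        curve.density, prominence=min_prominence * curve.density.max()
    )
    return curve.grid[idx]


def peak_to_peak_ratios(modes: np.ndarray) -> np.ndarray:
    """Back-transformed spacings between consecutive log-scale modes.

    For sorted log-scale mode locations m_1 < ... < m_n, returns
    ``exp(m_{i+1} - m_i)``, the dimensionless length ratio between adjacent
    lumps.  All ratios are >= 1 by construction.
    """
    modes = np.asarray(modes, dtype=float).ravel()
    if np.any(np.diff(modes) < 0):
        raise ValueError("modes must be sorted ascending")
    return np.exp(np.diff(modes))
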
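"""Identification-probability models over candidate-pair metric values.

Given the population of one metric's values across all candidate pairs of a
session pair, these models assign each pair a probability of being the same
cell.  Three methods are provided:

* ``percentile`` — the (tie-averaged) fraction of the population that is
  worse than the value;
* ``mixture`` — a two-component Gaussian mixture ``h = w f + (1-w) g`` fit
  by nonlinear least squares to a boundary-reflected kernel density
  estimate, with the Bayes posterior ``w f / (w f + (1-w) g)``;
* ``soft_kmeans`` — fuzzy two-means membership of the identified cluster,
  with fuzzifier ``m`` controlling the spread.

Populations smaller than ``MIN_MODEL_VALUES`` fall back to percentiles, and
an (all-identical) degenerate population yields the neutral probability 0.5.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

MIN_MODEL_VALUES = 10  # below this, density fits are unstable
DEFAULT_FUZZIFIER = 2.0
_GRID_SIZE = 256


class DegeneratePopulationError(ValueError):
    """All metric values identical; no density can be estimated."""


def _orient(values: np.ndarray, x, direction: str):
    """Map values so that *larger is worse* regardless of metric direction."""
    if direction == "distance":
        return values, x
    return -values, -np.asarray(x, dtype=float)


def percentile_probability(values, x, direction: str = "distance"):
    """Tie-averaged fraction of the population worse than ``x``.

    For a distance metric "worse" means larger; for a similarity metric,
    smaller.  Scalar or vector ``x``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty population")
    v, xq = _orient(values, np.atleast_1d(x), direction)
    worse = (v[None, :] > xq[:, None]).sum(axis=1)
    ties = (v[None, :] == xq[:, None]).sum(axis=1)
    p = (worse + 0.5 * ties) / v.size
    return float(p[0]) if np.isscalar(x) else p


def estimate_density(values, bounds: tuple[float, float]):
    """Boundary-reflected Gaussian KDE (Silverman bandwidth) over ``bounds``.

    Returns a vectorized density function supported on [lo, hi]; reflection
    at each finite bound removes the usual boundary bias so that the density
    still integrates to ~1 over the bounds.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = bounds
    if values.size < 2 or np.ptp(values) == 0:
        raise DegeneratePopulationError("cannot estimate density from identical values")
    kde = gaussian_kde(values, bw_method="silverman")

    def density(x):
        x = np.asarray(x, dtype=float)
        d = kde(x)
        if np.isfinite(lo):
            d = d + kde(2 * lo - x)
        if np.isfinite(hi):
            d = d + kde(2 * hi - x)
        return np.where((x >= lo) & (x <= hi), d, 0.0)

    return density


def _gaussian(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


@dataclasses.dataclass
class IdentificationModel:
    """Fitted two-population model mapping a metric value to P(same cell)."""

    method: str
    direction: str
    # mixture parameters
    weight: float | None = None  # mass of the identified component f
    mu_f: float | None = None
    sd_f: float | None = None
    mu_g: float | None = None
    sd_g: float | None = None
    # soft-kmeans parameters
    centers: tuple[float, float] | None = None  # (identified, other)
    fuzzifier: float = DEFAULT_FUZZIFIER
    # percentile fallback keeps the population itself
    population: np.ndarray | None = None

    def posterior(self, x):
        """Identification probability for value(s) ``x``, in [0, 1]."""
        if self.method == "mixture":
            return self._mixture_posterior(x)
        if self.method == "soft_kmeans":
            return self._fuzzy_membership(x)
        if self.method == "percentile":
            return percentile_probability(self.population, x, self.direction)
        if self.method == "neutral":
            return 0.5 if np.isscalar(x) else np.full(np.shape(x), 0.5)
        raise ValueError(f"unknown method {self.method!r}")

    def _mixture_posterior(self, x):
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        f = self.weight * _gaussian(x, self.mu_f, self.sd_f)
        g = (1.0 - self.weight) * _gaussian(x, self.mu_g, self.sd_g)
        h = f + g
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(h > 0, f / np.where(h > 0, h, 1.0), np.nan)
        # where both densities vanish (deep tails): nearest component mode
        empty = ~np.isfinite(p)
        if np.any(empty):
            nearer_f = np.abs(x - self.mu_f) <= np.abs(x - self.mu_g)
            p = np.where(empty, np.where(nearer_f, 1.0, 0.0), p)
        p = np.clip(p, 0.0, 1.0)
        return float(p[0]) if scalar else p

    def _fuzzy_membership(self, x):
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        c_id, c_other = self.centers
        d_id = np.abs(x - c_id)
        d_other = np.abs(x - c_other)
        expo = 2.0 / (self.fuzzifier - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (d_id / d_other) ** expo
            p = 1.0 / (1.0 + ratio)
        p = np.where(d_id == 0, 1.0, p)
        p = np.where((d_other == 0) & (d_id > 0), 0.0, p)
        return float(p[0]) if scalar else np.clip(p, 0.0, 1.0)

    def discriminatory_power(self, bounds=(-np.inf, np.inf), n_grid=512) -> float | None:
        """Overlap coefficient of f and g (mixture models): the integral of
        min(f, g).  Small overlap = strong discrimination.  None when the
        model has no fitted component densities."""
        if self.method != "mixture":
            return None
        lo = min(self.mu_f - 6 * self.sd_f, self.mu_g - 6 * self.sd_g)
        hi = max(self.mu_f + 6 * self.sd_f, self.mu_g + 6 * self.sd_g)
        lo = max(lo, bounds[0])
        hi = min(hi, bounds[1])
        x = np.linspace(lo, hi, n_grid)
        f = _gaussian(x, self.mu_f, self.sd_f)
        g = _gaussian(x, self.mu_g, self.sd_g)
        return float(np.trapezoid(np.minimum(f, g), x))

    def to_dict(self) -> dict:
        d = {"method": self.method, "direction": self.direction}
        if self.method == "mixture":
            d.update(
                weight=self.weight, mu_f=self.mu_f, sd_f=self.sd_f,
                mu_g=self.mu_g, sd_g=self.sd_g,
                discriminatory_power=self.discriminatory_power(),
            )
        elif self.method == "soft_kmeans":
            d.update(centers=list(self.centers), fuzzifier=self.fuzzifier)
        return d


def _two_means_split(values: np.ndarray, seed: int = 0):
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    return centers, labels


def fit_two_component_mixture(
    values,
    direction: str = "distance",
    bounds: tuple[float, float] = (-np.inf, np.inf),
    seed: int = 0,
) -> IdentificationModel:
    """Fit ``h(x) = w f(x) + (1-w) g(x)`` (Gaussian f, g) to the reflected
    KDE of the population by bounded nonlinear least squares on a fixed grid.

    The component whose mean is better for the metric's direction (smaller
    for distances, larger for similarities) is labeled *identified* (f).
    Falls back to soft k-means if the fit diverges.
    """
    values = np.asarray(values, dtype=float)
    if values.size < MIN_MODEL_VALUES:
        return IdentificationModel(
            method="percentile", direction=direction, population=values
        )
    if np.ptp(values) == 0:
        return IdentificationModel(method="neutral", direction=direction)
    density = estimate_density(values, bounds)
    lo = bounds[0] if np.isfinite(bounds[0]) else float(values.min())
    hi = bounds[1] if np.isfinite(bounds[1]) else float(values.max())
    if hi <= lo:
        hi = lo + 1.0
    grid = np.linspace(lo, hi, _GRID_SIZE)
    target = density(grid)

    centers, labels = _two_means_split(values, seed)
    order = np.argsort(centers)
    spread = max(np.std(values), 1e-6)
    p0 = [0.5]
    for c in centers[order]:
        sd0 = np.std(values[labels == np.where(centers == c)[0][0]])
        p0 += [float(c), float(max(sd0, 0.05 * spread))]

    def model(x, w, mu1, sd1, mu2, sd2):
        return w * _gaussian(x, mu1, sd1) + (1 - w) * _gaussian(x, mu2, sd2)

    span = max(hi - lo, spread)
    fit_bounds = (
        [0.0, lo - span, 1e-6 * span, lo - span, 1e-6 * span],
        [1.0, hi + span, 10 * span, hi + span, 10 * span],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, grid, target, p0=p0, bounds=fit_bounds,
                                maxfev=20000)
    except (RuntimeError, ValueError):
        logger.warning("mixture fit diverged; falling back to soft k-means")
        return fit_soft_kmeans(values, direction, seed=seed)
    w, mu1, sd1, mu2, sd2 = popt
    # pick the identified component by direction
    if (direction == "distance") == (mu1 <= mu2):
        weight, mu_f, sd_f, mu_g, sd_g = w, mu1, sd1, mu2, sd2
    else:
        weight, mu_f, sd_f, mu_g, sd_g = 1 - w, mu2, sd2, mu1, sd1
    return IdentificationModel(
        method="mixture", direction=direction, weight=float(weight),
        mu_f=float(mu_f), sd_f=float(sd_f), mu_g=float(mu_g), sd_g=float(sd_g),
    )


def fit_soft_kmeans(
    values,
    direction: str = "distance",
    fuzzifier: float = DEFAULT_FUZZIFIER,
    seed: int = 0,
) -> IdentificationModel:
    """Two-cluster fuzzy membership model on a 1-D metric population."""
    values = np.asarray(values, dtype=float)
    if values.size < MIN_MODEL_VALUES:
        return IdentificationModel(
            method="percentile", direction=direction, population=values
        )
    if np.ptp(values) == 0:
        return IdentificationModel(method="neutral", direction=direction)
    centers, _ = _two_means_split(values, seed)
    lo_c, hi_c = float(centers.min()), float(centers.max())
    ident, other = (lo_c, hi_c) if direction == "distance" else (hi_c, lo_c)
    return IdentificationModel(
        method="soft_kmeans", direction=direction,
        centers=(ident, other), fuzzifier=fuzzifier,
    )


def soft_kmeans_probability(
    values, x, direction: str = "distance",
    fuzzifier: float = DEFAULT_FUZZIFIER, seed: int = 0,
):
    """Convenience wrapper: fit fuzzy two-means on ``values`` and return the
    identified-cluster membership of ``x``."""
    return fit_soft_kmeans(values, direction, fuzzifier, seed).posterior(x)


def fit_identification_model(
    values,
    method: str = "soft_kmeans",
    direction: str = "distance",
    bounds: tuple[float, float] = (-np.inf, np.inf),
    fuzzifier: float = DEFAULT_FUZZIFIER,
    seed: int = 0,
) -> IdentificationModel:
    """Dispatch on ``method`` ('percentile' | 'mixture' | 'soft_kmeans')."""
    values = np.asarray(values, dtype=float)
    if method == "percentile":
        if values.size == 0:
            raise ValueError("empty population")
        return IdentificationModel(
            method="percentile", direction=direction, population=values
        )
    if method == "mixture":
        return fit_two_component_mixture(values, direction, bounds, seed)
    if method == "soft_kmeans":
        return fit_soft_kmeans(values, direction, fuzzifier, seed)
    raise ValueError(f"unknown method {method!r}")
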
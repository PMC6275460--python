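"""Gaussian-mixture model of the normalized coverage.

The normalized coverage of a well-behaved library is dominated by a
central, approximately Gaussian population centred on 1; deleted,
depleted and duplicated regions form a second, minor population. A k=2
Gaussian mixture is fitted by expectation-maximization; the central
component's parameters (mu0, sigma0) then convert every base into a
z-score, from which adaptive thresholds in the original coverage space
and the centralness summary statistic follow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .detrend import DetrendedTrack

__all__ = [
    "MixtureFit",
    "ThresholdSpec",
    "fit_em",
    "zscores",
    "adaptive_thresholds",
    "tolerance_interval",
    "expected_chance_outliers",
    "centralness",
    "InsufficientDataError",
    "DegenerateDataError",
]

SIGMA_FLOOR = 1e-6
#: z sentinel for bases where the running median is zero: more extreme
#: than any finite threshold, so they always satisfy the low-side test.
Z_SENTINEL = -np.inf


class InsufficientDataError(ValueError):
    """Fewer than the minimum number of usable values for fitting."""


class DegenerateDataError(ValueError):
    """All usable values identical; a mixture fit is meaningless."""


@dataclass
class MixtureFit:
    """Parameters of the two-component Gaussian mixture.

    Component 0 is the central distribution (dominant weight, centred
    near 1); component 1 models the outliers. ``single_population`` is
    set when the fitted secondary component is not a separated outlier
    class, in which case (mu0, sigma0) are the plain mean/SD of the data
    (see the methods note).
    """

    mu0: float
    sigma0: float
    pi0: float
    mu1: float
    sigma1: float
    pi1: float
    n_iter: int
    loglik: float
    converged: bool
    single_population: bool = False
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


@dataclass
class ThresholdSpec:
    """Double-threshold configuration in z-score units.

    ``n_high``/``n_low`` are the outer (acceptance) thresholds; a cluster
    must reach them to be reported. The inner (extension) thresholds are
    ``m = alpha * n`` with ``alpha <= 1``, usually 1/2: a cluster extends
    over every contiguous base beyond m.
    """

    n_high: float = 4.0
    n_low: float = -4.0
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.n_high <= 0:
            raise ValueError("n_high must be > 0")
        if self.n_low >= 0:
            raise ValueError("n_low must be < 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    @property
    def m_high(self) -> float:
        return self.alpha * self.n_high

    @property
    def m_low(self) -> float:
        return self.alpha * self.n_low


def _log_normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)


def fit_em(
    normalized: np.ndarray,
    mask: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> MixtureFit:
    """Fit the k=2 Gaussian mixture to normalized coverage by EM.

    Parameters
    ----------
    normalized : ndarray
        Normalized coverage values (>= 0).
    mask : ndarray of bool, optional
        True where a value must be ignored (running median zero). Exact
        zeros of the normalized coverage (deleted bases) are always
        ignored as well.
    max_iter, tol : int, float
        EM stops when the mean per-base log-likelihood improves by less
        than ``tol``, or after ``max_iter`` iterations.

    Notes
    -----
    Initialization is robust: the central component starts at the median
    with sigma = 1.4826 * MAD, the outlier component at the mean of the
    values outside +/- 3 sigma of the median. After convergence the
    central component is the one with the dominant weight (the working
    hypothesis is that the central population predominates). If the
    secondary component is not a separated outlier class -- weight below
    0.1 with more than half of its mass inside mu0 +/- 3 sigma0 -- the
    data are treated as a single population and (mu0, sigma0) revert to
    the plain mean/SD.
    """
    x = np.asarray(normalized, dtype=np.float64)
    keep = x > 0
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    x = x[keep]
    if x.size < 100:
        raise InsufficientDataError(
            f"mixture fit needs >= 100 unmasked values, got {x.size}"
        )
    if np.all(x == x[0]):
        raise DegenerateDataError("all unmasked values are identical")

    # float32 working copy on whole-chromosome inputs: the per-iteration
    # cost is memory-bound and the parameter precision needed is far
    # coarser than float32 resolution; small inputs stay float64 so the
    # likelihood path is monotone to machine precision.
    x32 = x.astype(np.float32) if x.size > 500_000 else x

    mu0 = float(np.median(x))
    sigma0 = max(1.4826 * float(np.median(np.abs(x - mu0))), 1e-3)
    tail = x[np.abs(x - mu0) > 3 * sigma0]
    mu1 = float(tail.mean()) if tail.size else 0.5
    sigma1 = 2 * sigma0
    pi0, pi1 = 0.95, 0.05

    n = x.size
    ll_old = -np.inf
    ll_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        la = math.log(pi0) + _log_normal_pdf(x32, mu0, sigma0)
        lb = math.log(pi1) + _log_normal_pdf(x32, mu1, sigma1)
        m = np.maximum(la, lb)
        lse = m + np.log(np.exp(la - m) + np.exp(lb - m))
        r = np.exp(la - lse)
        ll = float(lse.mean(dtype=np.float64))
        ll_path.append(ll)

        w0 = float(r.sum(dtype=np.float64))
        w1 = n - w0
        rx = float(np.dot(r, x32))
        mu0 = rx / w0
        mu1 = (float(x.sum()) - rx) / max(w1, 1e-12)
        d0 = (x32 - mu0) ** 2
        sigma0 = max(math.sqrt(float(np.dot(r, d0)) / w0), SIGMA_FLOOR)
        d1 = (x32 - mu1) ** 2
        sigma1 = max(
            math.sqrt(
                max(float(d1.sum(dtype=np.float64)) - float(np.dot(r, d1)), 0.0)
                / max(w1, 1e-12)
            ),
            SIGMA_FLOOR,
        )
        pi0 = min(max(w0 / n, 1e-12), 1 - 1e-12)
        pi1 = 1.0 - pi0

        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll

    # component 0 = dominant (central) population
    if pi1 > pi0:
        mu0, sigma0, pi0, mu1, sigma1, pi1 = mu1, sigma1, pi1, mu0, sigma0, pi0

    single = False
    if pi1 < 0.1:
        # mass of the secondary component inside the central +/- 3 sigma band
        z_hi = (mu0 + 3 * sigma0 - mu1) / (sigma1 * math.sqrt(2))
        z_lo = (mu0 - 3 * sigma0 - mu1) / (sigma1 * math.sqrt(2))
        inside = 0.5 * (erf(z_hi) - erf(z_lo))
        if inside > 0.5:
            single = True
            mu0 = float(x.mean())
            sigma0 = max(float(x.std()), SIGMA_FLOOR)
            pi0 = min(max(float(np.mean(np.abs(x - mu0) <= 3 * sigma0)), 1e-12), 1 - 1e-12)
            pi1 = 1.0 - pi0

    return MixtureFit(
        mu0=mu0,
        sigma0=sigma0,
        pi0=pi0,
        mu1=mu1,
        sigma1=sigma1,
        pi1=pi1,
        n_iter=it,
        loglik=ll_path[-1] * n,
        converged=converged,
        single_population=single,
        loglik_path=np.asarray(ll_path),
    )


def zscores(detrended: DetrendedTrack, fit: MixtureFit) -> np.ndarray:
    """Per-base z-score relative to the central distribution.

    ``z = (normalized - mu0) / sigma0`` where the running median is
    positive. Bases with a zero running median get the low-side sentinel
    (-inf). The reconstruction identity
    ``(mu0 + z * sigma0) * rm == coverage`` holds exactly on unmasked
    bases.
    """
    if fit.sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    z = (detrended.normalized - fit.mu0) / fit.sigma0
    z[detrended.undefined_mask] = Z_SENTINEL
    return z


def adaptive_thresholds(
    rm: np.ndarray, fit: MixtureFit, spec: ThresholdSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Detection thresholds mapped back to the original coverage space.

    Returns ``(lower, upper)`` per-base coverage thresholds
    ``(mu0 + n * sigma0) * rm``; the lower threshold is clipped at 0.
    """
    rm = np.asarray(rm, dtype=np.float64)
    upper = (fit.mu0 + spec.n_high * fit.sigma0) * rm
    lower = np.clip((fit.mu0 + spec.n_low * fit.sigma0) * rm, 0.0, None)
    return lower, upper


def tolerance_interval(n: float) -> float:
    """Central mass of a standard normal between -n and +n, erf(n/sqrt(2))."""
    if n <= 0:
        raise ValueError("threshold n must be > 0")
    return float(erf(n / math.sqrt(2)))


def expected_chance_outliers(G: int, n: float) -> float:
    """Expected number of bases beyond +/- n by pure chance in a genome of G bases."""
    if G < 0:
        raise ValueError("genome length must be >= 0")
    return G * (1.0 - tolerance_interval(n))


def centralness(z: np.ndarray, n: float) -> float:
    """One minus the fraction of bases with |z| >= n.

    Equals 1 when there are no outliers; values below 0.5 mean the
    "central" distribution is not central, and trigger a warning.
    """
    z = np.asarray(z)
    if z.size == 0:
        raise ValueError("empty z-score vector")
    theta = 1.0 - float(np.count_nonzero(np.abs(z) >= n)) / z.size
    if theta < 0.5:
        warnings.warn(
            f"centralness {theta:.3f} is below 0.5 and therefore meaningless",
            stacklevel=2,
        )
    return theta
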
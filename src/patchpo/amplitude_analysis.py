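"""Amplitude histograms and equidistant-constrained Gaussian mixture fits.

A membrane patch holding N identical channels produces an amplitude
histogram with up to N+1 peaks at currents

    mu_k = mu_0 + k * i,        k = 0 .. N,

with mu_0 the baseline (all channels closed) and i the signed unitary
amplitude.  The histogram is fitted by least squares with a sum of Gaussian
components whose means are *structurally* constrained to that ladder; free
parameters are mu_0, i, the per-component widths sigma_k and the component
weights A_k (points per component).  Each component's contribution to a bin
is its Gaussian mass integrated over the bin (A_k times the CDF difference),
which stays well defined even when peaks are narrower than a bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from scipy.special import ndtr

from .trace_io import Trace

__all__ = [
    "AmplitudeHistogram",
    "GmmFit",
    "GmmFitError",
    "DEFAULT_BIN_WIDTH_PA",
    "build_amplitude_histogram",
    "detect_levels",
    "fit_constrained_gmm",
]

#: histogram resolution for ~0.3 pA unitary currents
DEFAULT_BIN_WIDTH_PA = 0.01

# peak-detection conventions: prominence threshold as a fraction of the tallest
# bin, and minimum peak separation as a fraction of the first spacing estimate
_PEAK_PROMINENCE_FRAC = 0.05
_PEAK_MIN_SEPARATION_FRAC = 0.5
_N_MULTISTART = 5


class GmmFitError(RuntimeError):
    """Mixture fit failed to converge; carries the best attempt."""

    def __init__(self, message: str, best: "GmmFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class AmplitudeHistogram:
    """Binned current amplitudes at uniform bin width."""

    bin_edges: np.ndarray  # length n_bins + 1, strictly increasing, uniform
    counts: np.ndarray  # non-negative integers

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if edges.size != counts.size + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.max(np.abs(widths - widths[0])) > 1e-9 * widths[0]:
            raise ValueError("bins must be uniform")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_samples(self) -> int:
        return int(np.sum(self.counts))


@dataclass(frozen=True)
class GmmFit:
    """Result of the equidistant-constrained mixture fit.

    ``weights[k]`` estimates the number of samples spent at level k (k open
    channels counted away from the baseline component); ``unitary_amplitude``
    is the signed spacing i of the ladder (0 by convention for a
    single-component fit, where no spacing is defined).
    """

    mu0: float
    unitary_amplitude: float
    sigmas: np.ndarray
    weights: np.ndarray
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    converged: bool = True

    @property
    def n_components(self) -> int:
        return int(len(self.weights))

    @property
    def means(self) -> np.ndarray:
        return self.mu0 + np.arange(self.n_components) * self.unitary_amplitude

    def predicted_counts(self, hist: AmplitudeHistogram) -> np.ndarray:
        return _model_counts(
            hist.bin_edges,
            self.mu0,
            self.unitary_amplitude,
            self.sigmas,
            self.weights,
        )


# ---------------------------------------------------------------------------
# histogram construction


def build_amplitude_histogram(
    trace: Trace | np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH_PA
) -> AmplitudeHistogram:
    """Bin the trace samples at fixed width covering [min, max].

    Bin *centers* are snapped to integer multiples of ``bin_width``, so a
    discrete current level at a multiple of the width sits at the middle of
    its bin and shifting a trace by a whole number of bins shifts the
    histogram exactly.
    """
    samples = trace.samples if isinstance(trace, Trace) else np.asarray(trace, float)
    if samples.size == 0:
        raise ValueError("cannot histogram an empty trace")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    k_lo = math.floor(samples.min() / bin_width + 0.5)
    k_hi = math.floor(samples.max() / bin_width + 0.5)
    edges = (np.arange(k_lo, k_hi + 2) - 0.5) * bin_width
    # guard against float round-off excluding the extremes
    edges[0] = min(edges[0], samples.min())
    edges[-1] = max(edges[-1], samples.max())
    counts, _ = np.histogram(samples, bins=edges)
    return AmplitudeHistogram(bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# level detection


def detect_levels(hist: AmplitudeHistogram) -> tuple[int, float, float]:
    """Locate equidistant current levels in an amplitude histogram.

    Returns ``(n_levels, initial_mu0, initial_i)``: the number of detected
    peaks, the baseline estimate (the peak nearest the least-inward current,
    i.e. the maximum with the inward-negative sign convention) and the signed
    median peak spacing.  Always succeeds; a featureless histogram falls back
    to a single level at its mode.
    """
    counts = hist.counts.astype(float)
    centers = hist.bin_centers
    if counts.size == 1 or np.all(counts == counts[0]):
        mode = centers[int(np.argmax(counts))]
        return 1, float(mode), 0.0

    # Rare high-occupancy levels (binomial tails) sit orders of magnitude
    # below the modal peak, so prominence is assessed on log(1 + counts):
    # a level is a peak if it rises a fixed fraction of the full log range
    # above its surroundings.  A light 3-bin smooth suppresses shot noise.
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    log_counts = np.log1p(smooth)
    # pad so peaks at the histogram edges are eligible
    padded = np.concatenate([[0.0], log_counts, [0.0]])
    prominence = _PEAK_PROMINENCE_FRAC * log_counts.max()
    peaks, _ = signal.find_peaks(padded, prominence=prominence)
    peaks -= 1
    if peaks.size == 0:
        mode = centers[int(np.argmax(counts))]
        return 1, float(mode), 0.0
    if peaks.size > 1:
        # second pass: enforce a minimum separation of half the spacing
        spacing_bins = float(np.median(np.diff(np.sort(peaks))))
        min_dist = max(1, int(round(_PEAK_MIN_SEPARATION_FRAC * spacing_bins)))
        peaks, _ = signal.find_peaks(
            padded, prominence=prominence, distance=min_dist
        )
        peaks -= 1

    # the smoothing can shift a sharp peak by a bin (plateaus resolve to
    # their left edge); snap each peak to the raw-count maximum nearby
    refined = []
    for p in peaks:
        lo = max(0, p - 1)
        hi = min(counts.size, p + 2)
        refined.append(lo + int(np.argmax(counts[lo:hi])))
    peaks = np.unique(refined)

    positions = np.sort(centers[peaks])
    if positions.size == 1:
        return 1, float(positions[0]), 0.0
    spacing = float(np.median(np.diff(positions)))
    # baseline = least-inward level; inward currents are negative
    mu0 = float(positions[-1])
    return int(positions.size), mu0, -spacing


# ---------------------------------------------------------------------------
# constrained mixture fit


def _model_counts(edges, mu0, amp, sigmas, weights):
    """Expected counts per bin: sum_k A_k * [Phi(hi) - Phi(lo)] per bin."""
    ks = np.arange(len(weights))
    mus = mu0 + ks * amp
    z = (edges[None, :] - mus[:, None]) / np.asarray(sigmas)[:, None]
    cdf = ndtr(z)
    return np.sum(np.asarray(weights)[:, None] * np.diff(cdf, axis=1), axis=0)


def _pack(mu0, amp, sigmas, weights):
    return np.concatenate([[mu0, amp], sigmas, weights])


def _unpack(theta, n_comp):
    mu0, amp = theta[0], theta[1]
    sigmas = theta[2 : 2 + n_comp]
    weights = theta[2 + n_comp :]
    return mu0, amp, sigmas, weights


def _initial_guess(hist, n_components, mu0, init_i, shared_width):
    counts = hist.counts.astype(float)
    centers = hist.bin_centers
    w = hist.bin_width
    sigma0 = max(0.5 * w, shared_width)
    mus = mu0 + np.arange(n_components) * init_i
    weights = np.empty(n_components)
    if n_components == 1 or init_i == 0.0:
        weights[:] = counts.sum() / n_components
    else:
        half = abs(init_i) / 2.0
        for k, mu in enumerate(mus):
            sel = np.abs(centers - mu) <= half
            weights[k] = max(counts[sel].sum(), 1.0)
    return _pack(mu0, init_i, np.full(n_components, sigma0), weights)


def fit_constrained_gmm(
    hist: AmplitudeHistogram,
    n_components: int | None = None,
    init: tuple[float, float] | None = None,
    shared_sigma: bool = False,
) -> GmmFit:
    """Least-squares fit of the equidistant Gaussian mixture to bin counts.

    Parameters
    ----------
    hist : AmplitudeHistogram
    n_components : int, optional
        Number of ladder components (levels).  Defaults to the number of
        detected levels — the minimum channel count that explains the
        observed levels.
    init : (mu0, i), optional
        Starting baseline and unitary amplitude; defaults to
        :func:`detect_levels` output.
    shared_sigma : bool
        Constrain all components to one width (more stable on sparse
        levels); per-component widths by default.

    Raises
    ------
    GmmFitError
        If no restart converges; the exception carries the best attempt.
    """
    n_levels, det_mu0, det_i = detect_levels(hist)
    if n_components is None:
        n_components = n_levels
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if init is not None:
        det_mu0, det_i = float(init[0]), float(init[1])
    if n_components > 1 and det_i == 0.0:
        # no spacing detected; seed with a width-scaled guess toward inward
        det_i = -(5.0 * hist.bin_width)

    counts = hist.counts.astype(float)
    edges = hist.bin_edges
    total = counts.sum()
    span = edges[-1] - edges[0]
    w = hist.bin_width

    # rough width guess: SD of samples closest to the baseline peak
    shared_width = max(0.5 * w, 0.05 * abs(det_i)) if det_i else 2.0 * w

    # components wider than half the level spacing would overlap their
    # neighbours and stop representing discrete levels; cap sigma there.
    # The floor is a quarter bin: anything narrower is indistinguishable
    # at the histogram's resolution and only stalls the optimizer.
    sigma_cap = max(0.5 * abs(det_i), 2.0 * w) if n_components > 1 else span

    # currents outside [min, max] were genuinely never observed: fit against
    # guard bins of zero counts so no component can park its mass beyond the
    # histogram's support where residuals would not see it
    n_guard = max(10, int(math.ceil(4.0 * sigma_cap / w)))
    ext_edges = np.concatenate([
        edges[0] + np.arange(-n_guard, 0) * w,
        edges,
        edges[-1] + np.arange(1, n_guard + 1) * w,
    ])
    ext_counts = np.concatenate([np.zeros(n_guard), counts, np.zeros(n_guard)])

    def residual(theta):
        mu0, amp, sigmas, weights = _unpack(theta, n_components)
        if shared_sigma:
            sigmas = np.full(n_components, sigmas[0])
        return _model_counts(ext_edges, mu0, amp, sigmas, weights) - ext_counts

    theta0 = _initial_guess(hist, n_components, det_mu0, det_i, shared_width)
    lower = _pack(
        edges[0],
        -2.0 * span,
        np.full(n_components, 0.25 * w),
        np.zeros(n_components),
    )
    upper = _pack(
        edges[-1],
        2.0 * span,
        np.full(n_components, sigma_cap),
        np.full(n_components, 2.0 * total + 1.0),
    )

    rng = np.random.default_rng(0)  # fixed jitter stream for restarts
    best = None
    starts = [theta0]
    for _ in range(_N_MULTISTART - 1):
        jitter = theta0.copy()
        jitter[0] += rng.normal(0.0, max(w, 0.05 * abs(det_i) if det_i else w))
        jitter[1] *= rng.uniform(0.9, 1.1)
        jitter[2 : 2 + n_components] *= rng.uniform(0.5, 2.0)
        starts.append(np.clip(jitter, lower + 1e-12, upper - 1e-12))
    for theta_start in starts:
        sol = optimize.least_squares(
            residual,
            np.clip(theta_start, lower + 1e-12, upper - 1e-12),
            bounds=(lower, upper),
            method="trf",
            x_scale="jac",
            max_nfev=400 * (2 + 2 * n_components),
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            break  # restarts are only for failed convergence

    mu0, amp, sigmas, weights = _unpack(best.x, n_components)
    if shared_sigma:
        sigmas = np.full(n_components, sigmas[0])
    if n_components == 1:
        amp = 0.0
    model = _model_counts(edges, mu0, amp, sigmas, weights)
    resid = counts - model
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)

    fit = GmmFit(
        mu0=float(mu0),
        unitary_amplitude=float(amp),
        sigmas=np.asarray(sigmas, float),
        weights=np.asarray(weights, float),
        r_squared=r2,
        residuals=resid,
        converged=bool(best.success),
    )
    if not best.success:
        raise GmmFitError("mixture fit did not converge after restarts", best=fit)
    return fit
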
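"""Open-probability inference from level occupancies.

For N independent, identical channels the probability of seeing exactly k
channels open simultaneously is binomial,

    B(k | P_o, N) = C(N, k) * P_o^k * (1 - P_o)^(N-k),

so the per-channel open probability P_o can be estimated by least-squares
fitting of the observed level occupancies P_k (the normalized Gaussian
component weights of the amplitude-histogram fit) to a binomial profile.

Two anchoring conventions map observed current levels to open-channel
counts.  ``baseline_closed`` assumes all channels are closed at the
least-inward observed level (observed level j = j channels open); this is
the default and, combined with N = number of observed open levels (the
minimum channel count that explains them), tends to *overestimate* P_o if
channels were missed.  ``top_open`` assumes all channels are open at the
most-inward observed level, mapping the observed ladder onto 0..N with
unseen intermediate counts treated as levels of observed probability zero —
the treatment appropriate when macroscopic currents argue that the single
observed open level hides several co-gating channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .amplitude_analysis import (
    DEFAULT_BIN_WIDTH_PA,
    AmplitudeHistogram,
    GmmFit,
    build_amplitude_histogram,
    detect_levels,
    fit_constrained_gmm,
)
from .trace_io import Trace

__all__ = [
    "OccupancyProfile",
    "BinomialFit",
    "PatchAnalysis",
    "occupation_probabilities",
    "fit_binomial_po",
    "scan_channel_count",
    "estimate_po_from_trace",
]

Anchoring = Literal["baseline_closed", "top_open"]
Objective = Literal["penalize_unobserved", "observed_only"]

_GRID_STEP = 1e-4


@dataclass(frozen=True)
class OccupancyProfile:
    """Occupation probabilities of the observed current levels.

    ``probs[j]`` is the fraction of time spent at observed level j, ordered
    from the baseline level outward (j = 0 is the least-inward level).
    """

    probs: np.ndarray
    anchoring: Anchoring = "baseline_closed"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.size < 1:
            raise ValueError("need at least one level")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1 (within 1e-9)")
        if self.anchoring not in ("baseline_closed", "top_open"):
            raise ValueError(f"unknown anchoring {self.anchoring!r}")

    @property
    def n_observed(self) -> int:
        return int(self.probs.size)

    @property
    def n_open_levels(self) -> int:
        """Observed levels above baseline — the minimum admissible N."""
        return self.n_observed - 1

    def level_map(self, n_channels: int) -> dict[int, int]:
        """Observed index -> open-channel count k, given the anchoring and N."""
        K = self.n_observed
        if n_channels < max(1, K - 1):
            raise ValueError(
                f"N = {n_channels} cannot account for {K - 1} observed open levels"
            )
        if self.anchoring == "baseline_closed" or K == 1:
            return {j: j for j in range(K)}
        # top_open: baseline -> 0 open, most-inward observed -> all N open;
        # interior observed levels spread proportionally over 0..N
        return {j: round(j * n_channels / (K - 1)) for j in range(K)}


@dataclass(frozen=True)
class BinomialFit:
    """Binomial occupancy fit for an assumed channel count N."""

    n_channels: int
    p_open: float
    r_squared: float
    predicted: np.ndarray  # B(k | P_o, N) for k = 0..N
    objective: Objective = "penalize_unobserved"

    def __post_init__(self) -> None:
        predicted = np.asarray(self.predicted, dtype=float)
        object.__setattr__(self, "predicted", predicted)


def occupation_probabilities(
    fit: GmmFit | np.ndarray, anchoring: Anchoring = "baseline_closed"
) -> OccupancyProfile:
    """Normalize mixture component weights into level occupancies.

    ``P_k = A_k / sum_j A_j`` where ``A_k`` is the fitted number of samples
    in the k-th Gaussian component, ordered from the baseline outward.
    """
    weights = fit.weights if isinstance(fit, GmmFit) else np.asarray(fit, float)
    total = float(np.sum(weights))
    if total <= 0:
        raise ValueError("all component weights are zero")
    return OccupancyProfile(probs=weights / total, anchoring=anchoring)


# ---------------------------------------------------------------------------
# binomial fitting


def _mapped_observations(
    occ: OccupancyProfile, n_channels: int
) -> tuple[np.ndarray, np.ndarray]:
    """(y, observed_mask) over k = 0..N under the profile's anchoring.

    Unobserved intermediate counts carry observed probability 0; the mask
    marks levels that were actually seen.
    """
    y = np.zeros(n_channels + 1)
    mask = np.zeros(n_channels + 1, dtype=bool)
    for j, k in occ.level_map(n_channels).items():
        y[k] = occ.probs[j]
        mask[k] = True
    return y, mask


def _binomial_pmf(p: float, n: int) -> np.ndarray:
    return stats.binom.pmf(np.arange(n + 1), n, p)


def fit_binomial_po(
    occ: OccupancyProfile,
    n_channels: int,
    objective: Objective = "penalize_unobserved",
) -> BinomialFit:
    """Least-squares estimate of P_o for an assumed channel count N.

    Minimizes ``sum_k (P_k_obs - B(k | P_o, N))^2`` over the mapped levels.
    With the default objective every k = 0..N enters the sum (levels never
    observed count as probability 0); ``observed_only`` restricts the sum to
    levels that were actually seen.  The minimizer is located on a P_o grid
    of step 1e-4 and refined by bounded scalar minimization; the N = 1 case
    with both levels observed has the closed form
    ``P_o = (1 - P_0 + P_1) / 2`` and is solved exactly.

    R² is reported as ``1 - SS_res / SS_tot`` with SS_tot taken about the
    mean of the fitted observations.
    """
    y, mask = _mapped_observations(occ, n_channels)
    use = np.ones_like(mask) if objective == "penalize_unobserved" else mask

    if n_channels == 1 and mask.all():
        p_hat = float(np.clip((1.0 - y[0] + y[1]) / 2.0, 0.0, 1.0))
    else:
        grid = np.arange(0.0, 1.0 + _GRID_STEP / 2, _GRID_STEP)
        k = np.arange(n_channels + 1)[use]
        yk = y[use]
        pmf = stats.binom.pmf(k[None, :], n_channels, grid[:, None])
        sse = np.sum((yk[None, :] - pmf) ** 2, axis=1)
        i_best = int(np.argmin(sse))
        lo = grid[max(i_best - 1, 0)]
        hi = grid[min(i_best + 1, grid.size - 1)]

        def loss(p: float) -> float:
            return float(np.sum((yk - stats.binom.pmf(k, n_channels, p)) ** 2))

        res = optimize.minimize_scalar(
            loss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
        )
        p_hat = float(res.x) if res.fun <= sse[i_best] else float(grid[i_best])

    predicted = _binomial_pmf(p_hat, n_channels)
    resid = (y - predicted)[use]
    y_used = y[use]
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y_used - y_used.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return BinomialFit(
        n_channels=n_channels,
        p_open=p_hat,
        r_squared=r2,
        predicted=predicted,
        objective=objective,
    )


def scan_channel_count(
    occ: OccupancyProfile,
    n_min: int | None = None,
    n_max: int | None = None,
    objective: Objective = "penalize_unobserved",
) -> list[BinomialFit]:
    """Binomial fits over a range of assumed channel counts.

    Defaults to scanning from the minimum admissible N (the number of
    observed open levels) to that minimum plus two, the customary check that
    extra hypothetical channels do not improve the fit.
    """
    floor = max(1, occ.n_open_levels)
    n_min = floor if n_min is None else n_min
    n_max = n_min + 2 if n_max is None else n_max
    if n_min < floor:
        raise ValueError(f"n_min = {n_min} below observed open levels {floor}")
    if n_max < n_min:
        raise ValueError("n_max must be >= n_min")
    return [fit_binomial_po(occ, n, objective) for n in range(n_min, n_max + 1)]


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class PatchAnalysis:
    """All intermediates of a patch-trace open-probability estimate."""

    histogram: AmplitudeHistogram = field(repr=False)
    n_levels_detected: int
    gmm: GmmFit
    occupancy: OccupancyProfile
    binomial: BinomialFit
    flags: tuple[str, ...] = ()

    @property
    def p_open(self) -> float:
        return self.binomial.p_open

    @property
    def n_channels(self) -> int:
        return self.binomial.n_channels

    @property
    def unitary_amplitude(self) -> float:
        return self.gmm.unitary_amplitude


def estimate_po_from_trace(
    trace: Trace,
    bin_width: float = DEFAULT_BIN_WIDTH_PA,
    anchoring: Anchoring = "baseline_closed",
    n_channels: int | None = None,
    n_components: int | None = None,
    objective: Objective = "penalize_unobserved",
    shared_sigma: bool = False,
) -> PatchAnalysis:
    """Histogram → constrained mixture → occupancies → binomial P_o.

    ``n_channels`` defaults to the number of observed open levels (the
    minimum N consistent with the record); fixing it larger reproduces a
    channel-count scan point.  Deterministic given the trace and options.
    """
    hist = build_amplitude_histogram(trace, bin_width=bin_width)
    n_levels, _, _ = detect_levels(hist)
    flags: list[str] = []

    if n_levels == 1:
        # degenerate record: no channel openings resolved
        gmm = fit_constrained_gmm(hist, n_components=1)
        occ = OccupancyProfile(probs=np.array([1.0]), anchoring=anchoring)
        fit = BinomialFit(
            n_channels=n_channels or 1,
            p_open=0.0,
            r_squared=float("nan"),
            predicted=_binomial_pmf(0.0, n_channels or 1),
            objective=objective,
        )
        flags.append("no open levels detected")
        return PatchAnalysis(
            histogram=hist,
            n_levels_detected=1,
            gmm=gmm,
            occupancy=occ,
            binomial=fit,
            flags=tuple(flags),
        )

    gmm = fit_constrained_gmm(
        hist, n_components=n_components or n_levels, shared_sigma=shared_sigma
    )
    occ = occupation_probabilities(gmm, anchoring=anchoring)
    n_used = n_channels if n_channels is not None else occ.n_open_levels
    fit = fit_binomial_po(occ, n_used, objective=objective)
    return PatchAnalysis(
        histogram=hist,
        n_levels_detected=n_levels,
        gmm=gmm,
        occupancy=occ,
        binomial=fit,
        flags=tuple(flags),
    )
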
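"""Generative models for patch-clamp and whole-cell (TEVC) current traces.

The patch simulator draws N independent, identical two-state (closed/open)
Markov channels.  Gating is simulated in discrete time at the sampling rate
with per-step transition probability ``1 - exp(-rate * dt)``, which is exact
for the two-state chain observed at sample resolution.  The rates are chosen
so that the stationary open probability of each channel equals ``p_open``:

    closing rate  beta  = 1 / mean_open_dwell
    opening rate  alpha = p_open / ((1 - p_open) * mean_open_dwell)

so alpha / (alpha + beta) = p_open.  The recorded current is
``baseline + k(t) * i + noise`` with ``k(t)`` the number of simultaneously
open channels, optionally passed through a zero-phase Gaussian low-pass
filter (−3 dB at the configured cutoff) emulating digital filtering of the
acquisition chain.

The whole-cell simulator produces a macroscopic current obeying
``I = leak + n * i * P_o * g(t) * rundown(t) + noise`` with an epoch schedule
(amiloride block, protease, MTSET, solution changes) modulating ``P_o`` and
the conductance scale, mirroring a cut-open oocyte TEVC protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .trace_io import Epoch, EpochSet, Trace

__all__ = [
    "PatchSimConfig",
    "TevcSimConfig",
    "ConfigurationError",
    "simulate_patch_trace",
    "simulate_tevc_trace",
    "mtset_protocol",
    "protease_protocol",
]


class ConfigurationError(ValueError):
    """Simulation configuration violates a physical or numeric constraint."""


# ---------------------------------------------------------------------------
# patch-clamp (single-channel) simulation


@dataclass(frozen=True)
class PatchSimConfig:
    """Parameters of an on-cell patch simulation.

    Defaults describe the kind of recording the analysis is designed for:
    a few identical inward channels of ~0.3 pA unitary amplitude sampled at
    10 kHz and digitally filtered at 0.1 kHz.  ``mean_open_dwell`` sets the
    gating time scale only; the stationary occupancies depend on ``p_open``
    alone.
    """

    n_channels: int = 1
    p_open: float = 0.5
    mean_open_dwell: float = 0.250  # seconds; ENaC gating is slow
    unitary_amplitude: float = -0.3  # pA, inward negative
    baseline_current: float = 0.0  # pA
    noise_sd: float = 0.05  # pA, white, applied before filtering
    sampling_rate: float = 10_000.0  # Hz
    filter_cutoff: float | None = 100.0  # Hz; None disables filtering
    duration: float = 60.0  # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if not 0.0 <= self.p_open <= 1.0:
            raise ConfigurationError("p_open must lie in [0, 1]")
        if self.mean_open_dwell <= 0:
            raise ConfigurationError("mean_open_dwell must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ConfigurationError("sampling_rate and duration must be positive")
        if self.duration * self.sampling_rate < 1:
            raise ConfigurationError("duration * sampling_rate must be >= 1")
        if self.filter_cutoff is not None and self.filter_cutoff <= 0:
            raise ConfigurationError("filter_cutoff must be positive or None")

    @property
    def closing_rate(self) -> float:
        return 1.0 / self.mean_open_dwell

    @property
    def opening_rate(self) -> float:
        if self.p_open >= 1.0:
            return math.inf
        return self.p_open / ((1.0 - self.p_open) * self.mean_open_dwell)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def _step_probability(rate: float, dt: float) -> float:
    if math.isinf(rate):
        return 1.0
    return -math.expm1(-rate * dt)


def _sample_channel_states(
    cfg: PatchSimConfig, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """One channel's 0/1 state per sample via geometric sojourn sampling.

    The discrete-time chain spends a Geometric(p_leave) number of samples in
    each state; sampling sojourns directly is equivalent to stepping the
    chain sample by sample and much faster for slow gating.
    """
    p = cfg.p_open
    if p == 0.0:
        return np.zeros(n_samples, dtype=np.int8)
    if p == 1.0:
        return np.ones(n_samples, dtype=np.int8)

    dt = 1.0 / cfg.sampling_rate
    p_open_to_closed = _step_probability(cfg.closing_rate, dt)
    p_closed_to_open = _step_probability(cfg.opening_rate, dt)

    state = int(rng.random() < p)  # stationary start
    out = np.empty(n_samples, dtype=np.int8)
    pos = 0
    # draw sojourns in blocks to amortize RNG calls
    while pos < n_samples:
        leave_p = p_open_to_closed if state else p_closed_to_open
        run = int(rng.geometric(leave_p))
        run = min(run, n_samples - pos)
        out[pos : pos + run] = state
        pos += run
        state ^= 1
    return out


def gaussian_lowpass(
    samples: np.ndarray, sampling_rate: float, cutoff: float
) -> np.ndarray:
    """Zero-phase Gaussian low-pass with −3 dB at ``cutoff`` Hz.

    A Gaussian kernel of temporal SD sigma has |H(f)| = exp(-2 pi^2 sigma^2
    f^2); solving |H(f_c)|^2 = 1/2 gives sigma = sqrt(ln 2) / (2 pi f_c).
    Gaussian smoothing is monotone step response (no ringing), matching
    common practice for display filtering of single-channel records.
    """
    sigma_samples = math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff) * sampling_rate
    return ndimage.gaussian_filter1d(samples, sigma_samples, mode="nearest")


def simulate_patch_trace(cfg: PatchSimConfig) -> tuple[Trace, np.ndarray]:
    """Simulate an on-cell patch recording.

    Returns
    -------
    trace : Trace
        The (optionally filtered) current trace in pA.
    latent_states : ndarray of int
        Number of simultaneously open channels at each sample, before noise
        and filtering.  ``sum(latent > 0) / n`` is the ground-truth fraction
        of time at least one channel conducts.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    open_count = np.zeros(n, dtype=np.int16)
    for _ in range(cfg.n_channels):
        open_count += _sample_channel_states(cfg, n, rng)

    current = cfg.baseline_current + open_count * cfg.unitary_amplitude
    if cfg.noise_sd > 0:
        current = current + rng.normal(0.0, cfg.noise_sd, size=n)
    if cfg.filter_cutoff is not None:
        current = gaussian_lowpass(current, cfg.sampling_rate, cfg.filter_cutoff)

    trace = Trace(
        samples=current,
        sampling_rate=cfg.sampling_rate,
        units="pA",
        channel_label=f"sim_patch_N{cfg.n_channels}",
    )
    return trace, open_count


# ---------------------------------------------------------------------------
# whole-cell (TEVC) simulation


@dataclass(frozen=True)
class TevcSimConfig:
    """Parameters of a whole-cell TEVC simulation at fixed holding potential.

    The epoch schedule is a list of ``(label, start_s, end_s)`` (or
    ``(label, start_s, end_s, scale)`` with a per-epoch conductance scale,
    e.g. reduced driving force in low-Na⁺ solution).  Outside any epoch the
    bath is treated like ``highNa`` with scale 1.  MTSET acts instantly at
    the start of its epoch, setting the per-channel open probability to
    ``p_open_after_mtset`` for the rest of the recording with the unitary
    conductance unchanged unless ``mtset_conductance_factor`` says otherwise.
    A protease epoch multiplies the open probability by
    ``protease_po_multiplier`` from the end of the epoch onward; amiloride is
    co-applied during protease exposure (as in a standard protocol that
    avoids Na⁺ loading), controlled by ``amiloride_during_protease``.
    """

    epochs: tuple = ()
    n_channels_wholecell: float = 2.0e7
    unitary_current: float = -3.0e-7  # µA per open channel (= -0.3 pA)
    p_open_baseline: float = 0.5
    p_open_after_mtset: float | None = None
    protease_po_multiplier: float = 1.0
    rundown_rate: float = 0.0  # fractional loss per minute, >= 0
    residual_block_fraction: float = 0.0  # ENaC current left under amiloride
    mtset_conductance_factor: float = 1.0
    amiloride_during_protease: bool = True
    leak_current: float = -0.2  # µA
    noise_sd: float = 0.0  # µA
    sampling_rate: float = 20.0  # Hz
    duration: float | None = None  # defaults to the end of the last epoch
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_open_baseline <= 1.0:
            raise ConfigurationError("p_open_baseline must lie in [0, 1]")
        if self.p_open_after_mtset is not None and not (
            0.0 <= self.p_open_after_mtset <= 1.0
        ):
            raise ConfigurationError("p_open_after_mtset must lie in [0, 1]")
        if self.protease_po_multiplier < 0:
            raise ConfigurationError("protease_po_multiplier must be >= 0")
        if self.rundown_rate < 0:
            raise ConfigurationError("rundown_rate must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.epochs:
            raise ConfigurationError("an epoch schedule is required")

    def epoch_set(self) -> EpochSet:
        return EpochSet([Epoch(e[0], e[1], e[2]) for e in self.epochs])

    def epoch_scales(self) -> dict[tuple[str, float], float]:
        return {
            (e[0], e[1]): (e[3] if len(e) > 3 else 1.0) for e in self.epochs
        }


def simulate_tevc_trace(cfg: TevcSimConfig) -> tuple[Trace, EpochSet]:
    """Simulate a transmembrane-current recording with an epoch protocol."""
    epoch_set = cfg.epoch_set()  # validates ordering/overlap
    scales = cfg.epoch_scales()
    duration = cfg.duration or max(e.end_s for e in epoch_set)
    n = int(round(duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate

    p_open = np.full(n, cfg.p_open_baseline)
    g_scale = np.ones(n)
    blocked = np.zeros(n, dtype=bool)
    for epoch in epoch_set:
        mask = (t >= epoch.start_s) & (t < epoch.end_s)
        g_scale[mask] = scales[(epoch.label, epoch.start_s)]
        if epoch.label == "amiloride":
            blocked |= mask
        elif epoch.label == "protease":
            if cfg.amiloride_during_protease:
                blocked |= mask
            p_open[t >= epoch.end_s] *= cfg.protease_po_multiplier
        elif epoch.label == "mtset" and cfg.p_open_after_mtset is not None:
            p_open[t >= epoch.start_s] = cfg.p_open_after_mtset

    np.clip(p_open, 0.0, 1.0, out=p_open)
    unitary = np.full(n, cfg.unitary_current)
    if cfg.p_open_after_mtset is not None:
        for epoch in epoch_set.by_label("mtset"):
            unitary[t >= epoch.start_s] = (
                cfg.unitary_current * cfg.mtset_conductance_factor
            )

    rundown = np.exp(-cfg.rundown_rate * t / 60.0)
    block_factor = np.where(blocked, cfg.residual_block_fraction, 1.0)
    enac = cfg.n_channels_wholecell * unitary * p_open * g_scale * rundown
    current = cfg.leak_current + block_factor * enac
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        current = current + rng.normal(0.0, cfg.noise_sd, size=n)

    trace = Trace(
        samples=current,
        sampling_rate=cfg.sampling_rate,
        units="uA",
        channel_label="sim_tevc",
    )
    return trace, epoch_set


# ---------------------------------------------------------------------------
# canned protocols


def mtset_protocol(
    pre_s: float = 30.0,
    ami_s: float = 15.0,
    plateau_s: float = 30.0,
    mtset_s: float = 15.0,
) -> tuple:
    """highNa / amiloride / highNa / MTSET / highNa / amiloride / highNa.

    ΔI_Ami measured around the first amiloride epoch reflects the baseline
    open probability; around the second, the post-MTSET open probability.
    """
    t = 0.0
    sched = []
    for label, dur in [
        ("highNa", pre_s),
        ("amiloride", ami_s),
        ("highNa", plateau_s),
        ("mtset", mtset_s),
        ("highNa", plateau_s),
        ("amiloride", ami_s),
        ("highNa", pre_s),
    ]:
        sched.append((label, t, t + dur))
        t += dur
    return tuple(sched)


def protease_protocol(
    pre_s: float = 30.0,
    ami_s: float = 15.0,
    plateau_s: float = 30.0,
    protease_s: float = 300.0,
) -> tuple:
    """highNa / amiloride / highNa / protease / highNa / amiloride / highNa."""
    t = 0.0
    sched = []
    for label, dur in [
        ("highNa", pre_s),
        ("amiloride", ami_s),
        ("highNa", plateau_s),
        ("protease", protease_s),
        ("highNa", plateau_s),
        ("amiloride", ami_s),
        ("highNa", pre_s),
    ]:
        sched.append((label, t, t + dur))
        t += dur
    return tuple(sched)


def with_seed(cfg, seed: int):
    """Copy of a simulation config with a different RNG seed."""
    return replace(cfg, seed=seed)
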
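"""Whole-cell (TEVC) analysis: amiloride-sensitive currents and ratios.

The amiloride-sensitive current fraction ΔI_Ami — the portion of the
transmembrane current blocked by amiloride — is the whole-cell proxy for
total channel activity N·i·P_o.  Protease effects are quantified as the
fold change in ΔI_Ami across the treatment epoch, and the degenerin-site
estimator reads relative channel activity as
ΔI_Ami(before MTSET) / ΔI_Ami(after MTSET): if MTSET locks the channels
fully open without changing the unitary conductance, that ratio is the
baseline open probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trace_io import Epoch, EpochSet, Trace

__all__ = [
    "DeltaIAmi",
    "TevcResult",
    "GroupSummary",
    "delta_i_ami",
    "fold_change",
    "relative_activity",
    "summarize_group",
    "analyze_tevc",
]

#: trailing plateau window (s) used for epoch means; long enough to average
#: noise at 20 Hz, short enough to dodge solution-exchange transients
DEFAULT_PLATEAU_WINDOW_S = 5.0


@dataclass(frozen=True)
class DeltaIAmi:
    """One amiloride-sensitive current measurement."""

    label: str  # e.g. "highNa/amiloride@30.0"
    value: float  # |reference plateau - amiloride plateau|, trace units
    reference_mean: float
    amiloride_mean: float
    signed: float  # reference - amiloride, before taking the magnitude


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TevcResult:
    """Per-recording summary of a protease or MTSET protocol."""

    delta_i_ami_values: tuple[DeltaIAmi, ...]
    fold_change: float | None = None
    relative_activity: float | None = None
    flags: tuple[str, ...] = ()


def _plateau_mean(trace: Trace, epoch: Epoch, window_s: float) -> float:
    """Mean current over the trailing ``window_s`` of an epoch."""
    start = max(epoch.start_s, epoch.end_s - window_s)
    i0 = int(math.ceil((start - trace.start_time) * trace.sampling_rate))
    i1 = int(math.floor((epoch.end_s - trace.start_time) * trace.sampling_rate))
    i1 = min(i1, trace.n_samples)
    if i1 <= i0:
        raise ValueError(
            f"plateau window [{start}, {epoch.end_s}) holds no samples"
        )
    return float(np.mean(trace.samples[i0:i1]))


def delta_i_ami(
    trace: Trace,
    epochs: EpochSet,
    window_s: float = DEFAULT_PLATEAU_WINDOW_S,
) -> list[DeltaIAmi]:
    """ΔI_Ami for every amiloride epoch with a preceding reference plateau.

    For each amiloride epoch, the plateau mean over the trailing ``window_s``
    of the immediately preceding non-amiloride epoch is compared with the
    plateau mean over the trailing ``window_s`` of the amiloride epoch
    itself; the magnitude of the difference is ΔI_Ami (the signed value is
    kept alongside).  An amiloride epoch at the very start of the recording
    has no reference plateau and is skipped.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    ami_epochs = epochs.by_label("amiloride")
    if not ami_epochs:
        raise ValueError("no amiloride epoch in the schedule")
    out: list[DeltaIAmi] = []
    for ami in ami_epochs:
        ref = epochs.preceding(ami)
        if ref is None or ref.label == "amiloride":
            continue  # no usable reference plateau; skip with no entry
        ref_mean = _plateau_mean(trace, ref, window_s)
        ami_mean = _plateau_mean(trace, ami, window_s)
        signed = ref_mean - ami_mean
        out.append(
            DeltaIAmi(
                label=f"{ref.label}/{ami.label}@{ami.start_s:g}",
                value=abs(signed),
                reference_mean=ref_mean,
                amiloride_mean=ami_mean,
                signed=signed,
            )
        )
    return out


def fold_change(before: float, after: float, noise_floor: float = 0.0) -> float:
    """ΔI_Ami(after treatment) / ΔI_Ami(before); NaN below the noise floor."""
    if before <= noise_floor or before <= 0:
        return float("nan")
    return after / before


def relative_activity(
    dami_before_mtset: float, dami_after_mtset: float
) -> float:
    """ΔI_Ami(before MTSET) / ΔI_Ami(after MTSET).

    Under the assumption that MTSET drives the open probability to 1.0 with
    unchanged unitary conductance this ratio equals the baseline P_o.
    Values above 1 (channel already fully open, or conductance altered) are
    returned as-is; callers may flag them.
    """
    if dami_after_mtset <= 0:
        return float("nan")
    return dami_before_mtset / dami_after_mtset


def summarize_group(values) -> GroupSummary:
    """Mean, sample SD (n−1 denominator) and n of a group of measurements."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(mean=float(np.mean(arr)), sd=sd, n=int(arr.size))


def analyze_tevc(
    trace: Trace,
    epochs: EpochSet,
    window_s: float = DEFAULT_PLATEAU_WINDOW_S,
) -> TevcResult:
    """ΔI_Ami series plus the ratios the epoch schedule supports.

    With a ``protease`` epoch between two amiloride measurements the
    before/after fold change is reported; with an ``mtset`` epoch the
    relative activity (before/after ratio) is reported instead.  Run-down is
    deliberately not corrected — protocols are designed to be compared
    against mock-treated controls whose fold change reflects run-down alone.
    """
    damis = delta_i_ami(trace, epochs, window_s)
    flags: list[str] = []
    fold = None
    rel = None

    def _bracketing_pair(label: str):
        marks = epochs.by_label(label)
        if not marks:
            return None
        mark = marks[0]
        before = [d for d in damis if _ami_start(d) < mark.start_s]
        after = [d for d in damis if _ami_start(d) >= mark.end_s]
        if before and after:
            return before[-1], after[0]
        return None

    pair = _bracketing_pair("protease")
    if pair:
        fold = fold_change(pair[0].value, pair[1].value)
        if math.isnan(fold):
            flags.append("fold change undefined: before-treatment ΔI_Ami ≤ 0")
    pair = _bracketing_pair("mtset")
    if pair:
        rel = relative_activity(pair[0].value, pair[1].value)
        if not math.isnan(rel) and rel > 1.0:
            flags.append("relative activity > 1 (already open, or conductance change)")
    return TevcResult(
        delta_i_ami_values=tuple(damis),
        fold_change=fold,
        relative_activity=rel,
        flags=tuple(flags),
    )


def _ami_start(d: DeltaIAmi) -> float:
    return float(d.label.rsplit("@", 1)[1])
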
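"""Reading and writing time–current traces and epoch annotations.

Traces are uniformly sampled current recordings (patch-clamp in pA,
two-electrode voltage clamp in µA).  The primary on-disk format is open and
diffable: a two-column delimited text file (time in seconds, current) plus a
JSON sidecar ``<file>.json`` carrying units, sampling rate and optional epoch
annotations.  Axon Text File (ATF) input is supported as a convenience
dialect; proprietary binary formats (HEKA .dat, ABF) are deliberately not.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "Epoch",
    "EpochSet",
    "TraceFormatError",
    "TraceMetadataError",
    "EpochScheduleError",
    "read_trace",
    "write_trace",
    "read_epochs",
    "write_epochs",
    "write_report",
    "config_hash",
]

VALID_UNITS = ("pA", "nA", "uA")
#: canonical vocabulary for epoch labels; extensible — unknown labels are kept
KNOWN_EPOCH_LABELS = (
    "baseline",
    "lowNa",
    "highNa",
    "amiloride",
    "protease",
    "mtset",
    "washout",
)

# relative tolerance on time-step uniformity when reading timed columns
_UNIFORMITY_RTOL = 1e-6


class TraceFormatError(ValueError):
    """Malformed trace file (non-uniform timebase, bad ATF header, ...)."""


class TraceMetadataError(ValueError):
    """Required metadata (units, sampling rate) missing or invalid."""


class EpochScheduleError(ValueError):
    """Epoch annotations violate ordering/overlap invariants."""


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled time–current series.

    Parameters
    ----------
    samples : ndarray
        Current values; inward current is negative by convention.
    sampling_rate : float
        Samples per second (Hz).
    units : str
        One of ``pA``, ``nA``, ``uA``.
    channel_label : str
        Free-text label (e.g. electrode or cell identifier).
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    units: str = "pA"
    channel_label: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("trace must hold at least one sample in 1-D")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.units not in VALID_UNITS:
            raise TraceMetadataError(
                f"units must be one of {VALID_UNITS}, got {self.units!r}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds (n samples at 1/rate each)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class Epoch:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise EpochScheduleError(
                f"epoch {self.label!r}: need 0 <= start < end, "
                f"got [{self.start_s}, {self.end_s})"
            )


@dataclass
class EpochSet:
    """Ordered, non-overlapping labeled intervals, half-open [start, end)."""

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = [
            e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs
        ]
        self._validate()

    def _validate(self) -> None:
        ordered = sorted(self.epochs, key=lambda e: e.start_s)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.start_s < prev.end_s:
                raise EpochScheduleError(
                    f"epochs {prev.label!r} and {cur.label!r} overlap"
                )
        self.epochs = ordered

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def by_label(self, label: str) -> list[Epoch]:
        return [e for e in self.epochs if e.label == label]

    def preceding(self, epoch: Epoch) -> Epoch | None:
        """Epoch immediately before ``epoch``, or None at the trace start."""
        before = [e for e in self.epochs if e.end_s <= epoch.start_s]
        return before[-1] if before else None

    def to_list(self) -> list[list]:
        return [[e.label, e.start_s, e.end_s] for e in self.epochs]


# ---------------------------------------------------------------------------
# trace file I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _check_uniform(times: np.ndarray) -> float:
    """Validate a uniform timebase; return the sampling rate."""
    if times.size < 2:
        raise TraceFormatError("need at least two samples to infer timebase")
    deltas = np.diff(times)
    dt = float(np.median(deltas))
    if dt <= 0:
        raise TraceFormatError("time column is not strictly increasing")
    if np.max(np.abs(deltas - dt)) > _UNIFORMITY_RTOL * dt:
        raise TraceFormatError("non-uniform timebase")
    return 1.0 / dt


def read_trace(path: str | Path, dialect: str = "csv2col") -> Trace:
    """Read a trace from disk.

    ``csv2col`` expects two delimited columns (time_s, current) and a JSON
    sidecar ``<file>.json`` with at least ``units``; ``sampling_rate`` is
    taken from the sidecar if present, otherwise from the time column.  The
    ``atf`` dialect parses an Axon Text File, taking units from the current
    column title.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv2col":
        return _read_csv2col(path)
    if dialect == "atf":
        return _read_atf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv2col(path: Path) -> Trace:
    try:
        data = pd.read_csv(
            path, header=None, comment="#", float_precision="round_trip"
        ).to_numpy(float)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise TraceFormatError(f"cannot parse {path}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] < 2 or data.shape[0] < 1:
        raise TraceFormatError(f"{path}: expected two columns (time_s, current)")
    times, samples = data[:, 0], data[:, 1]

    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if "units" not in meta:
        raise TraceMetadataError(f"{path}: units missing (no sidecar {sidecar.name})")
    rate = meta.get("sampling_rate")
    if times.size >= 2:
        inferred = _check_uniform(times)
        rate = float(rate) if rate is not None else inferred
    elif rate is None:
        raise TraceMetadataError(f"{path}: sampling_rate required for 1-sample file")
    return Trace(
        samples=samples,
        sampling_rate=float(rate),
        units=meta["units"],
        channel_label=meta.get("channel_label", ""),
        start_time=float(times[0]),
    )


def _read_atf(path: Path) -> Trace:
    """Minimal ATF (Axon Text File) reader for 2-column time/current files."""
    with open(path) as fh:
        magic = fh.readline().split()
        if not magic or magic[0] != "ATF":
            raise TraceFormatError(f"{path}: missing ATF signature")
        try:
            n_optional, _n_cols = (int(tok) for tok in fh.readline().split()[:2])
        except ValueError as exc:
            raise TraceFormatError(f"{path}: bad ATF header counts") from exc
        for _ in range(n_optional):
            fh.readline()
        titles = [t.strip().strip('"') for t in fh.readline().rstrip("\n").split("\t")]
        data = pd.read_csv(
            fh, sep=r"\s+", header=None, float_precision="round_trip"
        ).to_numpy(float)
    if data.shape[1] < 2:
        raise TraceFormatError(f"{path}: expected >= 2 ATF data columns")
    units = None
    if len(titles) >= 2 and "(" in titles[1]:
        units = titles[1].split("(")[-1].rstrip(")").strip()
        units = {"µA": "uA", "uA": "uA", "nA": "nA", "pA": "pA"}.get(units)
    if units is None:
        raise TraceMetadataError(f"{path}: current units not found in column title")
    times, samples = data[:, 0], data[:, 1]
    rate = _check_uniform(times)
    return Trace(samples=samples, sampling_rate=rate, units=units,
                 start_time=float(times[0]))


def write_trace(
    trace: Trace,
    path: str | Path,
    dialect: str = "csv2col",
    epochs: EpochSet | None = None,
) -> Path:
    """Write a trace (full float precision) plus its JSON sidecar."""
    if dialect != "csv2col":
        raise ValueError("only the csv2col dialect is written")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    times = trace.times
    with open(path, "w") as fh:
        fh.writelines(
            f"{float(t)!r},{float(y)!r}\n" for t, y in zip(times, trace.samples)
        )
    meta = {
        "units": trace.units,
        "sampling_rate": trace.sampling_rate,
        "channel_label": trace.channel_label,
        "start_time": trace.start_time,
    }
    if epochs is not None:
        meta["epochs"] = epochs.to_list()
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


# ---------------------------------------------------------------------------
# epochs and reports


def read_epochs(path: str | Path) -> EpochSet:
    """Read epochs from a JSON file: either ``{"epochs": [...]}`` or a list."""
    payload = json.loads(Path(path).read_text())
    entries = payload.get("epochs", []) if isinstance(payload, dict) else payload
    return EpochSet([Epoch(str(lbl), float(s), float(e)) for lbl, s, e in entries])


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"epochs": epochs.to_list()}, indent=1) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__
        }
    return obj


def config_hash(config) -> str:
    """Stable SHA-256 over a canonical JSON rendering of a configuration."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(results, path: str | Path, tables: dict | None = None) -> Path:
    """Serialize analysis results as JSON; optional TSV side tables.

    ``tables`` maps a suffix (e.g. ``"scan"``) to a DataFrame written next to
    the JSON file as ``<stem>.<suffix>.tsv``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(results), indent=1) + "\n")
    for suffix, frame in (tables or {}).items():
        frame.to_csv(path.with_suffix(f".{suffix}.tsv"), sep="\t", index=False)
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
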
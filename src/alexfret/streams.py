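"""Photon-stream containers and on-disk formats.

A confocal ALEX measurement is a list of photon detection events: an integer
timestamp (in clock ticks) and a detector channel (0 = green/donor channel,
1 = red/acceptor channel).  The excitation laser alternates between donor and
acceptor with a fixed period, so the phase ``timestamp mod period`` decides
which laser was on when the photon arrived.  The canonical regime alternates
every 50 us within a 100 us period at a 1 MHz clock (1 tick = 1 us).

On disk a stream is plain text: ``# key=value`` header lines carrying the
clock and alternation metadata, then two whitespace-separated integer columns
(timestamp_ticks, detector).  An HDF5 container mirroring the same fields is
also supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import FormatError, MalformedStreamError

GREEN = 0
RED = 1

#: header keys required by the text format
_HEADER_KEYS = (
    "clock_rate_hz",
    "alternation_period_ticks",
    "donor_window_start_ticks",
    "donor_window_end_ticks",
)


@dataclass(frozen=True)
class AlternationScheme:
    """Laser alternation timing, in clock ticks.

    The donor laser is on during the half-open phase interval
    ``[donor_start, donor_end)``; the acceptor laser is on for the rest of the
    period.  Defaults encode 50 us donor / 50 us acceptor windows in a 100 us
    period at a 1 MHz clock.
    """

    period: int = 100
    donor_start: int = 0
    donor_end: int = 50
    clock_rate_hz: float = 1_000_000.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        if not (0 <= self.donor_start < self.donor_end <= self.period):
            raise ValueError(
                "donor window must satisfy 0 <= start < end <= period, got "
                f"[{self.donor_start}, {self.donor_end}) in period {self.period}"
            )
        if self.clock_rate_hz <= 0:
            raise ValueError("clock_rate_hz must be positive")

    @property
    def donor_fraction(self) -> float:
        """Fraction of the period with the donor laser on."""
        return (self.donor_end - self.donor_start) / self.period

    def ticks_per_ms(self) -> float:
        return self.clock_rate_hz / 1000.0


@dataclass
class PhotonStream:
    """Timestamped two-detector photon records plus alternation metadata."""

    timestamps: np.ndarray
    detectors: np.ndarray
    alternation: AlternationScheme = field(default_factory=AlternationScheme)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.detectors = np.asarray(self.detectors, dtype=np.int8)
        if self.timestamps.ndim != 1 or self.detectors.ndim != 1:
            raise MalformedStreamError("timestamps and detectors must be 1-D")
        if len(self.timestamps) != len(self.detectors):
            raise MalformedStreamError(
                f"length mismatch: {len(self.timestamps)} timestamps vs "
                f"{len(self.detectors)} detectors"
            )
        if len(self.timestamps) and self.timestamps[0] < 0:
            raise MalformedStreamError("timestamps must be nonnegative")
        if np.any(np.diff(self.timestamps) < 0):
            bad = int(np.argmax(np.diff(self.timestamps) < 0)) + 1
            raise MalformedStreamError(
                f"timestamps must be nondecreasing; record {bad} goes backwards"
            )
        bad_det = ~np.isin(self.detectors, (GREEN, RED))
        if np.any(bad_det):
            idx = int(np.argmax(bad_det))
            raise MalformedStreamError(
                f"unknown detector code {self.detectors[idx]} at record {idx}"
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1]) / self.alternation.clock_rate_hz


def write_photon_stream(stream: PhotonStream, path: str | Path) -> None:
    """Write a stream in the two-column text format with a ``# key=value`` header."""
    alt = stream.alternation
    header = (
        f"# clock_rate_hz={alt.clock_rate_hz:g}\n"
        f"# alternation_period_ticks={alt.period}\n"
        f"# donor_window_start_ticks={alt.donor_start}\n"
        f"# donor_window_end_ticks={alt.donor_end}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.column_stack([stream.timestamps, stream.detectors]), fmt="%d")


def read_photon_stream(path: str | Path) -> PhotonStream:
    """Read a photon stream, validating header completeness and record order.

    Dispatches on extension: ``.h5``/``.hdf5`` use the HDF5 container,
    anything else the plain-text format.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return read_photon_stream_hdf5(path)
    meta: dict[str, float] = {}
    ts: list[int] = []
    det: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = float(val)
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: record at line {lineno} is not two columns")
            try:
                ts.append(int(parts[0]))
                det.append(int(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer record at line {lineno}") from exc
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing header key(s): {', '.join(missing)}")
    alt = AlternationScheme(
        period=int(meta["alternation_period_ticks"]),
        donor_start=int(meta["donor_window_start_ticks"]),
        donor_end=int(meta["donor_window_end_ticks"]),
        clock_rate_hz=meta["clock_rate_hz"],
    )
    t = np.asarray(ts, dtype=np.int64)
    if np.any(np.diff(t) < 0):
        bad = int(np.argmax(np.diff(t) < 0)) + 2  # 1-based record index
        raise FormatError(f"{path}: timestamps not sorted at record {bad}")
    d = np.asarray(det, dtype=np.int64)
    bad_det = ~np.isin(d, (GREEN, RED))
    if np.any(bad_det):
        rec = int(np.argmax(bad_det)) + 1
        raise FormatError(f"{path}: unknown detector code at record {rec}")
    return PhotonStream(t, d, alt)


def write_photon_stream_hdf5(stream: PhotonStream, path: str | Path) -> None:
    import h5py

    alt = stream.alternation
    with h5py.File(path, "w") as fh:
        fh.create_dataset("timestamps", data=stream.timestamps)
        fh.create_dataset("detectors", data=stream.detectors)
        fh.attrs["clock_rate_hz"] = alt.clock_rate_hz
        fh.attrs["alternation_period_ticks"] = alt.period
        fh.attrs["donor_window_start_ticks"] = alt.donor_start
        fh.attrs["donor_window_end_ticks"] = alt.donor_end


def read_photon_stream_hdf5(path: str | Path) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as fh:
        missing = [k for k in _HEADER_KEYS if k not in fh.attrs]
        if missing:
            raise FormatError(f"{path}: missing attribute(s): {', '.join(missing)}")
        alt = AlternationScheme(
            period=int(fh.attrs["alternation_period_ticks"]),
            donor_start=int(fh.attrs["donor_window_start_ticks"]),
            donor_end=int(fh.attrs["donor_window_end_ticks"]),
            clock_rate_hz=float(fh.attrs["clock_rate_hz"]),
        )
        t = np.asarray(fh["timestamps"], dtype=np.int64)
        d = np.asarray(fh["detectors"], dtype=np.int64)
    if np.any(np.diff(t) < 0):
        raise FormatError(f"{path}: timestamps not sorted")
    return PhotonStream(t, d, alt)
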
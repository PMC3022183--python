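"""Core data model and readers/writers for the plain-text formats.

The toolkit exchanges data in simple whitespace/TSV text dialects:

* **EPH** — a matrix file with a one-line header ``N T sampling_rate``
  followed by ``T`` rows of ``N`` potentials (µV). Rows are timeframes,
  columns are channels.
* **CSV** — channels as columns with a header row of channel names.
* **XYZ** — electrode montage: optional count line, then ``x y z name``
  per electrode.
* **Marker TSV** — ``onset_tf<TAB>offset_tf<TAB>label`` per line,
  0-based inclusive timeframe intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeMontage",
    "MarkerList",
    "Recording",
    "FormatError",
    "read_eph",
    "write_eph",
    "read_csv",
    "write_csv",
    "read_xyz",
    "write_xyz",
    "read_markers",
    "write_markers",
]


class FormatError(ValueError):
    """Raised when a text file does not conform to its declared dialect."""


@dataclass(frozen=True)
class ElectrodeMontage:
    """Electrode names with head-centered 3D coordinates.

    Parameters
    ----------
    names
        Unique, non-empty channel labels.
    positions
        Array of shape ``(n, 3)``; no two electrodes may coincide.
    """

    names: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "names", names)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        object.__setattr__(self, "positions", pos)
        if len(names) != pos.shape[0]:
            raise ValueError("positions count must equal names count")
        if any(not n for n in names):
            raise ValueError("channel names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        # identical coordinates indicate a corrupt montage
        uniq = {tuple(np.round(row, 12)) for row in pos}
        if len(uniq) != pos.shape[0]:
            raise ValueError("two electrodes share identical coordinates")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class MarkerList:
    """Sorted list of ``(onset_tf, offset_tf, label)`` triggers.

    Intervals are 0-based and inclusive on both ends, so an
    instantaneous trigger has ``onset_tf == offset_tf``.
    """

    entries: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        cleaned = []
        for onset, offset, label in self.entries:
            onset_i, offset_i = int(onset), int(offset)
            if onset_i != onset or offset_i != offset:
                raise ValueError("marker timeframes must be integers")
            if onset_i > offset_i:
                raise ValueError(
                    f"marker onset {onset_i} exceeds offset {offset_i}"
                )
            cleaned.append((onset_i, offset_i, str(label)))
        cleaned.sort(key=lambda e: (e[0], e[1]))
        object.__setattr__(self, "entries", tuple(cleaned))

    def __len__(self) -> int:
        return len(self.entries)

    def with_label(self, label: str) -> "MarkerList":
        return MarkerList(tuple(e for e in self.entries if e[2] == label))


@dataclass(frozen=True)
class Recording:
    """A multichannel recording: ``channels × timeframes`` potentials in µV.

    Attributes
    ----------
    data
        Array of shape ``(N, T)``; all values finite, ``N >= 2``, ``T >= 1``.
    sampling_rate
        Sampling rate in Hz, strictly positive.
    montage
        Optional :class:`ElectrodeMontage`; channel count must match ``N``.
    markers
        Optional :class:`MarkerList`.
    reference
        ``"average"``, ``"channel:<name>"`` (or a ``+``-joined set), or
        ``"unknown"``.
    """

    data: np.ndarray
    sampling_rate: float
    montage: ElectrodeMontage | None = None
    markers: MarkerList | None = None
    reference: str = "unknown"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a channels × timeframes matrix")
        n, t = data.shape
        if n < 2:
            raise ValueError(f"need at least 2 channels, got {n}")
        if t < 1:
            raise ValueError("need at least 1 timeframe")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.montage is not None and len(self.montage) != n:
            raise ValueError(
                f"montage has {len(self.montage)} channels, data has {n}"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timeframes(self) -> int:
        return self.data.shape[1]

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.montage is not None:
            return self.montage.names
        return tuple(f"E{i + 1}" for i in range(self.n_channels))

    def with_data(self, data: np.ndarray, **changes) -> "Recording":
        """Return a copy with new data (and optional field overrides)."""
        return replace(self, data=data, **changes)


# ---------------------------------------------------------------------------
# EPH matrix files
# ---------------------------------------------------------------------------

def read_eph(path: str | Path) -> Recording:
    """Read an EPH-like text matrix into a :class:`Recording`.

    The header line holds ``N T sampling_rate``; each of the following
    ``T`` lines holds ``N`` whitespace-separated potentials (one row per
    timeframe). The returned data is transposed to channels × timeframes
    and the reference is tagged ``"unknown"``.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise FormatError(
                f"{path}: header must be 'N T sampling_rate', got "
                f"{' '.join(header)!r}"
            )
        try:
            n, t = int(header[0]), int(header[1])
            rate = float(header[2])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric header field") from exc
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            vals = line.split()
            if len(vals) != n:
                raise FormatError(
                    f"{path}, line {lineno}: expected {n} values, "
                    f"got {len(vals)}"
                )
            rows.append([float(v) for v in vals])
    if len(rows) != t:
        raise FormatError(
            f"{path}: header declares {t} timeframes but {len(rows)} rows found"
        )
    data = np.asarray(rows, dtype=float).T
    return Recording(data=data, sampling_rate=rate, reference="unknown")


def write_eph(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` to an EPH-like text matrix."""
    path = Path(path)
    n, t = rec.data.shape
    rate = rec.sampling_rate
    rate_str = f"{int(rate)}" if float(rate).is_integer() else f"{rate:g}"
    with path.open("w") as fh:
        fh.write(f"{n} {t} {rate_str}\n")
        for col in rec.data.T:
            fh.write(" ".join(f"{v:.10g}" for v in col) + "\n")


# ---------------------------------------------------------------------------
# CSV (channels as columns)
# ---------------------------------------------------------------------------

def read_csv(
    path: str | Path, sampling_rate: float
) -> tuple[Recording, tuple[str, ...]]:
    """Read a CSV with one column per channel (header row = names).

    Returns the recording and the header channel names (the
    :class:`Recording` itself carries names only through a montage).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 channel columns")
    names = tuple(str(c) for c in df.columns)
    data = df.to_numpy(dtype=float).T
    return Recording(data=data, sampling_rate=sampling_rate), names


def write_csv(rec: Recording, path: str | Path) -> None:
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_names))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# XYZ montages
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> ElectrodeMontage:
    """Read an electrode montage: optional count line, then ``x y z name``."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty montage file")
    declared: int | None = None
    first = lines[0].split()
    if len(first) == 1:
        try:
            declared = int(first[0])
            lines = lines[1:]
        except ValueError:
            pass
    names: list[str] = []
    positions: list[list[float]] = []
    for lineno, line in enumerate(lines, start=1):
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(
                f"{path}, electrode line {lineno}: expected 'x y z name'"
            )
        try:
            xyz = [float(p) for p in parts[:3]]
        except ValueError as exc:
            raise FormatError(
                f"{path}, electrode line {lineno}: non-numeric coordinate"
            ) from exc
        names.append(" ".join(parts[3:]))
        positions.append(xyz)
    if declared is not None and declared != len(names):
        raise FormatError(
            f"{path}: header declares {declared} electrodes, found {len(names)}"
        )
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate electrode names")
    return ElectrodeMontage(names=tuple(names), positions=np.asarray(positions))


def write_xyz(montage: ElectrodeMontage, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{len(montage)}\n")
        for name, (x, y, z) in zip(montage.names, montage.positions):
            fh.write(f"{x:.10g} {y:.10g} {z:.10g} {name}\n")


# ---------------------------------------------------------------------------
# Marker TSV
# ---------------------------------------------------------------------------

def read_markers(path: str | Path) -> MarkerList:
    """Read a TSV of ``onset_tf<TAB>offset_tf<TAB>label`` lines."""
    path = Path(path)
    entries = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise FormatError(
                f"{path}, line {lineno}: expected 3 tab-separated fields"
            )
        try:
            onset, offset = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FormatError(
                f"{path}, line {lineno}: non-integer timeframe"
            ) from exc
        if onset > offset:
            raise FormatError(
                f"{path}, line {lineno}: onset {onset} > offset {offset}"
            )
        entries.append((onset, offset, parts[2]))
    return MarkerList(tuple(entries))


def write_markers(markers: MarkerList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for onset, offset, label in markers.entries:
            fh.write(f"{onset}\t{offset}\t{label}\n")
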
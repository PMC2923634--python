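"""Reading event matrices, writing labelings.

Two input formats are supported: delimited text (comma- or tab-separated,
one optional header row of channel names) and list-mode FCS 3.0/3.1 files.
FCS values are clustered exactly as stored; no compensation or
fluorescence transform (log/logicle) is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import SamspecError

__all__ = ["EventMatrix", "RunConfig", "read_events", "write_labels", "read_labels"]


@dataclass(frozen=True)
class EventMatrix:
    """An n x d matrix of events (rows) by markers/channels (columns).

    Values are in arbitrary per-channel units; all entries must be finite.
    """

    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("event matrix must have at least one row and column")
        if not np.all(np.isfinite(values)):
            raise ValueError("event matrix contains non-finite entries")
        names = list(self.channel_names)
        if not names:
            names = [f"ch{i + 1}" for i in range(values.shape[1])]
        if len(names) != values.shape[1]:
            raise ValueError(
                f"{len(names)} channel names for {values.shape[1]} columns"
            )
        object.__setattr__(self, "channel_names", names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def select_channels(self, channels: Sequence[str]) -> "EventMatrix":
        """Return a copy restricted to the named channels, in the given order."""
        idx = []
        for name in channels:
            if name not in self.channel_names:
                raise KeyError(f"unknown channel {name!r}; have {self.channel_names}")
            idx.append(self.channel_names.index(name))
        return EventMatrix(self.values[:, idx], [self.channel_names[i] for i in idx])


@dataclass
class RunConfig:
    """Parameters of one clustering run.

    sigma — scale of the heat kernel exp(-D^2 / 2 sigma^2), in the same
        units as the event coordinates.  There is no sensible universal
        default: it must be tuned per dataset (typically once, on one or
        two samples), so it is a required argument.
    m — upper bound on the number of communities; the sampling loop
        targets m/2 <= m' <= m representatives.
    separation_factor — threshold on the between/within similarity ratio
        above which two spectral clusters are merged into one component.
        Smaller values merge more aggressively.
    k_override — if set, skip knee-point estimation and use this many
        spectral clusters.
    seed — single source for all randomness (sampling pick orders and
        k-means initialization).
    """

    sigma: float
    separation_factor: float
    m: int = 3000
    k_override: int | None = None
    seed: int = 0
    max_sampling_iterations: int = 20
    kmeans_restarts: int = 10

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.separation_factor > 0:
            raise ValueError("separation_factor must be positive")
        if self.k_override is not None and self.k_override < 1:
            raise ValueError("k_override must be a positive integer")
        if self.max_sampling_iterations < 1:
            raise ValueError("max_sampling_iterations must be >= 1")


def read_events(
    path: str | Path,
    format: str | None = None,
    channels: Sequence[str] | None = None,
) -> EventMatrix:
    """Read an event matrix from ``path``.

    format is "fcs" or "delimited"; if None it is guessed from the file
    extension (.fcs -> fcs, anything else -> delimited).  ``channels``
    optionally restricts (and reorders) the columns by name.
    """
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "delimited"
    if format == "fcs":
        matrix = _read_fcs(path)
    elif format == "delimited":
        matrix = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'fcs' or 'delimited'")
    if channels is not None:
        matrix = matrix.select_channels(channels)
    return matrix


def write_labels(path: str | Path, labels: Sequence[int]) -> None:
    """Write one integer component id per line, in event order."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if labels.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    with open(path, "w") as fh:
        for lab in labels:
            fh.write(f"{int(lab)}\n")


def read_labels(path: str | Path) -> np.ndarray:
    """Read a labels file written by :func:`write_labels`."""
    labels = np.loadtxt(path, dtype=int, ndmin=1)
    if labels.size == 0:
        raise SamspecError(f"no labels in {path}")
    return labels


# -- delimited text ---------------------------------------------------------


def _read_delimited(path: Path) -> EventMatrix:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise SamspecError(f"{path}: empty file")
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    tokens = [t.strip() for t in first.rstrip("\n").split(sep)]
    has_header = not _all_numeric(tokens)
    try:
        values = np.loadtxt(
            path, delimiter=sep, skiprows=1 if has_header else 0, ndmin=2
        )
    except ValueError as exc:
        raise SamspecError(f"{path}: non-numeric value in delimited input: {exc}")
    names = tokens if has_header else []
    return EventMatrix(values, names)


def _all_numeric(tokens: list[str]) -> bool:
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            return False
    return True


# -- FCS 3.0 / 3.1 ----------------------------------------------------------
#
# A deliberately small list-mode reader: HEADER offsets, TEXT keyword
# segment, and uncompressed DATA in float, double or integer type with a
# uniform bit width.  This covers files produced by the common acquisition
# software paths; exotic features (variable $PnB, bit-packed integers,
# analysis segments) are rejected with a clear error.


def _read_fcs(path: Path) -> EventMatrix:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise SamspecError(f"{path}: too short to be an FCS file")
    version = raw[0:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise SamspecError(f"{path}: bad FCS magic {version!r}")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError:
        raise SamspecError(f"{path}: unparseable FCS header offsets")

    text = _parse_text_segment(raw[text_start : text_end + 1], path)
    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise SamspecError(f"{path}: only list mode ($MODE=L) is supported")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    bits = {int(text.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise SamspecError(f"{path}: mixed per-parameter bit widths unsupported")
    nbits = bits.pop()

    if datatype == "F":
        if nbits != 32:
            raise SamspecError(f"{path}: $DATATYPE=F requires 32-bit parameters")
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        if nbits != 64:
            raise SamspecError(f"{path}: $DATATYPE=D requires 64-bit parameters")
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        if nbits not in (8, 16, 32):
            raise SamspecError(f"{path}: integer bit width {nbits} unsupported")
        dtype = np.dtype(f"{endian}u{nbits // 8}")
    else:
        raise SamspecError(f"{path}: $DATATYPE={datatype} unsupported")

    nbytes = n_tot * n_par * dtype.itemsize
    segment = raw[data_start : data_start + nbytes]
    if len(segment) < nbytes:
        raise SamspecError(f"{path}: DATA segment truncated")
    if data_end and data_end - data_start + 1 < nbytes:
        raise SamspecError(f"{path}: DATA segment shorter than $TOT*$PAR events")
    values = np.frombuffer(segment, dtype=dtype).reshape(n_tot, n_par).astype(float)
    names = [
        text.get(f"$P{i}N", text.get(f"$P{i}S", f"P{i}")) for i in range(1, n_par + 1)
    ]
    return EventMatrix(values, names)


def _parse_text_segment(seg: bytes, path: Path) -> dict[str, str]:
    if not seg:
        raise SamspecError(f"{path}: empty TEXT segment")
    delim = seg[0:1]
    body = seg[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Escaped delimiters (doubled) are rare in practice and not supported.
    fields = body.split(delim)
    if len(fields) % 2 != 0:
        fields = fields[:-1]
    keys = [f.decode("ascii", "replace").strip().upper() for f in fields[0::2]]
    vals = [f.decode("ascii", "replace").strip() for f in fields[1::2]]
    text = dict(zip(keys, vals))
    for required in ("$PAR", "$TOT"):
        if required not in text:
            raise SamspecError(f"{path}: TEXT segment missing {required}")
    return text
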
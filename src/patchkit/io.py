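"""Reading and writing recordings.

Three on-disk forms are supported:

* **ATF-style text** — tab-separated columns, column 0 = time in ms, with
  the two-line "ATF 1.0" header convention plus a column-title line; files
  without the header are accepted (the sniffing decision is logged).
* **CSV/TSV** — the same tabular layout with a configurable separator.
* **HDF5** — lossless container with the layout
  ``/channels/<index>`` (attributes ``name``, ``y_unit``, ``dt_ms``) holding
  1-D float64 datasets ``sweep_<index>`` (attribute ``t0_ms``); root
  attributes ``format_version`` plus free-form metadata.

Text files written by this module encode each sweep as one column titled
``<channel>.<sweep-index>`` so that multi-sweep recordings round-trip;
foreign text files map columns to channels, one sweep per file.  Binary
vendor formats are out of scope: externally parsed structures can be
converted through :func:`recording_from_arrays`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .core import Channel, Recording, Trace
from .errors import FormatError

__all__ = [
    "FileDialect",
    "ATF",
    "CSV",
    "read_text",
    "write_text",
    "read_hdf5",
    "write_hdf5",
    "read_recording",
    "write_recording",
    "recording_from_arrays",
]

log = logging.getLogger(__name__)

FORMAT_VERSION = "1"
_DT_UNIFORMITY = 1e-4  # relative tolerance on time-step uniformity


@dataclass
class FileDialect:
    kind: str = "atf"            # atf | csv | hdf5
    column_separator: str = "\t"
    decimal_digits: int = 9

    def __post_init__(self) -> None:
        if self.kind not in ("atf", "csv", "hdf5"):
            raise ValueError(f"unknown dialect kind {self.kind!r}")
        if self.decimal_digits < 1:
            raise ValueError("decimal_digits must be >= 1")


ATF = FileDialect("atf", "\t")
CSV = FileDialect("csv", ",")

_TITLE_RE = re.compile(r"^(?P<chan>.+)\.(?P<sweep>\d+)$")


def _parse_titles(fields: list[str]) -> list[tuple[str, int]] | None:
    """Map column titles back to (channel, sweep) if they use our naming."""
    out = []
    for f in fields:
        m = _TITLE_RE.match(f.strip().strip('"'))
        if not m:
            return None
        out.append((m.group("chan"), int(m.group("sweep"))))
    return out


def _is_numeric_row(fields: list[str]) -> bool:
    try:
        [float(f) for f in fields]
        return True
    except ValueError:
        return False


def read_text(path, dialect: FileDialect = ATF) -> Recording:
    """Read a tabular text file: column 0 = time (ms), remaining columns data.

    dt is inferred from the first two time values and the whole time column
    is verified uniform to 1 part in 1e4.
    """
    sep = dialect.column_separator
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header_meta: dict[str, str] = {}
    i = 0
    if lines and lines[0].split(sep)[0].strip().upper().startswith("ATF"):
        log.info("%s: ATF header detected", path)
        header_meta["atf_version"] = lines[0].split(sep)[-1].strip()
        if len(lines) < 2:
            raise FormatError("truncated ATF header")
        i = 2  # version line + dimensions line
    else:
        log.info("%s: no ATF header, assuming bare columns", path)
    titles = None
    if i < len(lines) and not _is_numeric_row(lines[i].split(sep)):
        raw = lines[i].split(sep)
        titles = _parse_titles(raw[1:])
        i += 1
    rows = []
    for ln in lines[i:]:
        fields = ln.split(sep)
        if not _is_numeric_row(fields):
            raise FormatError(f"non-numeric data row: {ln[:60]!r}")
        rows.append([float(f) for f in fields])
    if len(rows) < 2:
        raise FormatError("need at least two data rows to infer dt")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] < 2:
        raise FormatError("need a time column plus at least one data column")
    tcol = data[:, 0]
    dt = tcol[1] - tcol[0]
    if dt <= 0:
        raise FormatError("time column must be strictly increasing")
    steps = np.diff(tcol)
    if np.any(np.abs(steps - dt) > _DT_UNIFORMITY * abs(dt)):
        raise FormatError("time column is not uniformly sampled (1e-4 tolerance)")
    t0 = float(tcol[0])
    ncols = data.shape[1] - 1
    if titles is not None and len(titles) == ncols:
        chans: dict[str, list[tuple[int, Trace]]] = {}
        for c in range(ncols):
            name, sw = titles[c]
            chans.setdefault(name, []).append(
                (sw, Trace(data[:, c + 1], dt, "mV", t0)))
        channels = [Channel(name, [tr for _, tr in sorted(sweeps)])
                    for name, sweeps in chans.items()]
    else:
        channels = [Channel(f"ch{c}", [Trace(data[:, c + 1], dt, "mV", t0)])
                    for c in range(ncols)]
    return Recording(channels, header_meta)


def write_text(recording: Recording, path, dialect: FileDialect = ATF) -> None:
    """Write a recording as a tabular text file (see module docstring).

    All sweeps must share dt, t0 and length (one shared time column).
    """
    sep = dialect.column_separator
    cols: list[np.ndarray] = []
    titles: list[str] = []
    ref = recording.channels[0].sweeps[0]
    for ch in recording.channels:
        for s, tr in enumerate(ch.sweeps):
            if len(tr) != len(ref) or abs(tr.dt - ref.dt) > 1e-12 * ref.dt:
                raise ValueError("text output requires equal-length sweeps sharing dt")
            cols.append(tr.samples)
            titles.append(f"{ch.name}.{s}")
    fmt = f"%.{dialect.decimal_digits}g"
    lines = []
    if dialect.kind == "atf":
        lines.append(f"ATF{sep}1.0")
        lines.append(f"0{sep}{len(cols) + 1}")
    lines.append(sep.join(['"Time (ms)"'] + [f'"{t}"' for t in titles]))
    times = ref.times
    for i in range(len(ref)):
        # times at full precision so dt round-trips exactly
        lines.append(sep.join(["%.17g" % times[i]] + [fmt % c[i] for c in cols]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_hdf5(recording: Recording, path) -> None:
    """Write the documented HDF5 layout (bit-exact float64 round-trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        for k, v in recording.metadata.items():
            f.attrs[f"meta_{k}"] = str(v)
        grp = f.create_group("channels")
        for ci, ch in enumerate(recording.channels):
            g = grp.create_group(str(ci))
            g.attrs["name"] = ch.name
            g.attrs["y_unit"] = ch.y_unit
            g.attrs["dt_ms"] = float(ch.dt)
            for si, tr in enumerate(ch.sweeps):
                ds = g.create_dataset(f"sweep_{si}", data=tr.samples.astype(np.float64))
                ds.attrs["t0_ms"] = float(tr.t0)


def read_hdf5(path) -> Recording:
    """Read the documented HDF5 layout back into a Recording."""
    with h5py.File(path, "r") as f:
        if "format_version" not in f.attrs:
            raise FormatError("missing required attribute 'format_version'")
        if "channels" not in f:
            raise FormatError("missing /channels group")
        metadata = {k[5:]: str(f.attrs[k]) for k in f.attrs if k.startswith("meta_")}
        channels = []
        for ci in sorted(f["channels"], key=int):
            g = f["channels"][ci]
            for attr in ("name", "y_unit", "dt_ms"):
                if attr not in g.attrs:
                    raise FormatError(f"channel {ci}: missing required attribute {attr!r}")
            dt = float(g.attrs["dt_ms"])
            unit = str(g.attrs["y_unit"])
            sweeps = []
            names = sorted((k for k in g if k.startswith("sweep_")),
                           key=lambda s: int(s.split("_")[1]))
            for k in names:
                ds = g[k]
                sweeps.append(Trace(ds[...], dt, unit, float(ds.attrs.get("t0_ms", 0.0))))
            channels.append(Channel(str(g.attrs["name"]), sweeps))
    return Recording(channels, metadata)


def recording_from_arrays(arrays, dt: float, y_unit: str = "mV",
                          name: str = "ch0", metadata=None) -> Recording:
    """Adapter for externally parsed data: list of 1-D arrays -> Recording."""
    sweeps = [Trace(a, dt, y_unit) for a in arrays]
    return Recording([Channel(name, sweeps)], dict(metadata or {}))


def _dialect_for(path) -> FileDialect:
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return FileDialect("hdf5")
    if suffix == ".csv":
        return CSV
    return ATF


def read_recording(path, dialect: FileDialect | None = None) -> Recording:
    """Read any supported format, inferring the dialect from the suffix."""
    d = dialect or _dialect_for(path)
    return read_hdf5(path) if d.kind == "hdf5" else read_text(path, d)


def write_recording(recording: Recording, path,
                    dialect: FileDialect | None = None) -> None:
    """Write any supported format, inferring the dialect from the suffix."""
    d = dialect or _dialect_for(path)
    if d.kind == "hdf5":
        write_hdf5(recording, path)
    else:
        write_text(recording, path, d)
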
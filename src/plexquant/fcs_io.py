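"""Reading Flow Cytometry Standard (FCS) files into tabular event data.

The ingestion convention used throughout the package is

1. remove boundary events on the forward/side-scatter channels --
   saturated events are recorded at the detector limit and smear the
   scatter clusters;
2. arcsinh-transform the bead (fluorescence) channels -- unlike a plain
   ``log10``, ``asinh`` is defined for the negative values that digital
   cytometers can produce;
3. apply optional closed-interval range filters per channel;
4. return the events as a :class:`pandas.DataFrame` (one row per event,
   one column per channel, plus a ``sample_id`` column).

Scatter channels stay on their native linear scale by default, so range
filters for them are expressed in detector units while filters on bead
channels are expressed on the arcsinh scale.

The low-level reader supports FCS 3.0/3.1 and tolerates 2.0, list-mode
only, with float (``$DATATYPE F``/``D``) and unsigned-integer
(``$DATATYPE I``) storage. Channel names are taken from ``$PnN`` with a
``$PnS`` fallback.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

#: default file-name patterns: 'C' + integer marks a standard (control)
#: sample, 'S' + integer an experimental sample.
STANDARD_PATTERN = r"C(\d+)"
EXPERIMENTAL_PATTERN = r"S(\d+)"


@dataclass(frozen=True)
class SampleName:
    """Role and running number parsed from a sample/file name."""

    raw: str
    role: str  # "standard" | "experimental" | "unknown"
    number: int | None


def parse_sample_name(
    name: str,
    standard_pattern: str = STANDARD_PATTERN,
    experimental_pattern: str = EXPERIMENTAL_PATTERN,
) -> SampleName:
    """Classify a sample name as standard/experimental and extract its number.

    Patterns must contain exactly one integer-capturing group; the full
    multi-digit number is parsed (so ``C12`` yields 12, not 2). A name
    matching neither pattern gets role ``"unknown"`` and no number.
    """
    m = re.search(standard_pattern, name)
    if m is not None:
        return SampleName(raw=name, role="standard", number=int(m.group(1)))
    m = re.search(experimental_pattern, name)
    if m is not None:
        return SampleName(raw=name, role="experimental", number=int(m.group(1)))
    return SampleName(raw=name, role="unknown", number=None)


def transform_arcsinh(x, cofactor: float = 1.0) -> np.ndarray:
    """Elementwise ``asinh(x / cofactor)``.

    Strictly increasing, odd, and defined for negative intensities. The
    cofactor controls how quickly the transform becomes logarithmic;
    ``cofactor=1`` applies a plain ``asinh``.
    """
    if not np.isscalar(cofactor) or not cofactor > 0:
        raise DataError(f"arcsinh cofactor must be > 0, got {cofactor!r}")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def _require_channels(events: pd.DataFrame, channels: Iterable[str]) -> None:
    missing = [c for c in channels if c not in events.columns]
    if missing:
        available = [c for c in events.columns]
        raise DataError(
            f"channel(s) {missing} not present; available columns: {available}"
        )


def remove_boundary_events(
    events: pd.DataFrame,
    channels: Sequence[str],
    bounds: Mapping[str, tuple[float | None, float | None]] | None = None,
) -> pd.DataFrame:
    """Drop events sitting on a channel's boundary values.

    Events outside the detector range are registered at the extreme
    value, so any event *equal* to a channel's lower or upper boundary is
    removed (all ties drop together). Boundaries default to the observed
    per-channel min/max; pass ``bounds`` (e.g. from the FCS ``$PnR``
    keyword) to use the detector range instead -- ``None`` within a bound
    falls back to the observed extreme.
    """
    _require_channels(events, channels)
    keep = np.ones(len(events), dtype=bool)
    for ch in channels:
        col = events[ch].to_numpy(dtype=float)
        lo = hi = None
        if bounds is not None and ch in bounds:
            lo, hi = bounds[ch]
        if lo is None:
            lo = col.min() if len(col) else np.nan
        if hi is None:
            hi = col.max() if len(col) else np.nan
        at_edge = (col == lo) | (col >= hi)
        if len(col) and at_edge.all():
            warnings.warn(
                f"all events sit on the boundary of channel {ch!r}; "
                "removing every event",
                stacklevel=2,
            )
        keep &= ~at_edge
    return events.loc[keep]


def apply_range_filter(
    events: pd.DataFrame,
    filters: Mapping[str, tuple[float | None, float | None]] | None,
) -> pd.DataFrame:
    """Keep events inside the closed interval ``[low, high]`` for every
    filtered channel (conjunction). ``None``/``inf`` bounds are open."""
    if not filters:
        return events
    _require_channels(events, filters)
    keep = np.ones(len(events), dtype=bool)
    for ch, (lo, hi) in filters.items():
        lo = -np.inf if lo is None else float(lo)
        hi = np.inf if hi is None else float(hi)
        if lo > hi:
            raise DataError(f"filter for {ch!r} has low > high: ({lo}, {hi})")
        col = events[ch].to_numpy(dtype=float)
        keep &= (col >= lo) & (col <= hi)
    return events.loc[keep]


# ---------------------------------------------------------------------------
# low-level FCS format support
# ---------------------------------------------------------------------------


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise DataError("empty TEXT segment in FCS file")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        # odd split usually means escaped delimiters, which we do not support
        raise DataError(
            "cannot parse FCS TEXT segment (odd key/value count; "
            "escaped delimiters are not supported)"
        )
    out: dict[str, str] = {}
    for i in range(0, len(parts), 2):
        key = parts[i].decode("ascii", "replace").strip()
        val = parts[i + 1].decode("ascii", "replace").strip()
        out[key.upper() if key.startswith("$") else key] = val
    return out


def _header_int(buf: bytes, lo: int, hi: int) -> int:
    s = buf[lo:hi].decode("ascii", "replace").strip()
    return int(s) if s else 0


def read_fcs_file(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Parse an FCS file into (events DataFrame, TEXT keyword dict).

    All channels are returned as float64 columns named by ``$PnN``
    (``$PnS`` fallback). Log-amplified channels (``$PnE`` with a nonzero
    decade count) are decoded to the linear scale.
    """
    buf = Path(path).read_bytes()
    if len(buf) < 58 or not buf[:3] == b"FCS":
        raise DataError(f"{path}: not an FCS file (bad magic {buf[:6]!r})")
    version = buf[:6].decode("ascii", "replace")
    try:
        text_begin = _header_int(buf, 10, 18)
        text_end = _header_int(buf, 18, 26)
        data_begin = _header_int(buf, 26, 34)
        data_end = _header_int(buf, 34, 42)
    except ValueError as exc:
        raise DataError(f"{path}: malformed FCS header offsets ({exc})") from exc
    meta = _parse_text_segment(buf[text_begin : text_end + 1])
    meta["__version__"] = version

    if data_begin == 0:
        data_begin = int(meta.get("$BEGINDATA", 0))
    if data_end == 0:
        data_end = int(meta.get("$ENDDATA", 0))

    mode = meta.get("$MODE", "L")
    if mode != "L":
        raise DataError(f"{path}: unsupported $MODE {mode!r} (list mode only)")
    try:
        n_par = int(meta["$PAR"])
        n_tot = int(meta["$TOT"])
    except KeyError as exc:
        raise DataError(f"{path}: missing required keyword {exc}") from exc

    byteord = meta.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    datatype = meta.get("$DATATYPE", "F")
    bits = [int(meta.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32):
            raise DataError(
                f"{path}: unsupported mixed/odd $PnB widths {sorted(set(bits))} "
                "for $DATATYPE I"
            )
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise DataError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_values = n_par * n_tot
    raw = buf[data_begin : data_begin + n_values * dtype.itemsize]
    if len(raw) < n_values * dtype.itemsize:
        raise DataError(
            f"{path}: DATA segment truncated "
            f"(expected {n_values * dtype.itemsize} bytes from $TOT/$PAR)"
        )
    arr = np.frombuffer(raw, dtype=dtype, count=n_values).reshape(n_tot, n_par)
    arr = arr.astype(np.float64)

    names = []
    for i in range(1, n_par + 1):
        name = meta.get(f"$P{i}N") or meta.get(f"$P{i}S") or f"P{i}"
        names.append(name)
    if len(set(names)) != len(names):
        raise DataError(f"{path}: duplicate channel names in $PnN/$PnS: {names}")

    # decode log amplification: value = 10^(decades * x / range) * f2
    for i in range(1, n_par + 1):
        pne = meta.get(f"$P{i}E", "0,0")
        try:
            decades, f2 = (float(v) for v in pne.split(","))
        except ValueError:
            raise DataError(f"{path}: malformed $P{i}E {pne!r}") from None
        if decades > 0:
            rng = float(meta.get(f"$P{i}R", 1024))
            arr[:, i - 1] = 10 ** (decades * arr[:, i - 1] / rng) * max(f2, 1.0)

    return pd.DataFrame(arr, columns=names), meta


def channel_ranges(meta: Mapping[str, str]) -> dict[str, float]:
    """Extract numeric ``$PnR`` detector ranges keyed by channel name."""
    out: dict[str, float] = {}
    n_par = int(meta.get("$PAR", 0))
    for i in range(1, n_par + 1):
        name = meta.get(f"$P{i}N") or meta.get(f"$P{i}S") or f"P{i}"
        raw = meta.get(f"$P{i}R")
        if raw is None:
            continue
        try:
            out[name] = float(raw)
        except ValueError:
            continue
    return out


def write_fcs_file(
    path,
    events: pd.DataFrame,
    ranges: Mapping[str, float] | None = None,
) -> Path:
    """Write events to a minimal FCS 3.1 file (float32, little-endian).

    Only the columns of ``events`` are written, in order; values round
    trip through :func:`read_fcs_file` to float32 precision.
    """
    path = Path(path)
    chans = list(events.columns)
    data = np.ascontiguousarray(events.to_numpy(dtype=np.float64), dtype="<f4")
    n_bytes = data.nbytes

    def build_text(data_begin: int, data_end: int) -> bytes:
        kv: dict[str, str] = {
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            "$BEGINDATA": str(data_begin),
            "$ENDDATA": str(data_end),
            "$BYTEORD": "1,2,3,4",
            "$DATATYPE": "F",
            "$MODE": "L",
            "$NEXTDATA": "0",
            "$TOT": str(len(events)),
            "$PAR": str(len(chans)),
        }
        for i, ch in enumerate(chans, start=1):
            if "/" in ch:
                raise DataError(f"channel name {ch!r} contains the delimiter '/'")
            kv[f"$P{i}N"] = ch
            kv[f"$P{i}B"] = "32"
            kv[f"$P{i}E"] = "0,0"
            r = None if ranges is None else ranges.get(ch)
            kv[f"$P{i}R"] = str(int(r)) if r is not None else "262144"
        return ("/" + "/".join(f"{k}/{v}" for k, v in kv.items()) + "/").encode(
            "ascii"
        )

    text_begin = 58
    data_begin, data_end = 0, 0
    for _ in range(5):  # offsets change text length; iterate to fixed point
        text = build_text(data_begin, data_end)
        text_end = text_begin + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + max(n_bytes - 1, 0)
        if (new_begin, new_end) == (data_begin, data_end):
            break
        data_begin, data_end = new_begin, new_end
    header = (
        b"FCS3.1    "
        + b"".join(
            str(v).rjust(8).encode("ascii")
            for v in (text_begin, text_end, data_begin, data_end, 0, 0)
        )
    )
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
    return path


# ---------------------------------------------------------------------------
# high-level reader
# ---------------------------------------------------------------------------


def read_fcs(
    path,
    fsc_ssc: Sequence[str] = ("FSC-A", "SSC-A"),
    bead_channels: Sequence[str] = ("FL6-H", "FL2-H"),
    filters: Mapping[str, tuple[float | None, float | None]] | None = None,
    cofactor: float = 1.0,
    transform_scatter: bool = False,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Load one FCS file and apply the standard ingestion steps.

    Returns only the scatter + bead channels, with boundary events on
    the scatter channels removed (using ``$PnR`` as the upper detector
    limit when present), the arcsinh transform applied to the bead
    channels (and to scatter if ``transform_scatter``), and the range
    ``filters`` applied last. Source event order is preserved for
    retained events. ``sample_id`` defaults to the file stem.
    """
    if len(fsc_ssc) != 2:
        raise DataError(f"fsc_ssc must name exactly 2 channels, got {list(fsc_ssc)}")
    if len(bead_channels) < 1:
        raise DataError("at least one bead channel is required")
    events, meta = read_fcs_file(path)
    wanted = list(fsc_ssc) + [c for c in bead_channels if c not in fsc_ssc]
    _require_channels(events, wanted)
    events = events[wanted]

    pnr = channel_ranges(meta)
    bounds = {ch: (None, pnr.get(ch)) for ch in fsc_ssc}
    events = remove_boundary_events(events, list(fsc_ssc), bounds=bounds)

    events = events.copy()
    to_transform = list(bead_channels) + (list(fsc_ssc) if transform_scatter else [])
    for ch in to_transform:
        events[ch] = transform_arcsinh(events[ch].to_numpy(), cofactor)

    events = apply_range_filter(events, filters)
    events.insert(0, "sample_id", sample_id if sample_id is not None else Path(path).stem)
    return events.reset_index(drop=True)
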
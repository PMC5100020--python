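"""Event-table and time-course I/O.

Event data are bivariate cytometry measurements: one row per nucleus with a
linear DNA-stain intensity (``dapi``), a linear label intensity (``label``,
conventionally displayed on a log axis), and an optional side-scatter value
(``ssc``).  Supported on-disk formats are a fixed CSV dialect
(comma-separated, header row, UTF-8, '.' decimal) and minimal list-mode
FCS 3.1 (single dataset, float or unsigned-integer data).  A time course is
described by a YAML or JSON manifest listing ``time_h``, ``replicate`` and
``path`` per sample.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ChannelResolutionError, FormatError, ManifestError

logger = logging.getLogger("sphase")

#: canonical channel names used throughout the pipeline
CHANNELS = ("dapi", "label", "ssc")

# substrings used for channel auto-detection when no explicit map is given
_AUTO_PATTERNS = {
    "dapi": ("dapi", "460", "405", "dna"),
    "label": ("label", "488", "fitc", "530", "alexa", "af", "edu"),
    "ssc": ("ssc", "side"),
}


@dataclass
class EventTable:
    """Per-nucleus fluorescence measurements for one sample.

    ``data`` holds linear-scale values with canonical column names; extra
    ``truth_*`` columns (simulator ground truth) are carried through but
    ignored by the analysis stages.
    """

    data: pd.DataFrame
    sample: str = ""
    time_h: float = 0.0
    replicate: str = "1"

    def __post_init__(self) -> None:
        if "dapi" not in self.data.columns or "label" not in self.data.columns:
            raise FormatError(
                f"event table requires 'dapi' and 'label' columns, got "
                f"{list(self.data.columns)}"
            )
        if self.time_h < 0:
            raise FormatError("chase time must be >= 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dapi(self) -> np.ndarray:
        return self.data["dapi"].to_numpy(float)

    @property
    def label(self) -> np.ndarray:
        return self.data["label"].to_numpy(float)

    def with_meta(self, **kw) -> "EventTable":
        return replace(self, **kw)


@dataclass
class TimeCourse:
    """Ordered collection of event tables keyed by chase time and replicate."""

    entries: list[EventTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries.sort(key=lambda e: (e.time_h, str(e.replicate)))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[EventTable]:
        return iter(self.entries)

    @property
    def times(self) -> list[float]:
        return sorted({e.time_h for e in self.entries})

    @property
    def replicates(self) -> list[str]:
        return sorted({str(e.replicate) for e in self.entries})

    def at(self, time_h: float, replicate) -> EventTable:
        for e in self.entries:
            if e.time_h == time_h and str(e.replicate) == str(replicate):
                return e
        raise KeyError((time_h, replicate))


# ---------------------------------------------------------------------------
# channel resolution
# ---------------------------------------------------------------------------

def _resolve_channels(
    available: Sequence[str], channel_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical channel names to source column/parameter names."""
    resolved: dict[str, str] = {}
    if channel_map:
        for canon, source in channel_map.items():
            if canon not in CHANNELS:
                raise ChannelResolutionError(canon, CHANNELS)
            if source not in available:
                raise ChannelResolutionError(source, available)
            resolved[canon] = source
    else:
        # auto-detection: exact canonical names first, then substring heuristics
        lower = {name.lower(): name for name in available}
        for canon in CHANNELS:
            if canon in lower:
                resolved[canon] = lower[canon]
                continue
            for name in available:
                if any(p in name.lower() for p in _AUTO_PATTERNS[canon]):
                    resolved[canon] = name
                    break
    for required in ("dapi", "label"):
        if required not in resolved:
            raise ChannelResolutionError(required, available)
    return resolved


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_events_csv(
    path, channel_map: Mapping[str, str] | None = None, **meta
) -> EventTable:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"could not parse CSV {path}: {exc}") from exc
    if df.shape[1] == 0 or len(df) == 0:
        raise FormatError(f"no events in {path}")
    resolved = _resolve_channels(list(df.columns), channel_map)
    out = pd.DataFrame({c: df[src].to_numpy(float) for c, src in resolved.items()})
    for col in df.columns:  # carry simulator ground truth through round trips
        if col.startswith("truth_"):
            out[col] = df[col].to_numpy()
    if not np.isfinite(out[["dapi", "label"]].to_numpy()).all():
        raise FormatError(f"non-finite fluorescence values in {path}")
    return EventTable(out, sample=meta.get("sample", path.stem),
                      time_h=meta.get("time_h", 0.0),
                      replicate=str(meta.get("replicate", "1")))


def write_events_csv(table: EventTable, path, include_truth: bool = False) -> None:
    cols = [c for c in CHANNELS if c in table.data.columns]
    if include_truth:
        cols += [c for c in table.data.columns if c.startswith("truth_")]
    table.data[cols].to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# minimal FCS 3.1 (list mode, one dataset per file)
# ---------------------------------------------------------------------------

_FCS_DELIM = b"/"


def write_events_fcs(table: EventTable, path) -> None:
    """Write a minimal FCS 3.1 file: float32 list-mode data, linear channels."""
    cols = [c for c in CHANNELS if c in table.data.columns]
    arr = np.ascontiguousarray(table.data[cols].to_numpy(np.float32))
    n_events, n_par = arr.shape

    kw = {
        "$FCSversion": "3.1", "$MODE": "L", "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4", "$NEXTDATA": "0",
        "$PAR": str(n_par), "$TOT": str(n_events),
    }
    for i, name in enumerate(cols, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        rng = float(np.max(arr[:, i - 1], initial=1.0))
        kw[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)

    # two-pass: reserve fixed-width fields for the data offsets
    def text_bytes(begin_data: int, end_data: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = f"{begin_data:010d}"
        items["$ENDDATA"] = f"{end_data:010d}"
        parts = [_FCS_DELIM]
        for k, v in items.items():
            parts += [k.encode(), _FCS_DELIM, str(v).encode(), _FCS_DELIM]
        return b"".join(parts)

    header_len = 58
    t = text_bytes(0, 0)
    text_begin = header_len
    text_end = text_begin + len(t) - 1
    data_begin = text_end + 1
    data_end = data_begin + arr.nbytes - 1
    t = text_bytes(data_begin, data_end)
    assert text_end == text_begin + len(t) - 1  # fixed-width offsets

    header = b"FCS3.1    " + b"".join(
        f"{v:>8d}".encode()
        for v in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(t)
        fh.write(arr.tobytes())


def read_events_fcs(
    path, channel_map: Mapping[str, str] | None = None, **meta
) -> EventTable:
    path = Path(path)
    raw = path.read_bytes()
    if not raw.startswith(b"FCS"):
        raise FormatError(f"{path} is not an FCS file")

    def _off(lo: int, hi: int) -> int:
        try:
            return int(raw[lo:hi].decode("ascii").strip() or 0)
        except ValueError as exc:
            raise FormatError(f"bad FCS header offsets in {path}") from exc

    text_begin, text_end = _off(10, 18), _off(18, 26)
    data_begin, data_end = _off(26, 34), _off(34, 42)
    text = raw[text_begin:text_end + 1]
    if not text:
        raise FormatError(f"empty TEXT segment in {path}")
    delim = text[:1]
    fields = text[1:].split(delim)
    if fields and fields[-1] == b"":
        fields = fields[:-1]
    if len(fields) % 2:
        raise FormatError(f"odd keyword count in FCS TEXT segment of {path}")
    kw = {
        fields[i].decode("ascii", "replace").strip().upper():
        fields[i + 1].decode("ascii", "replace").strip()
        for i in range(0, len(fields), 2)
    }
    if not data_begin:
        data_begin = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw.get("$DATATYPE", "F").upper()
    little = kw.get("$BYTEORD", "1,2,3,4").startswith("1")
    order = "<" if little else ">"

    names = [kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}"
             for i in range(1, n_par + 1)]
    bits = [int(kw.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)]
    data = raw[data_begin:data_end + 1]

    if dtype_code == "F":
        arr = np.frombuffer(data, dtype=f"{order}f4", count=n_par * n_tot)
    elif dtype_code == "D":
        arr = np.frombuffer(data, dtype=f"{order}f8", count=n_par * n_tot)
    elif dtype_code == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise FormatError(f"unsupported integer widths {bits} in {path}")
        arr = np.frombuffer(data, dtype=f"{order}u{bits[0] // 8}",
                            count=n_par * n_tot)
    else:
        raise FormatError(f"unsupported $DATATYPE {dtype_code!r} in {path}")
    arr = arr.reshape(n_tot, n_par).astype(float)

    # de-log channels stored with log amplification ($PnE = "decades,f2")
    for i in range(n_par):
        pne = kw.get(f"$P{i + 1}E", "0,0").split(",")
        decades = float(pne[0]) if pne[0] else 0.0
        if decades > 0:
            f2 = float(pne[1]) if len(pne) > 1 and float(pne[1]) else 1.0
            rng = float(kw.get(f"$P{i + 1}R", 1024))
            arr[:, i] = f2 * 10.0 ** (decades * arr[:, i] / rng)

    df = pd.DataFrame(arr, columns=names)
    resolved = _resolve_channels(names, channel_map)
    out = pd.DataFrame({c: df[src].to_numpy(float) for c, src in resolved.items()})
    return EventTable(out, sample=meta.get("sample", path.stem),
                      time_h=meta.get("time_h", 0.0),
                      replicate=str(meta.get("replicate", "1")))


def read_events(path, channel_map: Mapping[str, str] | None = None,
                **meta) -> EventTable:
    """Read one sample (CSV or FCS, by sniffing the leading bytes)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"event file not found: {path}")
    with open(path, "rb") as fh:
        head = fh.read(3)
    if head == b"FCS":
        return read_events_fcs(path, channel_map, **meta)
    return read_events_csv(path, channel_map, **meta)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def load_manifest(path, channel_map: Mapping[str, str] | None = None,
                  allow_missing_t0: bool = False) -> TimeCourse:
    """Load a YAML/JSON manifest and every event file it references.

    The manifest is a list of ``{time_h, replicate, path}`` records (or a
    mapping with a ``samples`` key holding that list).  Paths are resolved
    relative to the manifest's directory.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, Mapping) and "samples" in doc:
        doc = doc["samples"]
    if not isinstance(doc, list) or not doc:
        raise ManifestError(f"manifest {path} must list samples")

    seen: set[tuple[float, str]] = set()
    entries: list[EventTable] = []
    for rec in doc:
        try:
            time_h = float(rec["time_h"])
            replicate = str(rec.get("replicate", "1"))
            sample_path = Path(rec["path"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ManifestError(f"bad manifest record {rec!r}") from exc
        key = (time_h, replicate)
        if key in seen:
            raise ManifestError(
                f"duplicate (time_h={time_h}, replicate={replicate}) in {path}"
            )
        seen.add(key)
        if not sample_path.is_absolute():
            sample_path = path.parent / sample_path
        if not sample_path.exists():
            raise FileNotFoundError(f"event file not found: {sample_path}")
        entries.append(read_events(sample_path, channel_map,
                                   time_h=time_h, replicate=replicate,
                                   sample=rec.get("sample", sample_path.stem)))

    course = TimeCourse(entries)
    missing_t0 = [r for r in course.replicates
                  if (0.0, r) not in {(e.time_h, str(e.replicate))
                                      for e in course}]
    if missing_t0:
        logger.warning("manifest %s lacks a 0 h sample for replicate(s) %s",
                       path, missing_t0)
        if not allow_missing_t0:
            raise ManifestError(
                f"no 0 h sample for replicate(s) {missing_t0}; pass "
                f"allow_missing_t0=True to proceed"
            )
    return course


def write_manifest(records: Sequence[Mapping], path) -> None:
    """Write a manifest (format chosen by extension: .json else YAML)."""
    path = Path(path)
    payload = {"samples": [dict(r) for r in records]}
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix == ".json":
            json.dump(payload, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(payload, fh, sort_keys=True)
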
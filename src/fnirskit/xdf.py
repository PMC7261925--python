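"""Compact reader/writer for the XDF container (lab streaming layer recordings).

XDF is a chunked binary format: a ``XDF:`` magic, then chunks, each prefixed
by a variable-length byte count and a 16-bit tag.  This module implements the
subset of the format the pipeline needs — FileHeader, StreamHeader, Samples,
ClockOffset/Boundary (skipped on read) and StreamFooter chunks, with
``double64``, ``float32``, ``int32``, ``int16`` and ``string`` channel
formats.  Clock-offset correction is not applied; timestamps are taken as
recorded, which is exact for the files this package itself writes.
"""

from __future__ import annotations

import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

MAGIC = b"XDF:"

_TAG_FILE_HEADER = 1
_TAG_STREAM_HEADER = 2
_TAG_SAMPLES = 3
_TAG_CLOCK_OFFSET = 4
_TAG_BOUNDARY = 5
_TAG_STREAM_FOOTER = 6

_FMT_SIZES = {"double64": 8, "float32": 4, "int32": 4, "int16": 2}
_FMT_DTYPES = {
    "double64": "<f8",
    "float32": "<f4",
    "int32": "<i4",
    "int16": "<i2",
}


@dataclass
class XDFStream:
    """One stream of an XDF recording."""

    stream_id: int
    name: str
    type: str
    channel_count: int
    nominal_srate: float
    channel_format: str
    time_series: object = None  # ndarray, or list of tuples for strings
    time_stamps: np.ndarray = field(default_factory=lambda: np.empty(0))


def _read_varlen_uint(buf: memoryview, pos: int) -> tuple[int, int]:
    nbytes = buf[pos]
    if nbytes not in (1, 4, 8):
        raise ValueError(f"bad XDF length field ({nbytes} length bytes)")
    val = int.from_bytes(bytes(buf[pos + 1 : pos + 1 + nbytes]), "little")
    return val, pos + 1 + nbytes


def _write_varlen_uint(out: bytearray, value: int) -> None:
    if value < 256:
        out.append(1)
        out += value.to_bytes(1, "little")
    elif value < 2**32:
        out.append(4)
        out += value.to_bytes(4, "little")
    else:
        out.append(8)
        out += value.to_bytes(8, "little")


def _parse_stream_header(xml_text: str, stream_id: int) -> XDFStream:
    info = ET.fromstring(xml_text)

    def get(tag: str, default: str = "") -> str:
        el = info.find(tag)
        return el.text if el is not None and el.text else default

    return XDFStream(
        stream_id=stream_id,
        name=get("name"),
        type=get("type"),
        channel_count=int(get("channel_count", "1")),
        nominal_srate=float(get("nominal_srate", "0")),
        channel_format=get("channel_format", "double64"),
    )


def read_xdf(path) -> list[XDFStream]:
    """Read an XDF file and return its streams with samples and timestamps."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != MAGIC:
        raise ValueError(f"{path}: not an XDF file (bad magic)")
    buf = memoryview(data)
    pos = 4
    streams: dict[int, XDFStream] = {}
    chunks: dict[int, list] = {}
    stamps: dict[int, list] = {}
    while pos < len(buf):
        length, pos = _read_varlen_uint(buf, pos)
        end = pos + length
        tag = struct.unpack_from("<H", buf, pos)[0]
        body = pos + 2
        if tag == _TAG_STREAM_HEADER:
            (sid,) = struct.unpack_from("<I", buf, body)
            xml_text = bytes(buf[body + 4 : end]).decode("utf-8")
            streams[sid] = _parse_stream_header(xml_text, sid)
            chunks[sid] = []
            stamps[sid] = []
        elif tag == _TAG_SAMPLES:
            (sid,) = struct.unpack_from("<I", buf, body)
            if sid not in streams:
                raise ValueError(f"samples for undeclared stream {sid}")
            st = streams[sid]
            p = body + 4
            n_samples, p = _read_varlen_uint(buf, p)
            dt = 1.0 / st.nominal_srate if st.nominal_srate > 0 else 0.0
            fmt = st.channel_format
            for _ in range(n_samples):
                ts_bytes = buf[p]
                p += 1
                if ts_bytes == 8:
                    (ts,) = struct.unpack_from("<d", buf, p)
                    p += 8
                else:
                    ts = (stamps[sid][-1] + dt) if stamps[sid] else 0.0
                stamps[sid].append(ts)
                if fmt == "string":
                    vals = []
                    for _ in range(st.channel_count):
                        slen, p = _read_varlen_uint(buf, p)
                        vals.append(bytes(buf[p : p + slen]).decode("utf-8"))
                        p += slen
                    chunks[sid].append(vals)
                else:
                    size = _FMT_SIZES[fmt]
                    row = np.frombuffer(
                        buf, dtype=_FMT_DTYPES[fmt], count=st.channel_count, offset=p
                    )
                    chunks[sid].append(row)
                    p += size * st.channel_count
        elif tag in (_TAG_FILE_HEADER, _TAG_CLOCK_OFFSET, _TAG_BOUNDARY, _TAG_STREAM_FOOTER):
            pass
        else:
            raise ValueError(f"unknown XDF chunk tag {tag}")
        pos = end

    out = []
    for sid, st in streams.items():
        st.time_stamps = np.asarray(stamps[sid], dtype=float)
        if st.channel_format == "string":
            st.time_series = chunks[sid]
        elif chunks[sid]:
            st.time_series = np.vstack(chunks[sid]).astype(float)
        else:
            st.time_series = np.empty((0, st.channel_count))
        out.append(st)
    return out


def _chunk(out: bytearray, tag: int, content: bytes) -> None:
    _write_varlen_uint(out, len(content) + 2)
    out += struct.pack("<H", tag)
    out += content


def _header_xml(st: XDFStream) -> bytes:
    info = ET.Element("info")
    for key, val in (
        ("name", st.name),
        ("type", st.type),
        ("channel_count", str(st.channel_count)),
        ("nominal_srate", repr(st.nominal_srate)),
        ("channel_format", st.channel_format),
    ):
        ET.SubElement(info, key).text = val
    return ET.tostring(info, encoding="utf-8")


def write_xdf(path, streams: list[XDFStream]) -> None:
    """Write streams (with explicit per-sample timestamps) to an XDF file."""
    out = bytearray(MAGIC)
    _chunk(out, _TAG_FILE_HEADER, b"<?xml version=\"1.0\"?><info><version>1.0</version></info>")
    for st in streams:
        _chunk(out, _TAG_STREAM_HEADER, struct.pack("<I", st.stream_id) + _header_xml(st))
    for st in streams:
        body = bytearray(struct.pack("<I", st.stream_id))
        n = len(st.time_stamps)
        _write_varlen_uint(body, n)
        is_string = st.channel_format == "string"
        for i in range(n):
            body += struct.pack("<Bd", 8, float(st.time_stamps[i]))
            if is_string:
                for v in st.time_series[i]:
                    raw = str(v).encode("utf-8")
                    _write_varlen_uint(body, len(raw))
                    body += raw
            else:
                row = np.asarray(st.time_series[i], dtype=_FMT_DTYPES[st.channel_format])
                body += row.tobytes()
        _chunk(out, _TAG_SAMPLES, bytes(body))
    for st in streams:
        _chunk(out, _TAG_STREAM_FOOTER, struct.pack("<I", st.stream_id) + b"<info/>")
    with open(path, "wb") as fh:
        fh.write(bytes(out))
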
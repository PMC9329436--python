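"""Compact FCS 3.0/3.1 codec for list-mode floating-point event data.

Covers the subset of the standard that cytometer exports in this pipeline
use: $MODE L, $DATATYPE F or D, a single data segment, and uniform
little- or big-endian byte order.  Integer data types, analysis segments
and multi-dataset files are out of scope.
"""

from __future__ import annotations

import struct

import numpy as np

_DELIM = "/"


def write_fcs(path, channel_names: list[str], values: np.ndarray) -> None:
    """Write events (rows) × channels (columns) as an FCS 3.1 file."""
    values = np.asarray(values, dtype="<f4")
    n_events, n_par = values.shape
    if n_par != len(channel_names):
        raise ValueError("channel name count does not match the value matrix")

    keywords = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_events), "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(values[:, i - 1])) + 1)))

    data = values.tobytes()
    # Data offsets depend on the TEXT length, which itself contains the
    # offsets; iterate until the digits stabilise.
    begin_data, end_data = 0, 0
    for _ in range(8):
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = _DELIM + _DELIM.join(
            f"{k}{_DELIM}{v}" for k, v in kw.items()) + _DELIM
        text_start = 58
        text_end = text_start + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + len(data) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{begin_data:>8d}".encode()
        + f"{end_data:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("ascii"))
        fh.write(data)


def read_fcs(path) -> tuple[list[str], np.ndarray]:
    """Read an FCS 3.0/3.1 file; returns (channel names, events × channels)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise IOError(f"unsupported FCS version marker {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start:text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    tokens = text[1:].rstrip(delim).split(delim)
    kw = {tokens[i].strip().upper(): tokens[i + 1]
          for i in range(0, len(tokens) - 1, 2)}

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").strip().upper()
    if datatype not in ("F", "D"):
        raise IOError(f"unsupported $DATATYPE {datatype!r} (only F/D handled)")
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if datatype == "F" else 8

    begin_data = int(kw.get("$BEGINDATA", "0") or 0)
    end_data = int(kw.get("$ENDDATA", "0") or 0)
    if begin_data == 0:  # FCS3.0 may carry offsets only in the header
        begin_data = int(raw[26:34])
        end_data = int(raw[34:42])
    buf = raw[begin_data:end_data + 1]
    expect = n_par * n_tot * itemsize
    if len(buf) < expect:
        raise IOError("FCS data segment shorter than $PAR × $TOT")
    dtype = np.dtype(f"{endian}f{itemsize}")
    values = np.frombuffer(buf[:expect], dtype=dtype).reshape(n_tot, n_par)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return names, values.astype(np.float64)


def _check_struct():  # pragma: no cover - import-time sanity
    assert struct.calcsize("<f") == 4
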
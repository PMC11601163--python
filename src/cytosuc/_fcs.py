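"""Minimal FCS 3.0/3.1 reader and writer.

Only the primary TEXT and DATA segments are handled: list-mode data
($MODE L) with $DATATYPE F (float32) or D (float64) and a uniform
$BYTEORD. That covers the common CyTOF export dialect. The writer emits
FCS 3.0 with $DATATYPE D so values round-trip exactly; corrected values
may be negative and are stored without clipping.

Per-cell string labels have no native slot in FCS, so the writer encodes
them as an extra integer parameter named by ``label_param`` plus a custom
keyword holding the code -> label mapping.
"""

from __future__ import annotations

import numpy as np

from ._exceptions import ParseError

#: custom keywords (vendor-prefixed, as FCS recommends for extensions)
KW_LABELS = "CYTOSUC_SAMPLE_LABELS"
KW_TRANSFORM = "CYTOSUC_TRANSFORM"
LABEL_PARAM = "sample_code"

_DELIM = "/"

_DTYPES = {"F": "f4", "D": "f8"}


def _pad(n: int, width: int = 8) -> bytes:
    s = str(n)
    if len(s) > width:
        raise ParseError(f"segment offset {n} exceeds header field width")
    return s.rjust(width).encode("ascii")


def write_fcs(
    path,
    data: np.ndarray,
    channel_names: list[str],
    extra_keywords: dict[str, str] | None = None,
) -> None:
    """Write a cells x channels float matrix as an FCS 3.0 file."""
    data = np.ascontiguousarray(data, dtype="<f8")
    n_events, n_par = data.shape
    if n_par != len(channel_names):
        raise ValueError("channel_names length does not match data width")

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "D",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(channel_names, start=1):
        kw[f"$P{i}B"] = "64"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}N"] = name
        kw[f"$P{i}S"] = name
        kw[f"$P{i}R"] = "262144"
    for k, v in (extra_keywords or {}).items():
        kw[k] = v

    # data offsets appear inside TEXT, so reserve fixed-width fields
    kw["$BEGINDATA"] = "0" * 12
    kw["$ENDDATA"] = "0" * 12

    def render(d: dict[str, str]) -> bytes:
        parts = [_DELIM]
        for k, v in d.items():
            if _DELIM in k or any(_DELIM in str(x) for x in (v,)):
                raise ValueError(f"delimiter character in keyword {k!r}")
            parts.append(f"{k}{_DELIM}{v if v != '' else ' '}{_DELIM}")
        return "".join(parts).encode("utf-8")

    header_len = 58  # 10-byte version + 6 ASCII offset fields of width 8
    text = render(kw)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1

    kw["$BEGINDATA"] = str(data_begin).rjust(12, "0")
    kw["$ENDDATA"] = str(data_end).rjust(12, "0")
    text = render(kw)
    assert text_begin + len(text) - 1 == text_end

    with open(path, "wb") as fh:
        fh.write(b"FCS3.0    ")
        fh.write(_pad(text_begin) + _pad(text_end))
        fh.write(_pad(data_begin) + _pad(data_end))
        fh.write(_pad(0) + _pad(0))
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ParseError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("utf-8", errors="replace")
    # strip leading delimiter; trailing delimiter terminates the last value
    fields = body[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2 != 0:
        raise ParseError("TEXT segment has an odd number of fields")
    return {fields[i].strip(): fields[i + 1] for i in range(0, len(fields), 2)}


def read_fcs(path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS 3.0/3.1 file.

    Returns (data, channel_names, keywords). Channel identity is taken
    from $PnS when present and non-blank, else $PnN.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise ParseError("file too short to be FCS")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise ParseError(f"unsupported FCS version {version!r}")

    def offset(lo: int, hi: int) -> int:
        field = raw[lo:hi].decode("ascii", errors="replace").strip()
        try:
            return int(field) if field else 0
        except ValueError as exc:
            raise ParseError(f"bad header offset field {field!r}") from exc

    text_begin, text_end = offset(10, 18), offset(18, 26)
    data_begin, data_end = offset(26, 34), offset(34, 42)
    kw = _parse_text(raw[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
    except KeyError as exc:
        raise ParseError(f"missing required FCS keyword {exc}") from exc
    if kw.get("$MODE", "L").strip().upper() != "L":
        raise ParseError("only list-mode ($MODE L) FCS data are supported")
    if datatype not in _DTYPES:
        raise ParseError(
            f"unsupported $DATATYPE {datatype!r} (only F and D are handled)"
        )
    widths = {kw.get(f"$P{i}B", "").strip() for i in range(1, n_par + 1)}
    expected = "32" if datatype == "F" else "64"
    if widths != {expected}:
        raise ParseError(f"non-uniform or unexpected $PnB widths {widths}")
    endian = "<" if byteord.startswith("1") else ">"
    dtype = np.dtype(endian + _DTYPES[datatype])

    nbytes = n_par * n_tot * dtype.itemsize
    seg = raw[data_begin : data_begin + nbytes]
    if len(seg) < nbytes:
        raise ParseError("DATA segment truncated")
    data = np.frombuffer(seg, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)

    names = []
    for i in range(1, n_par + 1):
        s = kw.get(f"$P{i}S", "").strip()
        names.append(s if s else kw.get(f"$P{i}N", f"P{i}").strip())
    return data, names, kw
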
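"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Supports the common case this tool needs: HEADER + primary TEXT segment,
list-mode DATA in float ($DATATYPE F/D) or unsigned integer ($DATATYPE I)
with a uniform $PnB, little- or big-endian $BYTEORD, and an optional
$SPILLOVER compensation matrix.  ANALYSIS segments, supplemental TEXT and
keyword escaping of delimiters are not handled.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ConfigurationError, InputError
from .model import EventTable
from .transforms import TransformConfig

logger = logging.getLogger(__name__)

__all__ = ["read_fcs", "write_fcs_file", "parse_spillover"]


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    parts = body.split(delim)[1:]  # leading delimiter
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    return {
        parts[i].strip().upper(): parts[i + 1]
        for i in range(0, len(parts), 2)
        if parts[i].strip()
    }


def parse_spillover(text: str) -> tuple[list[str], np.ndarray]:
    """Parse an FCS $SPILLOVER value: "n,name1,...,namen,v11,v12,...,vnn"."""
    fields = [f.strip() for f in text.split(",")]
    n = int(fields[0])
    names = fields[1 : 1 + n]
    vals = np.asarray([float(v) for v in fields[1 + n : 1 + n + n * n]], dtype=float)
    if vals.size != n * n:
        raise InputError("$SPILLOVER matrix is not n x n")
    return names, vals.reshape(n, n)


def _read_segments(path) -> tuple[dict[str, str], bytes]:
    with open(path, "rb") as fh:
        header = fh.read(58)
        version = header[:6].decode("latin-1")
        if version not in ("FCS3.0", "FCS3.1"):
            raise InputError(f"unsupported FCS version {version!r} in {path}")

        def _off(a, b):
            s = header[a:b].decode("latin-1").strip()
            return int(s) if s else 0

        text_start, text_end = _off(10, 18), _off(18, 26)
        data_start, data_end = _off(26, 34), _off(34, 42)
        fh.seek(text_start)
        text = _parse_text_segment(fh.read(text_end - text_start + 1))
        if data_start == 0:
            data_start = int(text["$BEGINDATA"])
            data_end = int(text["$ENDDATA"])
        fh.seek(data_start)
        data = fh.read(data_end - data_start + 1)
    return text, data


def _decode_data(text: dict[str, str], data: bytes) -> tuple[list[str], np.ndarray]:
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"
    bits = {int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise InputError("mixed $PnB widths are not supported")
    nbits = bits.pop()
    if datatype == "F":
        dtype = np.dtype(order + "f4")
    elif datatype == "D":
        dtype = np.dtype(order + "f8")
    elif datatype == "I":
        dtype = np.dtype(order + {8: "u1", 16: "u2", 32: "u4"}[nbits])
    else:
        raise InputError(f"unsupported $DATATYPE {datatype!r}")
    need = n_tot * n_par * dtype.itemsize
    vals = np.frombuffer(data[:need], dtype=dtype).astype(float)
    return names, vals.reshape(n_tot, n_par) if n_tot else vals.reshape(0, n_par)


def read_fcs(
    path,
    transform: TransformConfig,
    spillover: np.ndarray | None = None,
    spillover_params: list[str] | None = None,
    sample_id: str | None = None,
) -> EventTable:
    """Read an FCS file into an EventTable of normalized plot units.

    Compensation is applied before the display transform when a spillover
    matrix is given explicitly or stored in the file's $SPILLOVER keyword:
    with ``S[i][j]`` the fraction of dye ``j``'s signal observed in
    detector ``i``, compensated events solve ``S x = observed`` per event.
    After transforming, values are clipped to [0, 1]; events with a
    non-finite value in any configured parameter are dropped (logged).
    """
    text, data = _read_segments(path)
    names, raw = _decode_data(text, data)

    for p in transform.parameters():
        if p not in names:
            raise ConfigurationError(
                f"parameter {p!r} required by the transform config is not in {path}"
            )

    comp_params = spillover_params
    if spillover is None and "$SPILLOVER" in text:
        comp_params, spillover = parse_spillover(text["$SPILLOVER"])
    if spillover is not None:
        spillover = np.asarray(spillover, dtype=float)
        if comp_params is None:
            if spillover.shape[0] != len(names):
                raise InputError(
                    "spillover matrix size does not match parameter count; "
                    "pass spillover_params"
                )
            comp_params = list(names)
        cols = [names.index(p) for p in comp_params]
        try:
            comp = np.linalg.solve(spillover, raw[:, cols].T).T
        except np.linalg.LinAlgError:
            raise InputError("spillover matrix is singular") from None
        raw[:, cols] = comp

    params = transform.parameters()
    out = np.column_stack([transform.apply(p, raw[:, names.index(p)]) for p in params])
    finite = np.isfinite(out).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("dropped %d events with non-finite values from %s", dropped, path)
    out = np.clip(out[finite], 0.0, 1.0)
    return EventTable(sample_id or str(path), params, out)


def write_fcs_file(
    path,
    parameters: list[str],
    values: np.ndarray,
    extra_keywords: dict[str, str] | None = None,
) -> None:
    """Write a minimal FCS 3.1 list-mode float32 little-endian file."""
    values = np.atleast_2d(np.asarray(values, dtype="<f4"))
    if values.size == 0:
        values = values.reshape(0, len(parameters))
    n_tot, n_par = values.shape
    if n_par != len(parameters):
        raise InputError("values column count does not match parameter names")

    delim = "/"
    kw: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
    }
    for i, name in enumerate(parameters, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"
    if extra_keywords:
        kw.update(extra_keywords)

    data_bytes = values.tobytes()
    header_len = 58
    # iterate because $BEGINDATA/$ENDDATA lengths feed back into the offsets
    begin_data, end_data = 0, 0
    for _ in range(8):
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in sorted(kw.items())) + delim
        text_start = header_len
        text_end = text_start + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + max(len(data_bytes) - 1, 0)
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end

    header = (
        f"FCS3.1    "
        f"{text_start:>8d}{text_end:>8d}"
        f"{begin_data:>8d}{end_data:>8d}"
        f"{0:>8d}{0:>8d}"
    )
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text.encode("latin-1"))
        fh.write(data_bytes)
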
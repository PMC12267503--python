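"""Minimal NRRD reader/writer (raw encoding).

Supports the subset of NRRD needed for volumetric interchange here:
3-D or 4-D arrays, raw encoding, little-endian, ``spacings`` metadata.
Per NRRD convention ``sizes`` lists the fastest-varying axis first, so a
C-ordered numpy array of shape (d0, d1, d2) is stored with
``sizes: d2 d1 d0`` and read back with the same shape.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import FormatError, InputError

_DTYPES = {
    "uint8": np.uint8,
    "uchar": np.uint8,
    "int16": np.int16,
    "short": np.int16,
    "uint16": np.uint16,
    "ushort": np.uint16,
    "int32": np.int32,
    "int": np.int32,
    "uint32": np.uint32,
    "float": np.float32,
    "float32": np.float32,
    "double": np.float64,
    "float64": np.float64,
}

_DTYPE_NAMES = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16",
    np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32",
    np.dtype(np.uint32): "uint32",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}


def read_nrrd(path):
    """Read a raw-encoded NRRD file.

    Returns ``(array, header)`` where the array is C-ordered with the
    slowest axis first and ``header`` maps lower-cased field names to their
    raw string values.
    """
    if not os.path.isfile(path):
        raise InputError(f"no such file: {path}")
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise FormatError(f"{path}: not an NRRD file (bad magic {magic[:8]!r})")
        header: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n"):
                break
            if not line:
                raise FormatError(f"{path}: truncated NRRD header")
            text = line.decode("ascii", errors="replace").strip()
            if text.startswith("#"):
                continue
            if ":" not in text:
                raise FormatError(f"{path}: malformed header line {text!r}")
            key, _, value = text.partition(":")
            header[key.strip().lower()] = value.lstrip("= ").strip()
        blob = fh.read()

    for required in ("type", "dimension", "sizes", "encoding"):
        if required not in header:
            raise FormatError(f"{path}: NRRD header missing '{required}'")
    if header["encoding"] not in ("raw",):
        raise FormatError(f"{path}: unsupported NRRD encoding {header['encoding']!r}")
    type_name = header["type"].replace(" ", "")
    if type_name not in _DTYPES:
        raise FormatError(f"{path}: unsupported NRRD type {header['type']!r}")
    dtype = np.dtype(_DTYPES[type_name])
    if dtype.itemsize > 1 and header.get("endian", "little") != "little":
        dtype = dtype.newbyteorder(">")

    sizes = [int(s) for s in header["sizes"].split()]
    if len(sizes) != int(header["dimension"]):
        raise FormatError(f"{path}: sizes/dimension mismatch")
    count = int(np.prod(sizes))
    data = np.frombuffer(blob, dtype=dtype, count=count)
    if data.size != count:
        raise FormatError(f"{path}: payload shorter than sizes imply")
    # sizes are fastest-first; numpy shape is slowest-first.
    array = data.reshape(tuple(reversed(sizes))).astype(dtype.newbyteorder("="), copy=False)
    return array, header


def parse_spacings(header) -> tuple[float, ...] | None:
    """Extract per-axis spacings (slowest axis first) from a header, if any."""
    if "spacings" not in header:
        return None
    vals = [float(v) for v in header["spacings"].split()]
    return tuple(reversed(vals))


def write_nrrd(path, array: np.ndarray, spacings=None) -> None:
    """Write ``array`` as a raw-encoded little-endian NRRD file.

    ``spacings`` is per-axis, slowest axis first, matching the array shape.
    """
    array = np.ascontiguousarray(array)
    if array.dtype not in _DTYPE_NAMES:
        raise FormatError(f"cannot store dtype {array.dtype} in NRRD")
    lines = [
        "NRRD0004",
        f"type: {_DTYPE_NAMES[array.dtype]}",
        f"dimension: {array.ndim}",
        "sizes: " + " ".join(str(s) for s in reversed(array.shape)),
        "encoding: raw",
        "endian: little",
    ]
    if spacings is not None:
        if len(spacings) != array.ndim:
            raise FormatError("spacings length must match array dimension")
        lines.append("spacings: " + " ".join(repr(float(s)) for s in reversed(spacings)))
    payload = array.astype(array.dtype.newbyteorder("<"), copy=False).tobytes()
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode("ascii"))
        fh.write(payload)
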
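"""Minimal ENVI-format hypercube I/O (BSQ/BIL interleave, text header).

Writes a binary data file plus the classic ASCII ``.hdr`` companion with a
wavelength list; reads the subset of the header grammar needed for cubes
produced by typical line-scan plant-imaging systems.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .calibration import Hypercube

_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
           5: np.float64, 12: np.uint16}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def write_envi(cube: Hypercube, path, interleave: str = "bsq",
               dtype=np.float32) -> Path:
    """Write a cube as ENVI binary + ``.hdr``; returns the data-file path."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    path = Path(path)
    dtype = np.dtype(dtype)
    if dtype not in _CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    rows, cols, bands = cube.shape
    data = cube.data.astype(dtype)
    if interleave == "bsq":  # band-sequential: (bands, rows, cols)
        arr = np.transpose(data, (2, 0, 1))
    else:  # BIL: (rows, bands, cols)
        arr = np.transpose(data, (0, 2, 1))
    arr.tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {{spadspec {cube.kind} cube}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)
    return path


def _parse_header(text: str) -> dict:
    # collapse brace-delimited multi-line values before splitting into fields
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path, kind: str = "reflectance") -> Hypercube:
    """Read an ENVI cube given its data-file path (``.hdr`` beside it)."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    fields = _parse_header(hdr_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))
    if code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    if fields.get("byte order", "0").strip() != "0":
        raise ValueError("only little-endian (byte order = 0) is supported")
    raw = np.fromfile(path, dtype=_DTYPES[code], offset=offset,
                      count=rows * cols * bands)
    if raw.size != rows * cols * bands:
        raise ValueError(f"file {path} smaller than header promises")
    if interleave == "bsq":
        data = np.transpose(raw.reshape(bands, rows, cols), (1, 2, 0))
    elif interleave == "bil":
        data = np.transpose(raw.reshape(rows, bands, cols), (0, 2, 1))
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    m = re.search(r"\{([^}]*)\}", fields.get("wavelength", ""))
    if not m:
        raise ValueError("header has no wavelength list")
    wavelengths = np.array([float(v) for v in m.group(1).split(",") if v.strip()])
    return Hypercube(data.astype(float), wavelengths, kind=kind)
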
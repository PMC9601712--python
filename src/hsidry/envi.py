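"""Minimal ENVI band-sequential (BSQ) cube reader/writer.

Writes an ASCII ``.hdr`` alongside a raw binary image file.  Only the subset
of the ENVI header needed for reflectance cubes is supported: float32 data
(data type 4), BSQ interleave, little-endian byte order, and an optional
wavelength list in nanometres.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

_DTYPE_CODES = {4: np.float32, 5: np.float64, 2: np.int16, 12: np.uint16, 1: np.uint8}
_CODE_FOR = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(path: str | Path, data: np.ndarray, wavelengths=None) -> Path:
    """Write a (rows, cols, bands) array as ENVI BSQ; returns the header path.

    ``path`` may point at either the header or the image file; ``.hdr`` and
    ``.img`` siblings are derived from it.
    """
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("expected a (rows, cols, bands) cube")
    base = Path(path)
    if base.suffix in {".hdr", ".img"}:
        base = base.with_suffix("")
    hdr_path, img_path = base.with_suffix(".hdr"), base.with_suffix(".img")

    out = data.astype(np.float32, copy=False)
    rows, cols, bands = out.shape
    # BSQ: band-major on disk
    np.ascontiguousarray(np.moveaxis(out, 2, 0)).tofile(img_path)

    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        f"data type = {_CODE_FOR[np.dtype(np.float32)]}",
        "interleave = bsq",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.4f}" for w in np.asarray(wavelengths, dtype=float))
        lines.append("wavelength units = nm")
        lines.append("wavelength = { " + wl + " }")
    hdr_path.write_text("\n".join(lines) + "\n")
    return hdr_path


def _parse_header(text: str) -> dict:
    fields: dict = {}
    # brace-delimited values may span lines
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", text, re.MULTILINE):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def read_envi(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI BSQ cube; returns ``(data, wavelengths_or_None)``."""
    base = Path(path)
    if base.suffix in {".hdr", ".img"}:
        base = base.with_suffix("")
    hdr = _parse_header(base.with_suffix(".hdr").read_text())

    if hdr.get("interleave", "bsq").lower() != "bsq":
        raise ValueError(f"unsupported interleave {hdr.get('interleave')!r}")
    rows = int(hdr["lines"])
    cols = int(hdr["samples"])
    bands = int(hdr["bands"])
    dtype = _DTYPE_CODES[int(hdr.get("data type", 4))]

    flat = np.fromfile(base.with_suffix(".img"), dtype=dtype)
    if flat.size != rows * cols * bands:
        raise ValueError("image size does not match header dimensions")
    data = np.moveaxis(flat.reshape(bands, rows, cols), 0, 2)

    wavelengths = None
    if "wavelength" in hdr:
        inner = hdr["wavelength"].strip("{} \n")
        if inner:
            wavelengths = np.array([float(v) for v in inner.split(",")])
    return data, wavelengths
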
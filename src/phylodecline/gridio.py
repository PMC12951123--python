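"""Plain-text grid I/O in the ESRI ASCII dialect.

Layers are 2D float arrays; missing cells are NaN in memory and the header's
NODATA_value on disk. Row 0 is the northernmost row, matching the on-disk
top-to-bottom order.
"""

from __future__ import annotations

import numpy as np

NODATA = -9999.0

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_ascii_grid(path, layer: np.ndarray, cellsize: float = 1.0,
                     xllcorner: float = 0.0, yllcorner: float = 0.0) -> None:
    arr = np.asarray(layer, dtype=float)
    if arr.ndim != 2:
        raise ValueError("layer must be 2D")
    nrows, ncols = arr.shape
    out = arr.copy()
    out[~np.isfinite(out)] = NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner!r}\n")
        fh.write(f"yllcorner {yllcorner!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read a grid; returns (array with NaN for NODATA, header dict)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _HEADER_KEYS or key == "nodata_value":
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", NODATA)
    arr[arr == nodata] = np.nan
    if "nrows" in header and arr.shape != (
        int(header["nrows"]), int(header["ncols"])
    ):
        raise ValueError(
            f"grid shape {arr.shape} disagrees with header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return arr, header
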
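"""TIFF and sidecar I/O with a consistent y-up frame.

Image files store row 0 at the top; the analysis uses a mathematical y-up
frame (row index increases with y) so that counterclockwise-positive angular
velocities are unambiguous.  Images are therefore flipped row-wise on load
and flipped back on save; a load/save round trip is the identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_stack", "write_stack", "write_json", "read_json"]


def read_stack(path) -> np.ndarray:
    """Read a (multi-page) TIFF and flip rows into the y-up frame.

    Returns an array whose last two axes are (y, x) with y increasing
    upward.
    """
    data = tifffile.imread(str(path))
    return np.flip(np.asarray(data), axis=-2)


def write_stack(path, data: np.ndarray, dtype=None) -> None:
    """Write an array (last two axes y, x in y-up frame) as TIFF."""
    arr = np.flip(np.asarray(data), axis=-2)
    if dtype is not None:
        arr = arr.astype(dtype)
    tifffile.imwrite(str(path), arr)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
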
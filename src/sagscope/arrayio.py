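"""Plain-text container for label images and voxel masks.

Format (lossless, line-oriented, diff-friendly):

    # sagscope-array 1
    # shape: <d0> <d1> [...]
    # dtype: <numpy dtype name>
    <whitespace-separated integers, one row of the flattened
     (d0, prod(rest)) view per line>

Boolean arrays are stored as 0/1 and restored to bool.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_array(path: str | Path, arr: np.ndarray) -> None:
    arr = np.asarray(arr)
    if arr.dtype.kind not in "biu":
        raise ValueError("only integer/boolean arrays are supported")
    flat = arr.reshape(arr.shape[0] if arr.ndim else 1, -1)
    header = (
        "sagscope-array 1\n"
        f"shape: {' '.join(map(str, arr.shape))}\n"
        f"dtype: {arr.dtype.name}"
    )
    np.savetxt(path, flat.astype(np.int64), fmt="%d", header=header)


def read_array(path: str | Path) -> np.ndarray:
    shape: tuple[int, ...] | None = None
    dtype = "int64"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("shape:"):
                shape = tuple(int(x) for x in body.split(":", 1)[1].split())
            elif body.startswith("dtype:"):
                dtype = body.split(":", 1)[1].strip()
    if shape is None:
        raise ValueError(f"{path}: not a sagscope-array file")
    data = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return data.reshape(shape).astype(dtype)
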
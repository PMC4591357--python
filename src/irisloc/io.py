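"""Readers and writers for annotations, truth files and debug grids.

Landmark files come in two plain-text dialects:

* *flat*: one ``x y`` pair per line, landmark order fixed by the scheme;
* *pts*: a points-list with a ``n_points: L`` header and the pairs
  between ``{`` and ``}`` braces (the dialect common to face-alignment
  training sets).

Eye-center ground truth is the eye-file style (one data line, four
numbers: left-eye x y, right-eye x y; ``#`` lines are comments) or a
generic CSV with columns filename, lx, ly, rx, ry.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = [
    "read_landmarks",
    "write_landmarks_flat",
    "write_landmarks_pts",
    "read_eye_file",
    "write_eye_file",
    "read_truth_csv",
    "export_grid_txt",
    "export_heatmap_png",
]


def read_landmarks(path) -> np.ndarray:
    """Read a landmark file in either dialect; returns an (L, 2) array."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if any(ln.lower().startswith(("version", "n_points")) or ln in "{}" for ln in lines):
        pts = []
        in_body = False
        for ln in lines:
            if ln == "{":
                in_body = True
            elif ln == "}":
                in_body = False
            elif in_body:
                x, y = ln.split()
                pts.append((float(x), float(y)))
        n_expected = None
        for ln in lines:
            if ln.lower().startswith("n_points"):
                n_expected = int(ln.split(":")[1])
        arr = np.array(pts, dtype=np.float64)
        if n_expected is not None and len(arr) != n_expected:
            raise ValueError(f"{path}: header says {n_expected} points, found {len(arr)}")
        return arr
    pts = [tuple(map(float, ln.split()[:2])) for ln in lines]
    return np.array(pts, dtype=np.float64)


def write_landmarks_flat(path, shape: np.ndarray) -> None:
    with open(path, "w") as fh:
        for x, y in np.asarray(shape, dtype=np.float64):
            fh.write(f"{x:.6f} {y:.6f}\n")


def write_landmarks_pts(path, shape: np.ndarray) -> None:
    shape = np.asarray(shape, dtype=np.float64)
    with open(path, "w") as fh:
        fh.write("version: 1\n")
        fh.write(f"n_points: {len(shape)}\n{{\n")
        for x, y in shape:
            fh.write(f"{x:.6f} {y:.6f}\n")
        fh.write("}\n")


def read_eye_file(path):
    """Read an eye-position file; returns ((lx, ly), (rx, ry))."""
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        lx, ly, rx, ry = map(float, ln.split()[:4])
        return (lx, ly), (rx, ry)
    raise ValueError(f"{path}: no data line found")


def write_eye_file(path, left, right) -> None:
    with open(path, "w") as fh:
        fh.write("#LX LY RX RY\n")
        fh.write(f"{left[0]:.6f} {left[1]:.6f} {right[0]:.6f} {right[1]:.6f}\n")


def read_truth_csv(path) -> dict:
    """Read a filename,lx,ly,rx,ry CSV into {filename: (left, right)}."""
    import pandas as pd

    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[row.filename] = ((float(row.lx), float(row.ly)), (float(row.rx), float(row.ry)))
    return out


def export_grid_txt(path, grid: np.ndarray) -> None:
    """Dump a 2-D field (center map, curvedness) as a plain-text grid."""
    np.savetxt(path, np.asarray(grid, dtype=np.float64), fmt="%.6g")


def export_heatmap_png(path, grid: np.ndarray, cmap: str = "viridis") -> None:
    """Save a 2-D field as a PNG heatmap for debugging."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.asarray(grid), cmap=cmap)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
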
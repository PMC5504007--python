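"""Filesystem interface: filename patterns, tile reading, output writing.

Automated microscopes name tiles either by grid coordinates
(``img_r{rr}_c{cc}.tif``) or by a sequential position (``t_{ppp}.tif``) whose
traversal order and origin corner vary by vendor. ``resolve_grid_filenames``
maps both conventions onto the package's row-major, top-left grid.

The positions file is a line-per-tile text format, written bit-exactly::

    file: <name>; corr: <ncc of placing edge, 10 decimals or -1.0>; position: (<x>, <y>); grid: (<col>, <row>);
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import DataError, PatternError
from .grid import MosaicLayout
from .metrics import AccuracyReport, Roi

__all__ = ["resolve_grid_filenames", "read_tile", "write_tile",
           "write_positions", "read_positions", "read_roi_csv", "write_roi_csv",
           "write_report", "write_run_log"]

_PLACEHOLDER = re.compile(r"\{(r+|c+|p+)\}")

ORIGINS = ("top-left", "top-right", "bottom-left", "bottom-right")
NUMBERINGS = ("row-major", "column-major", "serpentine-row", "serpentine-col")


def _sequential_index(ar: int, ac: int, rows: int, cols: int, numbering: str) -> int:
    if numbering == "row-major":
        return ar * cols + ac
    if numbering == "column-major":
        return ac * rows + ar
    if numbering == "serpentine-row":
        return ar * cols + (ac if ar % 2 == 0 else cols - 1 - ac)
    if numbering == "serpentine-col":
        return ac * rows + (ar if ac % 2 == 0 else rows - 1 - ar)
    raise PatternError(f"unknown numbering {numbering!r}")


def resolve_grid_filenames(pattern: str, rows: int, cols: int,
                           origin: str = "top-left", numbering: str = "row-major",
                           start_index: int = 1) -> list[list[str]]:
    """Map (row, col) of the top-left-origin grid to acquisition filenames.

    ``pattern`` contains ``{r..}`` + ``{c..}`` placeholders (brace count sets
    zero padding; 0-based indices) or a single ``{p..}`` sequential placeholder
    whose traversal is set by ``numbering`` and starts at ``start_index``.
    ``origin`` names the corner where the acquisition began. Returns a
    row-major rows×cols matrix of filenames.
    """
    kinds = [m.group(1)[0] for m in _PLACEHOLDER.finditer(pattern)]
    if sorted(kinds) == ["c", "r"]:
        mode = "rc"
    elif kinds == ["p"]:
        mode = "p"
    else:
        raise PatternError(
            f"pattern {pattern!r} must contain either {{r..}} and {{c..}} or a "
            f"single {{p..}} placeholder")
    if origin not in ORIGINS:
        raise PatternError(f"origin must be one of {ORIGINS}, got {origin!r}")
    if numbering not in NUMBERINGS:
        raise PatternError(f"numbering must be one of {NUMBERINGS}, got {numbering!r}")

    def fill(values: dict[str, int]) -> str:
        def sub(m: re.Match) -> str:
            kind = m.group(1)[0]
            width = len(m.group(1))
            val = values[kind]
            text = f"{val:0{width}d}"
            if len(text) > width:
                raise PatternError(
                    f"index {val} overflows {width}-digit placeholder in {pattern!r}")
            return text
        return _PLACEHOLDER.sub(sub, pattern)

    out: list[list[str]] = []
    for row in range(rows):
        line = []
        for col in range(cols):
            ar = rows - 1 - row if origin.startswith("bottom") else row
            ac = cols - 1 - col if origin.endswith("right") else col
            if mode == "rc":
                line.append(fill({"r": ar, "c": ac}))
            else:
                idx = _sequential_index(ar, ac, rows, cols, numbering) + start_index
                line.append(fill({"p": idx}))
        out.append(line)
    return out


def read_tile(path: str | Path) -> np.ndarray:
    """Read one grayscale tile (8/16-bit TIFF or PNG), dtype preserved.

    Multi-page TIFFs yield their first page with a warning; RGB input is
    rejected (convert upstream).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"tile file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                if len(tf.pages) > 1:
                    warnings.warn(f"{path.name}: multi-page TIFF, using first page",
                                  stacklevel=2)
                img = tf.pages[0].asarray()
        else:
            img = iio.imread(path)
    except DataError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any decoder failure
        raise DataError(f"cannot read tile {path}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim == 3:
        raise DataError(f"{path}: RGB/multi-channel input not supported; "
                        f"convert to grayscale upstream")
    if img.ndim != 2:
        raise DataError(f"{path}: expected a 2-D image, got ndim={img.ndim}")
    return img


def write_tile(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def write_mosaic(path: str | Path, image: np.ndarray) -> None:
    """Write the stitched mosaic as TIFF (BigTIFF when it would exceed 4 GiB)."""
    big = image.nbytes >= 2 ** 32
    tifffile.imwrite(Path(path), image, bigtiff=big)


_POSITION_LINE = re.compile(
    r"^file:\s*(?P<file>[^;]+);\s*corr:\s*(?P<corr>[-0-9.eE]+);\s*"
    r"position:\s*\((?P<x>-?\d+),\s*(?P<y>-?\d+)\);\s*"
    r"grid:\s*\((?P<col>\d+),\s*(?P<row>\d+)\);\s*$")


def write_positions(layout: MosaicLayout, path: str | Path,
                    names: list[list[str]] | None = None) -> None:
    """Write the per-tile positions file (row-major tile order)."""
    lines = []
    for r in range(layout.rows):
        for c in range(layout.cols):
            name = names[r][c] if names is not None else f"tile_r{r:03d}_c{c:03d}.tif"
            corr = layout.placement_ncc[r, c]
            corr_text = "-1.0" if corr < 0 else f"{corr:.10f}"
            x, y = layout.position(r, c)
            lines.append(f"file: {name}; corr: {corr_text}; "
                         f"position: ({x}, {y}); grid: ({c}, {r});")
    Path(path).write_text("\n".join(lines) + "\n")


def read_positions(path: str | Path) -> tuple[MosaicLayout, list[list[str]]]:
    """Parse a positions file back into a layout plus the filename matrix.

    Round-trips :func:`write_positions` exactly (integer positions, ncc to 10
    decimals). Malformed lines raise with their line number.
    """
    entries: dict[tuple[int, int], tuple[str, float, int, int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        m = _POSITION_LINE.match(line)
        if m is None:
            raise DataError(f"{path}: malformed positions line {lineno}: {line!r}")
        entries[(int(m["row"]), int(m["col"]))] = (
            m["file"].strip(), float(m["corr"]), int(m["x"]), int(m["y"]))
    if not entries:
        raise DataError(f"{path}: empty positions file")
    rows = max(r for r, _ in entries) + 1
    cols = max(c for _, c in entries) + 1
    if len(entries) != rows * cols:
        raise DataError(f"{path}: positions file does not cover a full "
                        f"{rows}x{cols} grid")
    x = np.zeros((rows, cols), dtype=np.int64)
    y = np.zeros((rows, cols), dtype=np.int64)
    ncc = np.full((rows, cols), -1.0)
    names = [["" for _ in range(cols)] for _ in range(rows)]
    for (r, c), (name, corr, xx, yy) in entries.items():
        names[r][c] = name
        ncc[r, c] = corr
        x[r, c] = xx
        y[r, c] = yy
    layout = MosaicLayout(x=x, y=y, placement_ncc=ncc, tree_edges=[],
                          mosaic_width=int(x.max()), mosaic_height=int(y.max()))
    return layout, names


def read_roi_csv(path: str | Path) -> list[Roi]:
    """Read ROIs from CSV with required header columns label, x, y, area."""
    df = pd.read_csv(path)
    missing = {"label", "x", "y", "area"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: ROI CSV missing columns {sorted(missing)}")
    return [Roi(float(row.x), float(row.y), float(row.area), str(row.label))
            for row in df.itertuples()]


def write_roi_csv(rois: list[Roi], path: str | Path) -> None:
    pd.DataFrame(
        [{"label": r.label, "x": r.x, "y": r.y, "area": r.area} for r in rois]
    ).to_csv(path, index=False)


def write_report(report: AccuracyReport, csv_path: str | Path,
                 summary_path: str | Path | None = None) -> None:
    report.to_frame().to_csv(csv_path, index=False)
    if summary_path is not None:
        Path(summary_path).write_text(report.summary())


def write_run_log(path: str | Path, params: dict, model_text: str) -> None:
    """Echo all resolved parameters and the stage model into a run log."""
    lines = ["[parameters]"]
    for key in sorted(params):
        lines.append(f"{key}={params[key]}")
    lines.append("")
    lines.append("[stage_model]")
    lines.append(model_text.rstrip())
    Path(path).write_text("\n".join(lines) + "\n")
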
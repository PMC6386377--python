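"""Raster image, particle-table, recipe and report input/output.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)`` with row 0 at the image top;
* images are stored as 2-D float64 arrays in their *native* intensity range
  (an 8-bit PNG arrives as 0..255, a 16-bit TIFF as 0..65535) — no silent
  normalisation;
* multi-channel inputs are reduced to a single plane at read time, either by
  channel index or by an equal-weight mean ("luminance"), because
  fluorescence channels are not perceptual RGB.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "Image",
    "read_image",
    "write_image",
    "write_particle_table",
    "read_particle_table",
    "write_report",
    "recipe_from_report",
]

PARTICLE_TABLE_COLUMNS = [
    "label",
    "area_px",
    "area_um2",
    "centroid_row",
    "centroid_col",
    "perimeter",
    "major_axis",
    "minor_axis",
    "roundness",
    "circularity",
    "solidity",
    "mean_intensity",
]


@dataclass
class Image:
    """A single-channel 2-D image with optional physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of finite real intensities, at least 1x1.
    pixel_size
        Physical edge length of one pixel in micrometres, or ``None`` when
        unknown (the default); physical areas are only ever reported when it
        is present.
    provenance
        Source path or generator tag, for reports.
    """

    pixels: np.ndarray
    pixel_size: Optional[float] = None
    provenance: str = "<memory>"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("Image requires a non-empty 2-D pixel array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Image intensities must all be finite")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive when given")
        self.pixels = arr

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def _reduce_channels(arr: np.ndarray, channel_policy: Union[int, str]) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    # channels last (H, W, C) as delivered by imageio for RGB(A)
    n_chan = arr.shape[2]
    if channel_policy == "luminance":
        return arr[..., : min(n_chan, 3)].mean(axis=2)
    if isinstance(channel_policy, int):
        if not 0 <= channel_policy < n_chan:
            raise ValueError(
                f"channel index {channel_policy} out of range for {n_chan} channels"
            )
        return arr[..., channel_policy]
    raise ValueError(f"unknown channel_policy {channel_policy!r}")


def read_image(path, channel_policy: Union[int, str] = "luminance") -> Image:
    """Read a TIFF/PNG/JPEG file into a single-channel :class:`Image`.

    Multi-channel files are reduced per *channel_policy*: an integer selects
    that channel plane, ``"luminance"`` averages the (up to three) colour
    channels with equal weights.  Integer sample values are preserved
    losslessly in the float64 result.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(str(path))
        else:
            import imageio.v3 as iio

            arr = iio.imread(str(path))
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"empty image: {path}")
    plane = _reduce_channels(arr, channel_policy)
    return Image(np.asarray(plane, dtype=np.float64), provenance=str(path))


def write_image(image: Image, path, dtype: Optional[str] = None) -> None:
    """Write an :class:`Image` to TIFF or PNG.

    For TIFF the pixel dtype defaults to the smallest unsigned integer type
    that holds the data losslessly when the data are integral, else float32;
    pass ``dtype`` to force one.  PNG output requires uint8/uint16 range.
    """
    path = Path(path)
    arr = image.pixels
    if dtype is None:
        if np.all(arr == np.round(arr)) and arr.min() >= 0:
            dtype = "uint8" if arr.max() <= 255 else ("uint16" if arr.max() <= 65535 else "float32")
        else:
            dtype = "float32"
    out = arr.astype(dtype)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), out)
    elif suffix == ".png":
        import imageio.v3 as iio

        if out.dtype.kind == "f":
            raise ValueError("PNG output requires integer pixel values")
        iio.imwrite(str(path), out)
    else:
        raise ValueError(f"unsupported output format {suffix!r}")


def write_particle_table(table: pd.DataFrame, path) -> None:
    """Write a particle table to CSV with a locale-independent header row."""
    path = Path(path)
    cols = [c for c in PARTICLE_TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    try:
        table.loc[:, cols].to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise IOError(f"could not write particle table to {path}: {exc}") from exc


def read_particle_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


_RECIPE_BLOCK = re.compile(r"```json recipe\n(.*?)\n```", re.DOTALL)


def write_report(recipe, inputs, tables, path, summaries=None) -> None:
    """Write a Markdown processing report.

    The report lists every stage, operator name and parameter value of the
    recipe, the input filenames with per-image particle counts, and embeds
    the recipe JSON verbatim so that the analysis can be re-executed from
    the report alone (see :func:`recipe_from_report`).

    Parameters
    ----------
    recipe
        A complete :class:`~morphoquant.engine.PipelineRecipe`.
    inputs
        Sequence of input names (filenames or provenance tags).
    tables
        Sequence of particle tables, aligned with *inputs*.
    path
        Output ``.md`` path.
    """
    from .engine import PipelineRecipe  # local import to avoid a cycle

    if not isinstance(recipe, PipelineRecipe):
        raise TypeError("write_report expects a PipelineRecipe")
    recipe.require_complete()
    inputs = list(inputs)
    tables = list(tables)
    if len(inputs) != len(tables):
        raise ValueError("inputs and tables must align one-to-one")

    lines = ["# Particle analysis report", ""]
    ctx = recipe.context
    if ctx is not None:
        lines += [
            f"- imaging method: {ctx.imaging_method}",
            f"- specimen type: {ctx.specimen_type}",
        ]
    lines += [f"- tool version: {recipe.tool_version}", ""]
    lines += ["## Pipeline stages", ""]
    for stage_name, spec in recipe.iter_stages():
        params = ", ".join(f"{k}={v!r}" for k, v in sorted(spec.params.items()))
        lines.append(f"1. **{stage_name}**: `{spec.name}` ({params or 'no parameters'})")
    lines.append(
        f"1. **watershed**: `{recipe.watershed_method}` "
        f"({', '.join(f'{k}={v!r}' for k, v in sorted(recipe.watershed_params.items())) or 'no parameters'})"
    )
    lines += ["", "## Inputs and results", ""]
    for name, table in zip(inputs, tables):
        n = len(table)
        mean_area = float(table["area_px"].mean()) if n else float("nan")
        lines.append(
            f"- `{name}`: {n} particles"
            + (f", mean area {mean_area:.6g} px" if n else "")
        )
    if summaries:
        lines += ["", "## Summary", ""]
        for key, value in summaries.items():
            lines.append(f"- {key}: {value}")
    lines += [
        "",
        "## Recipe (machine readable)",
        "",
        "The JSON block below re-runs this analysis exactly.",
        "",
        "```json recipe",
        recipe.to_json(indent=2),
        "```",
        "",
    ]
    Path(path).write_text("\n".join(lines))


def recipe_from_report(path):
    """Recover the embedded :class:`PipelineRecipe` from a report file."""
    from .engine import PipelineRecipe

    text = Path(path).read_text()
    match = _RECIPE_BLOCK.search(text)
    if match is None:
        raise ValueError(f"no embedded recipe found in report {path}")
    return PipelineRecipe.from_json(match.group(1))
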
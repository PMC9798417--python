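"""Ion-image reconstruction from line-scan imaging data.

A surface-sampling imaging run rasters the stage line by line while the MS
acquires scans at a fixed rate; each scan is one pixel along the track.
With raster speed v (mm/s), scan time t, and pixel width w, the scan lands
in column floor(v*t / w) of its line's row.  The default pixel width equals
the line spacing (square pixels).  A pixel's intensity for a target ion is
the summed intensity of peaks within ±tolerance (Da) of the target m/z;
multiple scans mapping to one pixel are averaged, unvisited pixels are 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra import Spectrum

__all__ = ["IonImage", "reconstruct_image", "write_image", "read_image"]


@dataclass
class IonImage:
    """Rectangular intensity grid for one target ion.

    Row 0 is the first scanned line, column 0 the scan start; the origin is
    top-left.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    target_mz: float
    tolerance: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def reconstruct_image(
    raster: list[tuple[int, float, Spectrum]],
    raster_speed: float,
    line_spacing: float,
    target_mz: float,
    tolerance: float = 0.01,
    pixel_width: float | None = None,
) -> IonImage:
    """Map line scans onto a pixel grid and extract one target ion.

    Parameters
    ----------
    raster
        ``(line_index, scan_time_s, Spectrum)`` triples.
    raster_speed, line_spacing
        Stage speed along a line (mm/s) and spacing between lines (mm).
    target_mz, tolerance
        Ion extraction window: peaks within ``target_mz ± tolerance`` (Da).
    pixel_width
        Along-track pixel width in mm; defaults to ``line_spacing`` for
        square pixels.
    """
    if not raster:
        raise ValueError("raster is empty")
    if raster_speed <= 0 or line_spacing <= 0:
        raise ValueError("raster_speed and line_spacing must be > 0")
    if pixel_width is None:
        pixel_width = line_spacing

    entries: list[tuple[int, int, float]] = []
    for line, t, spec in raster:
        if t < 0:
            raise ValueError("scan time must be non-negative")
        col = int(np.floor(t * raster_speed / pixel_width))
        window = np.abs(spec.mz - target_mz) <= tolerance
        entries.append((int(line), col, float(spec.intensity[window].sum())))

    n_rows = max(e[0] for e in entries) + 1
    n_cols = max(e[1] for e in entries) + 1
    total = np.zeros((n_rows, n_cols))
    count = np.zeros((n_rows, n_cols))
    for r, c, val in entries:
        total[r, c] += val
        count[r, c] += 1
    pixels = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    return IonImage(pixels, pixel_size_mm=pixel_width, target_mz=target_mz,
                    tolerance=tolerance)


def write_image(image: IonImage, path: str | Path) -> None:
    """Write the pixel grid as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, image.pixels, delimiter="\t", fmt="%.17g")
    meta = {"pixel_size_mm": image.pixel_size_mm, "target_mz": image.target_mz,
            "tolerance": image.tolerance, "origin": "top-left",
            "rows": image.shape[0], "cols": image.shape[1]}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_image(path: str | Path) -> IonImage:
    path = Path(path)
    pixels = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return IonImage(pixels, meta["pixel_size_mm"], meta["target_mz"], meta["tolerance"])
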
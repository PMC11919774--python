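"""Screen geometry: degrees of visual angle <-> pixels <-> saliency-map cells.

The recording setup is a 19-inch 5:4 LCD (1280 x 1024 px) viewed from
70 cm. Gaze positions are expressed in degrees of visual angle relative to
the screen centre, with x increasing rightward and y increasing *downward*
(aligned with image rows, so cell (0, 0) is the top-left of the image).
Degrees are converted to pixels with a single small-angle pixel pitch
evaluated at the screen centre; over the +/-15 deg extent of this display
the error versus the exact tangent mapping is below 3%.

Saliency maps live on an 80 x 64 cell grid (16 x 16 px cells for the
default display), shared by every module in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CM_PER_INCH = 2.54


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry and the degree/pixel/cell conversions derived from it."""

    width_px: int = 1280
    height_px: int = 1024
    diagonal_inch: float = 19.0
    distance_cm: float = 70.0
    grid_cols: int = 80
    grid_rows: int = 64

    def __post_init__(self) -> None:
        if self.width_px % self.grid_cols or self.height_px % self.grid_rows:
            raise ValueError(
                "display resolution must be an integer multiple of the cell grid"
            )

    @property
    def pitch_cm(self) -> float:
        """Physical size of one pixel (cm), assuming square pixels."""
        diag_px = float(np.hypot(self.width_px, self.height_px))
        return self.diagonal_inch * CM_PER_INCH / diag_px

    @property
    def deg_per_px(self) -> float:
        """Small-angle pixel pitch in degrees, at the screen centre."""
        return float(np.degrees(np.arctan2(self.pitch_cm, self.distance_cm)))

    @property
    def px_per_deg(self) -> float:
        return 1.0 / self.deg_per_px

    @property
    def cell_px(self) -> int:
        """Edge length of one saliency-map cell in pixels."""
        return self.width_px // self.grid_cols

    @property
    def half_extent_deg(self) -> tuple[float, float]:
        """(x, y) half-width of the screen in degrees."""
        return (
            self.width_px / 2 * self.deg_per_px,
            self.height_px / 2 * self.deg_per_px,
        )

    # -- degrees <-> pixels -------------------------------------------------

    def deg_to_px(self, x_deg, y_deg):
        """Degrees (centre origin, y down) -> float pixel coordinates (x, y)."""
        x = np.asarray(x_deg, dtype=float) * self.px_per_deg + self.width_px / 2
        y = np.asarray(y_deg, dtype=float) * self.px_per_deg + self.height_px / 2
        return x, y

    def px_to_deg(self, x_px, y_px):
        x = (np.asarray(x_px, dtype=float) - self.width_px / 2) * self.deg_per_px
        y = (np.asarray(y_px, dtype=float) - self.height_px / 2) * self.deg_per_px
        return x, y

    # -- degrees <-> map cells ---------------------------------------------

    def deg_to_cell(self, x_deg, y_deg):
        """Degrees -> (row, col, on_screen).

        Rows/cols are clipped into the grid for convenience; the boolean
        ``on_screen`` mask is False for positions off the display, and such
        samples must be treated as missing by callers.
        """
        x_px, y_px = self.deg_to_px(x_deg, y_deg)
        on = (
            (x_px >= 0)
            & (x_px < self.width_px)
            & (y_px >= 0)
            & (y_px < self.height_px)
        )
        col = np.clip(np.floor(x_px / self.cell_px), 0, self.grid_cols - 1)
        row = np.clip(np.floor(y_px / self.cell_px), 0, self.grid_rows - 1)
        return row.astype(int), col.astype(int), on

    def cell_to_deg(self, row, col, rng: np.random.Generator | None = None):
        """Cell indices -> degrees.

        Returns the cell centre, or a uniform draw within the cell when a
        random generator is supplied (used when sampling saccade endpoints
        from a cell-resolution density).
        """
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        if rng is None:
            jx = jy = 0.5
        else:
            jx = rng.random(col.shape if col.shape else None)
            jy = rng.random(row.shape if row.shape else None)
        x_px = (col + jx) * self.cell_px
        y_px = (row + jy) * self.cell_px
        return self.px_to_deg(x_px, y_px)


DEFAULT_GEOMETRY = ScreenGeometry()
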
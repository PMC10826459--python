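"""Rasterized plan-view geometry of the hydrogel channel with an embedded spheroid.

The gel channel is modelled as a rectangle on a regular grid. Flow is driven
from the top edge (inlet, high pressure P1) to the bottom edge (outlet, P2);
the left/right walls are impermeable. A spheroid is a circular inclusion
strictly inside the gel. Grid convention: array index ``[i, j]`` maps to
physical position ``x = (j + 0.5) * h``, ``y = (i + 0.5) * h`` with *y*
increasing downstream (top edge is y = 0) and *h* the grid spacing in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChipGeometry", "GeometryError", "build_geometry"]


class GeometryError(ValueError):
    """Raised for inconsistent or unresolvable chip geometry."""


@dataclass(frozen=True)
class ChipGeometry:
    """Rasterized 2D map of the gel channel and spheroid inclusion.

    Attributes
    ----------
    gel_region : (ny, nx) bool array
        Cells belonging to the hydrogel (the whole rectangle by default).
    spheroid_mask : (ny, nx) bool array
        Cells inside the circular spheroid inclusion.
    spheroid_center : (x, y) in um.
    spheroid_radius : um.
    inlet_columns, outlet_columns : int arrays
        Column indices of the top/bottom boundary faces held at P1/P2
        (pillar-gap segments); all other boundary faces are no-flux.
    pillar_side, channel_height : um, metadata carried through for reporting.
    grid_spacing : um per cell.
    """

    gel_region: np.ndarray
    spheroid_mask: np.ndarray
    spheroid_center: tuple[float, float]
    spheroid_radius: float
    inlet_columns: np.ndarray
    outlet_columns: np.ndarray
    grid_spacing: float
    pillar_side: float = 150.0
    channel_height: float = 280.0
    extent: tuple[float, float] = field(default=(0.0, 0.0))  # (width_x, span_y) um

    @property
    def shape(self) -> tuple[int, int]:
        return self.gel_region.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of cell centers, um."""
        ny, nx = self.shape
        h = self.grid_spacing
        x = (np.arange(nx) + 0.5) * h
        y = (np.arange(ny) + 0.5) * h
        return np.meshgrid(x, y)

    def interface_shell(self) -> np.ndarray:
        """One-cell shell of gel immediately outside the spheroid."""
        from scipy.ndimage import binary_dilation

        return binary_dilation(self.spheroid_mask) & ~self.spheroid_mask


def build_geometry(
    width: float = 1000.0,
    span: float = 1000.0,
    spheroid_radius: float = 100.0,
    spheroid_center: tuple[float, float] | None = None,
    grid_spacing: float = 5.0,
    inlet_gaps: list[tuple[float, float]] | None = None,
    outlet_gaps: list[tuple[float, float]] | None = None,
    pillar_side: float = 150.0,
    channel_height: float = 280.0,
) -> ChipGeometry:
    """Rasterize the gel channel with a centered (or offset) spheroid.

    Parameters
    ----------
    width : cross-flow extent of the gel channel (x), um.
    span : flow-wise extent between the two fluidic channels (y), um.
    spheroid_radius : um; must resolve to at least 5 grid cells.
    spheroid_center : (x, y) um; defaults to the channel center.
    inlet_gaps, outlet_gaps : optional ``[(x_start, x_stop), ...]`` um ranges
        of open pillar gaps on the top/bottom boundary; default is fully open.
    """
    if width <= 0 or span <= 0 or grid_spacing <= 0:
        raise GeometryError("width, span and grid_spacing must be positive")
    if spheroid_radius < 5.0 * grid_spacing:
        raise GeometryError(
            f"grid too coarse: spheroid_radius {spheroid_radius} um must be "
            f">= 5 x grid_spacing ({5 * grid_spacing} um)"
        )
    nx = int(round(width / grid_spacing))
    ny = int(round(span / grid_spacing))
    if spheroid_center is None:
        spheroid_center = (width / 2.0, span / 2.0)
    cx, cy = spheroid_center
    margin = spheroid_radius + grid_spacing
    if not (margin < cx < width - margin and margin < cy < span - margin):
        raise GeometryError(
            "spheroid overlaps the channel boundary: center "
            f"({cx}, {cy}) um with radius {spheroid_radius} um does not fit "
            f"inside the {width} x {span} um gel channel"
        )

    gel = np.ones((ny, nx), dtype=bool)
    xg, yg = np.meshgrid(
        (np.arange(nx) + 0.5) * grid_spacing, (np.arange(ny) + 0.5) * grid_spacing
    )
    spheroid = (xg - cx) ** 2 + (yg - cy) ** 2 <= spheroid_radius**2

    def _gap_columns(gaps):
        if gaps is None:
            return np.arange(nx)
        cols = np.zeros(nx, dtype=bool)
        xc = (np.arange(nx) + 0.5) * grid_spacing
        for x0, x1 in gaps:
            cols |= (xc >= x0) & (xc <= x1)
        return np.flatnonzero(cols)

    inlet = _gap_columns(inlet_gaps)
    outlet = _gap_columns(outlet_gaps)
    if inlet.size == 0 or outlet.size == 0:
        raise GeometryError("inlet and outlet segments must be nonempty")

    return ChipGeometry(
        gel_region=gel,
        spheroid_mask=spheroid,
        spheroid_center=(cx, cy),
        spheroid_radius=spheroid_radius,
        inlet_columns=inlet,
        outlet_columns=outlet,
        grid_spacing=grid_spacing,
        pillar_side=pillar_side,
        channel_height=channel_height,
        extent=(width, span),
    )
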
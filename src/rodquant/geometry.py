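"""Per-cell geometric frames from label masks.

Each labeled component is reduced to a straight-axis model: a principal
axis through the pixel centroid, two poles at the extreme pixel-center
projections, and a length in micrometres. Downstream modules express
every position as an axial coordinate ``s`` in [0, 1] measured from
``pole_a`` toward ``pole_b``.

The straight-axis (principal-component) model assumes near-straight rods;
curved-cell medial axes are a documented extension point, not provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

__all__ = ["CellGeometry", "segment_simple", "extract_geometry", "axial_coordinate"]

#: components smaller than this many pixels are skipped by extract_geometry
MIN_COMPONENT_PX = 5

#: eigenvalue ratio above which a component is flagged as having no clear
#: long axis (e.g. a square); the first principal axis is still used
LOW_ANISOTROPY_RATIO = 0.9


@dataclass
class CellGeometry:
    """Straight-axis frame of one labeled cell.

    Poles are subpixel (row, col) coordinates at the extreme projections
    of the component's pixel centers onto its principal axis.  By
    construction ``s(pole_a) = 0`` and ``s(pole_b) = 1``.  Pole ordering
    is deterministic: ``pole_a`` is the pole with the smaller row
    (ties broken by smaller column), so outputs are reproducible before
    any biological orientation rule is applied.
    """

    cell_id: int
    pixel_size: float  # µm per pixel
    pole_a: np.ndarray  # (row, col), subpixel
    pole_b: np.ndarray
    centroid: np.ndarray
    axis: np.ndarray  # unit vector pointing pole_a -> pole_b
    length_um: float
    area_px: int
    low_anisotropy: bool = False

    @property
    def length_px(self) -> float:
        return self.length_um / self.pixel_size

    def flipped(self) -> "CellGeometry":
        """Frame with poles relabeled (a <-> b); maps s -> 1 - s."""
        return CellGeometry(
            cell_id=self.cell_id,
            pixel_size=self.pixel_size,
            pole_a=self.pole_b.copy(),
            pole_b=self.pole_a.copy(),
            centroid=self.centroid.copy(),
            axis=-self.axis,
            length_um=self.length_um,
            area_px=self.area_px,
            low_anisotropy=self.low_anisotropy,
        )


def segment_simple(
    channel: np.ndarray,
    min_area: int = 50,
    max_area: int = 100_000,
) -> np.ndarray:
    """Threshold-based segmentation for well-separated bright cells.

    Otsu threshold -> connected components (8-connectivity) -> area
    filter.  Surviving components are relabeled 1..K in raster order of
    their first pixel.  Intended for synthetic fields; segmentation of
    real DIC/phase images is out of scope.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0 or np.ptp(channel) == 0:
        warnings.warn("segment_simple: blank image, returning empty mask")
        return np.zeros(channel.shape, dtype=np.uint16)
    t = threshold_otsu(channel)
    cc = _cc_label(channel > t, connectivity=2)
    out = np.zeros(channel.shape, dtype=np.uint16)
    next_id = 1
    # skimage labels components in raster order of first pixel already;
    # iterating over sorted labels preserves that order through the filter
    for lab in range(1, cc.max() + 1):
        m = cc == lab
        area = int(m.sum())
        if min_area <= area <= max_area:
            out[m] = next_id
            next_id += 1
    if next_id == 1:
        warnings.warn("segment_simple: no components survived the area filter")
    return out


def extract_geometry(labels: np.ndarray, pixel_size: float) -> list[CellGeometry]:
    """Fit a straight-axis frame to every labeled component.

    The axis is the first principal component of the pixel coordinates;
    poles sit at the extreme pixel-center projections, so a horizontal
    100-px-long rectangle spans 99 px between pole centers.  Components
    of fewer than 5 px are skipped with a warning.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    labels = np.asarray(labels)
    out: list[CellGeometry] = []
    for cell_id in np.unique(labels):
        if cell_id == 0:
            continue
        coords = np.argwhere(labels == cell_id).astype(float)
        if len(coords) < MIN_COMPONENT_PX:
            warnings.warn(
                f"extract_geometry: component {cell_id} has {len(coords)} px "
                f"(< {MIN_COMPONENT_PX}), skipped"
            )
            continue
        centroid = coords.mean(axis=0)
        centered = coords - centroid
        cov = centered.T @ centered / len(coords)
        evals, evecs = np.linalg.eigh(cov)  # ascending
        axis = evecs[:, -1]
        low_aniso = bool(evals[-1] > 0 and evals[0] / evals[-1] > LOW_ANISOTROPY_RATIO)
        proj = centered @ axis
        pole_a = centroid + axis * proj.min()
        pole_b = centroid + axis * proj.max()
        # deterministic ordering: pole_a has the smaller row, ties -> column
        if (pole_a[0], pole_a[1]) > (pole_b[0], pole_b[1]):
            pole_a, pole_b = pole_b, pole_a
        sep = pole_b - pole_a
        length_px = float(np.hypot(*sep))
        if length_px == 0:
            warnings.warn(f"extract_geometry: component {cell_id} degenerate, skipped")
            continue
        out.append(
            CellGeometry(
                cell_id=int(cell_id),
                pixel_size=pixel_size,
                pole_a=pole_a,
                pole_b=pole_b,
                centroid=centroid,
                axis=sep / length_px,
                length_um=length_px * pixel_size,
                area_px=len(coords),
                low_anisotropy=low_aniso,
            )
        )
    return out


def axial_coordinate(point, geometry: CellGeometry):
    """Axial coordinate of a point in a cell's frame.

    Returns ``(s, x)`` where ``s`` is the projection of ``point - pole_a``
    onto the axis as a fraction of cell length, clamped to [0, 1], and
    ``x = s * length`` in µm.  Accepts a single (row, col) point or an
    (N, 2) array; perpendicular offset does not affect ``s``.
    """
    pt = np.asarray(point, dtype=float)
    proj_px = (pt - geometry.pole_a) @ geometry.axis
    s = np.clip(proj_px / geometry.length_px, 0.0, 1.0)
    return s, s * geometry.length_um
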
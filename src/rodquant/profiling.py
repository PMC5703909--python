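"""Axial fluorescence profiles and population demographs.

A demograph stacks per-cell 1D intensity profiles as image rows, sorted
by cell length with the shortest cell at the top, giving a population-
wide view of a protein's localization pattern over the cell cycle.

Profiles here use normalized axial coordinates: every in-mask pixel is
assigned to one of ``n_bins`` equal bins of the fractional axial
coordinate ``s``, and the bin intensity is the mean pixel value.  All
rows of a demograph therefore share columns regardless of cell length;
an absolute-length midcell-centered rendering is a display option of
:func:`plot_demograph`, not of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CellGeometry, axial_coordinate

__all__ = [
    "LineProfile",
    "Demograph",
    "extract_profile",
    "orient_profile",
    "orient_cell_profiles",
    "build_demograph",
    "plot_demograph",
]

DEFAULT_N_BINS = 100


class ProfileError(ValueError):
    pass


@dataclass
class LineProfile:
    """Mean intensity of one cell binned along its axis."""

    cell_id: int
    channel: str
    length_um: float
    s_centers: np.ndarray  # axial fraction, strictly increasing in (0, 1)
    intensity: np.ndarray  # mean photons per bin
    interpolated: np.ndarray  # bool per bin: filled from neighbors
    flipped: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.s_centers)

    @property
    def x_centers_um(self) -> np.ndarray:
        return self.s_centers * self.length_um

    def reversed(self) -> "LineProfile":
        return replace(
            self,
            intensity=self.intensity[::-1].copy(),
            interpolated=self.interpolated[::-1].copy(),
            flipped=not self.flipped,
        )


def extract_profile(
    image: np.ndarray,
    labels: np.ndarray,
    geometry: CellGeometry,
    n_bins: int = DEFAULT_N_BINS,
) -> LineProfile:
    """Bin a cell's pixels along the axial coordinate.

    Every pixel of the cell mask contributes to exactly one bin (the bin
    containing its ``s`` coordinate); bin intensity is the mean pixel
    value.  Empty bins are filled by linear interpolation between
    neighboring non-empty bins (leading/trailing empties copy the nearest
    valid bin) and flagged.  Raises :class:`ProfileError` when fewer than
    ``n_bins/2`` bins are non-empty — the cell is too small for the
    requested resolution.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    coords = np.argwhere(labels == geometry.cell_id)
    if len(coords) == 0:
        raise ProfileError(f"cell {geometry.cell_id} not present in label mask")
    s, _ = axial_coordinate(coords.astype(float), geometry)
    idx = np.minimum((s * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=image[coords[:, 0], coords[:, 1]], minlength=n_bins)
    nonempty = counts > 0
    if nonempty.sum() < n_bins / 2:
        raise ProfileError(
            f"cell {geometry.cell_id}: only {int(nonempty.sum())}/{n_bins} bins "
            "non-empty; too small for this n_bins"
        )
    centers = (np.arange(n_bins) + 0.5) / n_bins
    intensity = np.empty(n_bins, dtype=float)
    intensity[nonempty] = sums[nonempty] / counts[nonempty]
    if not nonempty.all():
        intensity[~nonempty] = np.interp(
            centers[~nonempty], centers[nonempty], intensity[nonempty]
        )
    return LineProfile(
        cell_id=geometry.cell_id,
        channel="",
        length_um=geometry.length_um,
        s_centers=centers,
        intensity=intensity,
        interpolated=~nonempty,
    )


def _wants_flip(profile: LineProfile) -> bool:
    """Brighter-half-first rule: flip when the second half outshines the first.

    Halves are the first and last floor(n/2) bins (an odd middle bin is
    ignored); an exact tie leaves the profile unflipped.
    """
    h = profile.n_bins // 2
    return float(profile.intensity[:h].sum()) < float(profile.intensity[-h:].sum())


def orient_profile(
    profile: LineProfile,
    rule: str = "brighter_half_first",
    reference: LineProfile | None = None,
) -> LineProfile:
    """Return the profile oriented by the given rule.

    ``brighter_half_first`` reverses the profile when its own integrated
    intensity is larger in the second half; ``by_reference_channel``
    applies the same decision computed on ``reference`` (another profile
    of the same cell); ``none`` returns the profile unchanged.
    """
    if rule == "none":
        return profile
    if rule == "brighter_half_first":
        return profile.reversed() if _wants_flip(profile) else profile
    if rule == "by_reference_channel":
        if reference is None:
            raise ValueError("by_reference_channel requires a reference profile")
        if reference.cell_id != profile.cell_id:
            raise ValueError("reference profile belongs to a different cell")
        return profile.reversed() if _wants_flip(reference) else profile
    raise ValueError(f"unknown orientation rule {rule!r}")


def orient_cell_profiles(
    profiles: dict[str, LineProfile],
    rule: str = "brighter_half_first",
    reference_channel: str | None = None,
) -> dict[str, LineProfile]:
    """Orient all channels of one cell with a single flip decision.

    The decision channel is ``reference_channel`` if given, else the
    first channel in the dict; the resulting flag is applied to every
    channel so multi-channel analyses stay consistent.
    """
    if rule == "none" or not profiles:
        return dict(profiles)
    ref_name = reference_channel if reference_channel is not None else next(iter(profiles))
    flip = _wants_flip(profiles[ref_name])
    return {k: (p.reversed() if flip else p) for k, p in profiles.items()}


@dataclass
class Demograph:
    """Stacked per-cell profiles, shortest cell first."""

    matrix: np.ndarray  # (n_cells, n_bins), min-max normalized rows by default
    cell_ids: np.ndarray
    lengths_um: np.ndarray  # non-decreasing top to bottom
    channel: str
    normalized: bool

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


def build_demograph(profiles: list[LineProfile], normalize: bool = True) -> Demograph:
    """Sort profiles by cell length (ties by cell id) and stack them.

    Rows are min-max normalized to [0, 1] by default; a constant row
    maps to all zeros.  Set ``normalize=False`` for raw intensities.
    """
    if not profiles:
        raise ValueError("build_demograph: no profiles")
    n_bins = profiles[0].n_bins
    channel = profiles[0].channel
    if any(p.n_bins != n_bins for p in profiles):
        raise ValueError("profiles differ in n_bins")
    if any(p.channel != channel for p in profiles):
        raise ValueError("profiles mix channels")
    order = sorted(range(len(profiles)), key=lambda i: (profiles[i].length_um, profiles[i].cell_id))
    mat = np.stack([profiles[i].intensity for i in order]).astype(float)
    if normalize:
        lo = mat.min(axis=1, keepdims=True)
        rng = np.ptp(mat, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(rng > 0, (mat - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return Demograph(
        matrix=mat,
        cell_ids=np.array([profiles[i].cell_id for i in order]),
        lengths_um=np.array([profiles[i].length_um for i in order]),
        channel=channel,
        normalized=normalize,
    )


def plot_demograph(demo: Demograph, path=None, absolute_length: bool = False, cmap="inferno"):
    """Render a demograph to a matplotlib figure (optionally saved).

    With ``absolute_length=True`` each row is drawn at its own physical
    width centered at midcell, the conventional display for demographs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 6))
    if not absolute_length:
        ax.imshow(demo.matrix, aspect="auto", cmap=cmap, interpolation="nearest")
        ax.set_xlabel("normalized cell length")
    else:
        half = demo.lengths_um.max() / 2
        n_cols = demo.matrix.shape[1]
        canvas = np.full((demo.n_cells, 2 * n_cols), np.nan)
        for i in range(demo.n_cells):
            w = max(2, int(round(n_cols * demo.lengths_um[i] / demo.lengths_um.max())))
            row = np.interp(np.linspace(0, 1, w), np.linspace(0, 1, n_cols), demo.matrix[i])
            start = n_cols - w // 2
            canvas[i, start:start + w] = row
        ax.imshow(canvas, aspect="auto", cmap=cmap, interpolation="nearest",
                  extent=(-half, half, demo.n_cells, 0))
        ax.set_xlabel("distance from midcell (µm)")
    ax.set_ylabel("cells (sorted by length)")
    ax.set_title(demo.channel or "demograph")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
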
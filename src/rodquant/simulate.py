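"""Synthetic multi-channel fluorescence fields of rod-shaped cells.

Cells are straight spherocylinders placed without overlap in a 2D field.
Each configured channel renders one signal kind:

``foci``
    0-3 diffraction-limited spots per cell, placed by a positional rule:
    ``polar_band`` (each focus a fraction of cell length from its nearest
    pole, drawn uniformly from a band, emulating the wild-type-like
    15-25% band of ParB-origin complexes), ``symmetric_pair`` (one band
    draw per cell, foci mirrored about midcell — the fully segregated
    wild-type arrangement), or ``uniform_over_nucleoid``.
``patch``
    an elongated zone of uniform emission starting at a pole (unipolar /
    bipolar, emulating 1-2 µm subpolar bactofilin scaffolds) or centered
    at midcell.
``nucleoid``
    a centered block occupying a configurable fraction of cell length,
    scaled per cell by a DNA-content multiplier.
``uniform``
    constant emission over the whole cell (cytoplasmic marker).

Rendering follows the standard fluorescence noise model: the ideal
photon map is blurred with a Gaussian PSF, a constant background is
added, pixel values are Poisson-sampled, and Gaussian read noise is
added.  Foci are rendered with pixel-integrated Gaussians so the
configured amplitude is the total photon count of the spot.

All randomness flows through one seeded generator per run; ground truth
for every cell is returned and can be round-tripped through CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from scipy.special import erf

__all__ = [
    "ChannelSpec",
    "SimConfig",
    "GroundTruthCell",
    "sample_population",
    "render_field",
    "simulate_field",
    "write_truth",
    "read_truth",
    "write_field",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap (field too small)."""


def focus_amplitude_for_snr(snr: float, background: float, psf_sigma: float) -> float:
    """Total focus photons giving the requested peak SNR.

    SNR is defined as peak amplitude over shot noise, peak / sqrt(background);
    a Gaussian spot of total mass A has peak A / (2 pi sigma^2).
    """
    return float(snr * np.sqrt(background) * 2.0 * np.pi * psf_sigma**2)


def extended_amplitude_for_snr(snr: float, background: float) -> float:
    """Photons/px over an extended footprint giving the requested peak SNR."""
    return float(snr * np.sqrt(background))


@dataclass
class ChannelSpec:
    """Specification of one fluorescence channel.

    Only the parameters of the channel's ``kind`` are used; the rest are
    ignored.  Amplitudes are photon counts: total photons per focus for
    ``kind='foci'``, photons per pixel of footprint otherwise.
    """

    name: str
    kind: str  # foci | patch | nucleoid | uniform
    amplitude: float = 1000.0
    # --- foci ---
    count_probs: dict = field(default_factory=lambda: {2: 1.0})  # over {0,1,2,3}
    rule: str = "polar_band"  # polar_band | symmetric_pair | uniform_over_nucleoid
    f_lo: float = 0.15
    f_hi: float = 0.25
    # --- patch ---
    patch_length_um: tuple = (1.0, 2.0)  # (lo, hi) or scalar, µm
    polarity: str = "bipolar"  # unipolar | bipolar | midcell
    # --- nucleoid ---
    nucleoid_fraction: float = 0.5  # of cell length
    center_offset: float = 0.0  # of cell length, signed
    content_values: tuple = (1.0,)  # per-cell DNA-content multiplier choices
    content_probs: tuple | None = None
    content_cv: float = 0.0  # lognormal-free Gaussian CV on the multiplier

    def __post_init__(self):
        if self.kind not in ("foci", "patch", "nucleoid", "uniform"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.kind == "foci":
            if self.rule not in ("polar_band", "symmetric_pair", "uniform_over_nucleoid"):
                raise ValueError(f"unknown focus rule {self.rule!r}")
            # keys may arrive as strings from YAML/JSON config echoes
            self.count_probs = {int(k): float(v) for k, v in self.count_probs.items()}
            if not (0.0 <= self.f_lo <= self.f_hi <= 0.5):
                raise ValueError("focus band requires 0 <= f_lo <= f_hi <= 0.5")
            if not all(0 <= int(k) <= 3 for k in self.count_probs):
                raise ValueError("focus counts must lie in {0,1,2,3}")
        if self.kind == "nucleoid" and not (0.0 < self.nucleoid_fraction <= 1.0):
            raise ValueError("nucleoid_fraction must be in (0, 1]")
        if self.kind == "patch" and self.polarity not in ("unipolar", "bipolar", "midcell"):
            raise ValueError(f"unknown patch polarity {self.polarity!r}")


@dataclass
class SimConfig:
    """Generative parameters for one synthetic field.

    Defaults resemble 100x/1.4NA widefield imaging of *M. xanthus*:
    65 nm pixels, a 1.3 px PSF sigma, 0.7 µm wide cells with lengths
    uniform on 3-12 µm.
    """

    n_cells: int = 50
    field_shape: tuple = (1024, 1024)  # (rows, cols) px
    pixel_size: float = 0.065  # µm / px
    cell_width_um: float = 0.7
    length_dist: tuple = ("uniform", 3.0, 12.0)  # or ("normal", mean, sd), µm
    psf_sigma: float = 1.3  # px
    background: float = 100.0  # photons / px
    read_noise_sd: float = 2.0  # photons
    seed: int = 0
    channels: list = field(default_factory=list)
    max_tries_per_cell: int = 500
    # minimum clearance between cells; ~2 psf_sigma so PSF-blurred
    # neighbors stay separable by thresholding
    placement_margin_px: int = 3

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        kind, *params = self.length_dist
        if kind == "uniform":
            lo, hi = params
            if not (0 < lo <= hi):
                raise ValueError("cell length support must be positive")
        elif kind == "normal":
            mu, sd = params
            if mu <= 0 or sd < 0:
                raise ValueError("cell length mean must be positive")
        else:
            raise ValueError(f"unknown length distribution {kind!r}")
        self.channels = [
            c if isinstance(c, ChannelSpec) else ChannelSpec(**c) for c in self.channels
        ]

    # -- config echo ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_shape"] = list(self.field_shape)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["field_shape"] = tuple(d.get("field_shape", (1024, 1024)))
        return cls(**d)


@dataclass
class GroundTruthCell:
    """Per-cell ground truth emitted by the generator.

    ``pole_a``/``pole_b`` are the outer tips of the spherocylinder in
    subpixel (row, col) coordinates; ``length_um`` is the tip-to-tip
    distance times the pixel size.  Axial positions and intervals are
    fractions of that length measured from ``pole_a``.
    """

    cell_id: int
    pole_a: tuple  # (row, col), px
    pole_b: tuple
    length_um: float
    width_um: float
    focus_positions: dict = field(default_factory=dict)  # channel -> [s, ...]
    patch_intervals: dict = field(default_factory=dict)  # channel -> [(s0, s1), ...]
    nucleoid_interval: dict = field(default_factory=dict)  # channel -> (s0, s1)
    dna_content: float = 1.0  # relative units

    def axis_unit(self) -> np.ndarray:
        v = np.asarray(self.pole_b, float) - np.asarray(self.pole_a, float)
        return v / np.hypot(*v)

    def focus_xy(self, channel: str) -> np.ndarray:
        """(row, col) px coordinates of the channel's true foci."""
        a = np.asarray(self.pole_a, float)
        b = np.asarray(self.pole_b, float)
        ss = np.asarray(self.focus_positions.get(channel, []), float)
        return a[None, :] + ss[:, None] * (b - a)[None, :]


# ---------------------------------------------------------------------------
# population sampling


def _sample_length(cfg: SimConfig, rng: np.random.Generator) -> float:
    kind, *p = cfg.length_dist
    if kind == "uniform":
        return float(rng.uniform(p[0], p[1]))
    mu, sd = p
    for _ in range(1000):
        val = rng.normal(mu, sd)
        if val > 0:
            return float(val)
    raise ValueError("length distribution support not positive")


def _spherocylinder_mask(pole_a, pole_b, radius_px, shape):
    """Boolean mask of points within radius_px of the inner axis segment.

    The inner segment runs between the poles pulled in by the cap radius,
    so the tip-to-tip extent equals the pole separation.
    """
    a = np.asarray(pole_a, float)
    b = np.asarray(pole_b, float)
    u = (b - a) / np.hypot(*(b - a))
    ia, ib = a + radius_px * u, b - radius_px * u
    lo = np.floor(np.minimum(a, b) - radius_px - 1).astype(int)
    hi = np.ceil(np.maximum(a, b) + radius_px + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, shape)
    if np.any(hi <= lo):
        return None, None
    rr, cc = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
    pts = np.stack([rr, cc], axis=-1).astype(float)
    seg = ib - ia
    seg_len2 = seg @ seg
    t = np.clip(((pts - ia) @ seg) / seg_len2, 0.0, 1.0) if seg_len2 > 0 else 0.0
    closest = ia + np.atleast_3d(t) * seg if seg_len2 > 0 else ia
    d2 = ((pts - closest) ** 2).sum(axis=-1)
    box_mask = d2 <= radius_px**2
    return box_mask, (slice(lo[0], hi[0]), slice(lo[1], hi[1]))


def _cell_fits(pole_a, pole_b, radius_px, shape) -> bool:
    for p in (pole_a, pole_b):
        if not (radius_px + 1 <= p[0] <= shape[0] - radius_px - 2):
            return False
        if not (radius_px + 1 <= p[1] <= shape[1] - radius_px - 2):
            return False
    return True


def sample_population(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[GroundTruthCell]:
    """Draw cell geometries and per-channel signal truth for one field.

    Cells are placed by rejection sampling: centers uniform over the
    field, orientation uniform on [0, pi), rejected on overlap with any
    previously placed cell after a 1-px dilation margin.  Raises
    :class:`PlacementError` if a cell cannot be placed within
    ``cfg.max_tries_per_cell`` attempts.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    radius_px = 0.5 * cfg.cell_width_um / cfg.pixel_size
    occupied = np.zeros(cfg.field_shape, dtype=bool)
    truths: list[GroundTruthCell] = []

    for cell_id in range(1, cfg.n_cells + 1):
        length_um = _sample_length(cfg, rng)
        half_px = 0.5 * length_um / cfg.pixel_size
        placed = False
        for _ in range(cfg.max_tries_per_cell):
            center = rng.uniform([0, 0], cfg.field_shape)
            theta = rng.uniform(0.0, np.pi)
            u = np.array([np.sin(theta), np.cos(theta)])
            pole_a = center - half_px * u
            pole_b = center + half_px * u
            if not _cell_fits(pole_a, pole_b, radius_px, cfg.field_shape):
                continue
            m, box = _spherocylinder_mask(pole_a, pole_b, radius_px, cfg.field_shape)
            if m is None or not m.any():
                continue
            dil = ndimage.binary_dilation(m, iterations=cfg.placement_margin_px)
            if (occupied[box] & dil).any():
                continue
            occupied[box] |= m
            truths.append(_make_truth(cell_id, pole_a, pole_b, length_um, cfg, rng))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {cell_id} after {cfg.max_tries_per_cell} tries; "
                "field too small for n_cells"
            )
    return truths


def _make_truth(cell_id, pole_a, pole_b, length_um, cfg, rng) -> GroundTruthCell:
    # deterministic pole ordering mirrors the geometry module
    pa = (float(pole_a[0]), float(pole_a[1]))
    pb = (float(pole_b[0]), float(pole_b[1]))
    if pa > pb:
        pa, pb = pb, pa
    gt = GroundTruthCell(
        cell_id=cell_id,
        pole_a=pa,
        pole_b=pb,
        length_um=length_um,
        width_um=cfg.cell_width_um,
    )
    # extended signals first so focus rules can reference the nucleoid
    for ch in cfg.channels:
        if ch.kind == "nucleoid":
            frac = ch.nucleoid_fraction
            c = 0.5 + ch.center_offset
            s0 = max(0.0, c - frac / 2)
            s1 = min(1.0, c + frac / 2)
            gt.nucleoid_interval[ch.name] = (s0, s1)
            mult = float(rng.choice(ch.content_values, p=ch.content_probs))
            if ch.content_cv > 0:
                mult *= max(0.05, 1.0 + rng.normal(0.0, ch.content_cv))
            gt.dna_content = mult
        elif ch.kind == "patch":
            gt.patch_intervals[ch.name] = _sample_patches(ch, length_um, rng)
    for ch in cfg.channels:
        if ch.kind == "foci":
            gt.focus_positions[ch.name] = _sample_foci(ch, gt, rng)
    return gt


def _patch_frac(ch: ChannelSpec, length_um: float, rng) -> float:
    pl = ch.patch_length_um
    lo, hi = (pl, pl) if np.isscalar(pl) else pl
    return min(1.0, float(rng.uniform(lo, hi)) / length_um)


def _sample_patches(ch: ChannelSpec, length_um: float, rng) -> list:
    if ch.polarity == "unipolar":
        f = _patch_frac(ch, length_um, rng)
        # random pole: subpolar patches occur at either cell end
        return [(0.0, f)] if rng.random() < 0.5 else [(1.0 - f, 1.0)]
    if ch.polarity == "bipolar":
        fa = _patch_frac(ch, length_um, rng)
        fb = _patch_frac(ch, length_um, rng)
        ivs = [(0.0, fa), (1.0 - fb, 1.0)]
        if ivs[0][1] >= ivs[1][0]:  # patches meet in a short cell
            return [(0.0, 1.0)]
        return ivs
    f = _patch_frac(ch, length_um, rng)
    return [(max(0.0, 0.5 - f / 2), min(1.0, 0.5 + f / 2))]


def _sample_foci(ch: ChannelSpec, gt: GroundTruthCell, rng) -> list:
    counts = sorted(int(k) for k in ch.count_probs)
    probs = np.array([ch.count_probs[k] for k in counts], float)
    n = int(rng.choice(counts, p=probs / probs.sum()))
    if n == 0:
        return []
    if ch.rule == "uniform_over_nucleoid":
        if gt.nucleoid_interval:
            s0, s1 = next(iter(gt.nucleoid_interval.values()))
        else:
            s0, s1 = 0.25, 0.75  # central default when no nucleoid channel
        return sorted(float(rng.uniform(s0, s1)) for _ in range(n))
    if ch.rule == "symmetric_pair" and n == 2:
        u = float(rng.uniform(ch.f_lo, ch.f_hi))
        return [u, 1.0 - u]
    # polar_band (and symmetric_pair fallback for n != 2): each focus a
    # band draw from its nearest pole; 2-focus cells use opposite poles
    ss = []
    for i in range(n):
        u = float(rng.uniform(ch.f_lo, ch.f_hi))
        if n >= 2 and i < 2:
            near_a = i == 0
        else:
            near_a = rng.random() < 0.5
        ss.append(u if near_a else 1.0 - u)
    return sorted(ss)


# ---------------------------------------------------------------------------
# rendering


def _axial_coverage(ss, s0, s1, length_px):
    """Fraction of each pixel's 1-px axial extent inside [s0, s1].

    Partial-coverage rasterization keeps the rendered interval edges at
    their true sub-pixel positions instead of snapping to pixel centers.
    """
    half = 0.5 / length_px
    return np.clip(
        (np.minimum(ss + half, s1) - np.maximum(ss - half, s0)) * length_px, 0.0, 1.0
    )


def _render_gaussian_spot(img, center, sigma, mass):
    """Add a pixel-integrated 2D Gaussian of total `mass` photons."""
    r0, c0 = center
    w = int(np.ceil(6 * sigma))
    rlo, rhi = max(0, int(r0) - w), min(img.shape[0], int(r0) + w + 1)
    clo, chi = max(0, int(c0) - w), min(img.shape[1], int(c0) + w + 1)
    if rhi <= rlo or chi <= clo:
        return
    rr = np.arange(rlo, rhi)
    cc = np.arange(clo, chi)
    den = sigma * np.sqrt(2.0)
    fr = 0.5 * (erf((rr + 0.5 - r0) / den) - erf((rr - 0.5 - r0) / den))
    fc = 0.5 * (erf((cc + 0.5 - c0) / den) - erf((cc - 0.5 - c0) / den))
    img[rlo:rhi, clo:chi] += mass * np.outer(fr, fc)


def render_field(
    truths: list[GroundTruthCell],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Render (channels, rows, cols) photon image and uint16 label mask.

    Extended sources are rasterized at the configured photons/px over
    their footprint and blurred with the PSF; foci are added as
    pixel-integrated Gaussians carrying their full amplitude.  The image
    is then Poisson-sampled over (signal + background) and Gaussian read
    noise is added.  Output is float64 photons (may dip below zero with
    read noise); :func:`write_field` quantizes to uint16.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.field_shape)
    radius_px = 0.5 * cfg.cell_width_um / cfg.pixel_size

    labels = np.zeros(shape, dtype=np.uint16)
    cell_masks = {}
    cell_s = {}
    for gt in truths:
        m, box = _spherocylinder_mask(gt.pole_a, gt.pole_b, radius_px, shape)
        if m is None or not m.any():
            raise ValueError(f"cell {gt.cell_id} lies outside the field")
        if not _cell_fits(gt.pole_a, gt.pole_b, radius_px, shape):
            raise ValueError(f"cell {gt.cell_id} lies outside the field")
        labels[box][m] = gt.cell_id
        cell_masks[gt.cell_id] = (m, box)
        # axial fraction of every footprint pixel, for interval rasterization
        a = np.asarray(gt.pole_a, float)
        u = gt.axis_unit()
        rr, cc = np.nonzero(m)
        pts = np.stack([rr + box[0].start, cc + box[1].start], axis=-1).astype(float)
        length_px = gt.length_um / cfg.pixel_size
        cell_s[gt.cell_id] = np.clip(((pts - a) @ u) / length_px, 0.0, 1.0)

    channels = np.zeros((len(cfg.channels),) + shape, dtype=float)
    for ci, ch in enumerate(cfg.channels):
        ideal = np.zeros(shape, dtype=float)
        for gt in truths:
            m, box = cell_masks[gt.cell_id]
            ss = cell_s[gt.cell_id]
            rr, cc = np.nonzero(m)
            rr = rr + box[0].start
            cc = cc + box[1].start
            length_px = gt.length_um / cfg.pixel_size
            if ch.kind == "uniform":
                ideal[rr, cc] += ch.amplitude
            elif ch.kind == "patch":
                for s0, s1 in gt.patch_intervals.get(ch.name, []):
                    w = _axial_coverage(ss, s0, s1, length_px)
                    ideal[rr, cc] += ch.amplitude * w
            elif ch.kind == "nucleoid":
                iv = gt.nucleoid_interval.get(ch.name)
                if iv is not None:
                    w = _axial_coverage(ss, iv[0], iv[1], length_px)
                    ideal[rr, cc] += ch.amplitude * gt.dna_content * w
        blurred = ndimage.gaussian_filter(ideal, cfg.psf_sigma, mode="constant")
        if ch.kind == "foci":
            for gt in truths:
                for center in gt.focus_xy(ch.name):
                    _render_gaussian_spot(blurred, center, cfg.psf_sigma, ch.amplitude)
        expected = blurred + cfg.background
        noisy = rng.poisson(np.maximum(expected, 0.0)).astype(float)
        if cfg.read_noise_sd > 0:
            noisy += rng.normal(0.0, cfg.read_noise_sd, size=shape)
        channels[ci] = noisy
    return channels, labels


def simulate_field(cfg: SimConfig):
    """Sample a population and render it with one generator seeded from cfg.

    Returns ``(truths, channels, labels)``; bit-identical for identical
    (config, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    truths = sample_population(cfg, rng)
    channels, labels = render_field(truths, cfg, rng)
    return truths, channels, labels


# ---------------------------------------------------------------------------
# ground-truth I/O


def write_truth(truths: list[GroundTruthCell], path) -> None:
    """Write one CSV row per cell; round-trips losslessly via read_truth."""
    if not truths:
        raise ValueError("write_truth: empty truth list")
    rows = []
    for gt in truths:
        rows.append(
            {
                "cell_id": gt.cell_id,
                "pole_a_row": repr(gt.pole_a[0]),
                "pole_a_col": repr(gt.pole_a[1]),
                "pole_b_row": repr(gt.pole_b[0]),
                "pole_b_col": repr(gt.pole_b[1]),
                "length_um": repr(gt.length_um),
                "width_um": repr(gt.width_um),
                "focus_positions": json.dumps(gt.focus_positions),
                "patch_intervals": json.dumps(gt.patch_intervals),
                "nucleoid_interval": json.dumps(gt.nucleoid_interval),
                "dna_content": repr(gt.dna_content),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth(path) -> list[GroundTruthCell]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, r in df.iterrows():
        out.append(
            GroundTruthCell(
                cell_id=int(r.cell_id),
                pole_a=(float(r.pole_a_row), float(r.pole_a_col)),
                pole_b=(float(r.pole_b_row), float(r.pole_b_col)),
                length_um=float(r.length_um),
                width_um=float(r.width_um),
                focus_positions={k: list(v) for k, v in json.loads(r.focus_positions).items()},
                patch_intervals={
                    k: [tuple(iv) for iv in v]
                    for k, v in json.loads(r.patch_intervals).items()
                },
                nucleoid_interval={
                    k: tuple(v) for k, v in json.loads(r.nucleoid_interval).items()
                },
                dna_content=float(r.dna_content),
            )
        )
    return out


def write_field(outdir, channels, labels, cfg: SimConfig, truths=None) -> None:
    """Write channel TIFF (uint16), label TIFF, config echo, truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img16 = np.clip(np.rint(channels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(outdir / "field.tif", img16)
    tifffile.imwrite(outdir / "labels.tif", labels.astype(np.uint16))
    cfg.to_yaml(outdir / "config.yaml")
    if truths:
        write_truth(truths, outdir / "truth.csv")
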
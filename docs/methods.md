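# Methods

This note documents the models, conventions, and design choices behind
each analysis stage, in the spirit of a methods supplement: what is
computed, under which assumptions, with which defaults, and what the
synthetic validation does and does not demonstrate.

## Synthetic fields

Cells are straight spherocylinders: an axis segment of half-width
*w*/2 = 0.35 µm with hemispherical caps, so the tip-to-tip pole
distance equals the nominal cell length. Curvature is not modeled —
every downstream metric is axial, and straight rods keep the ground
truth exact. Defaults emulate 100×/1.4 NA widefield imaging of
*M. xanthus*: pixel size 0.065 µm, PSF sigma 1.3 px, cell width
0.7 µm, lengths uniform on 3–12 µm. No acquisition parameters are
available for the original data, so these are plausible-instrument
choices, not calibrated ones.

Placement is rejection sampling: centers uniform over the field,
orientations uniform on [0, π), candidates rejected when their
footprint, dilated by `placement_margin_px` (default 3 px ≈ 2 PSF
sigma), touches an already placed cell. A 1-px margin is geometrically
sufficient for disjoint masks but lets PSF-blurred neighbors fuse into
one connected component, which would defeat threshold segmentation of
an otherwise ideal image; the 3-px default keeps adjacent cells
resolvable. Placement failure after `max_tries_per_cell` attempts
raises an error identifying the field as too small.

Per channel, one signal kind is rendered:

- **foci** — 0–3 point emitters per cell. Placement rules:
  `polar_band(f_lo, f_hi)` draws each focus's fractional distance from
  its nearest pole uniformly from the band (two-focus cells use
  opposite poles), emulating origin complexes positioned 15–25 % of
  cell length from the poles; `symmetric_pair` draws one band value
  *u* per cell and places foci at *s* = *u* and 1 − *u*, the fully
  segregated wild-type arrangement (true S = 100 %);
  `uniform_over_nucleoid` scatters foci uniformly over the cell's
  nucleoid interval (central half of the cell when no nucleoid channel
  is configured), emulating delocalized origins.
- **patch** — uniform emission over an axial interval: `unipolar` (a
  1–2 µm interval at a randomly chosen pole), `bipolar` (one at each
  pole), or `midcell`. Interval lengths are drawn uniformly from the
  configured range; in cells shorter than the two bipolar patches the
  patches merge into a full-length interval.
- **nucleoid** — uniform emission over a centered interval covering a
  configurable fraction of cell length (default 0.5), scaled by a
  per-cell DNA-content multiplier (choice distribution × optional
  Gaussian CV) to emulate content heterogeneity.
- **uniform** — constant emission over the footprint.

Rendering: extended sources are rasterized at their configured
photons/px with partial-coverage (anti-aliased) axial edges — snapping
interval edges to pixel centers would systematically widen every
extended signal by ~1 px — then blurred with a Gaussian PSF. Foci are
added as pixel-integrated Gaussians (error-function quadrature) whose
total mass is the configured amplitude, so photon conservation holds to
the kernel-truncation tolerance. A constant background is added, each
pixel is Poisson-sampled, and Gaussian read noise (default SD 2
photons) is added. SNR is defined as peak signal over background shot
noise, peak/√background; `focus_amplitude_for_snr` and
`extended_amplitude_for_snr` convert a target SNR into amplitudes.

One seeded generator (`numpy.random.default_rng(seed)`) drives
sampling and rendering in a fixed documented order, so identical
configurations give bit-identical truths and images.

## Geometry

Each labeled component is reduced to a straight-axis frame: the axis is
the first principal component of the pixel coordinates, the poles sit
at the extreme pixel-center projections onto it, and length is the
pole separation times the pixel size (a 100-px-long horizontal
rectangle therefore measures 99 px between pole centers). Pole
ordering is deterministic (smaller row, ties by column) so results are
reproducible before any biological orientation rule is applied.
Components under 5 px are skipped; near-isotropic components (square
footprints) are flagged `low_anisotropy` since their principal axis is
degenerate. The axial coordinate of any point is its projection onto
the axis as a fraction *s* ∈ [0, 1] of length, clamped at the poles.
On synthetic masks, measured lengths recover tip-to-tip truth within
2 px: the extreme pixel centers of a rasterized cap fall slightly
inside the analytic tips.

A principal-axis frame rather than a skeleton/medial axis is used
because the supported cells are straight; curved-cell axes are an
extension point, not implemented.

## Profiles and demographs

A cell's profile assigns every mask pixel to one of `n_bins` (default
100) equal bins of *s* and averages pixel values per bin; every in-mask
pixel contributes to exactly one bin. Empty bins are filled by linear
interpolation between neighbors (nearest-value at the profile ends)
and flagged; a cell with fewer than `n_bins`/2 non-empty bins is
rejected as too small for the requested resolution.

Demographs stack per-cell profiles as rows sorted by cell length,
shortest first, on a shared normalized-length axis; each row is min–max
normalized to [0, 1] (constant rows map to 0), with raw intensities
available by flag. An absolute-length, midcell-centered rendering is a
display option. Orientation uses the brighter-half-first rule —
reverse the profile when the integrated intensity of its second half
exceeds the first (exact ties unreversed) — either per channel or
driven by a reference channel so that all channels of a cell share one
flip. The original demograph convention for normalization and
orientation is not recorded anywhere authoritative; these rules are
documented choices, not inferences.

## Focus detection and segregation metrics

Detection: difference-of-Gaussians bandpass with sigmas
(psf_sigma, 2·psf_sigma); per-cell candidates are local maxima inside
the mask above median + k_sd × robust SD (1.4826 × MAD) of the in-mask
DoG response, k_sd = 5; candidates closer than 2·psf_sigma are merged
keeping the brighter. Each candidate is refined by least-squares
fitting an isotropic 2D Gaussian with constant offset in a 7×7 window
of the raw image; fits with non-positive amplitude, centers leaving the
window, or sigma outside [0.5, 2]·psf_sigma are rejected (a failed fit
drops the candidate, never the cell). A focus belongs to the cell
whose mask contains its fitted center; centers on background are
dropped. On synthetic populations at SNR 10 with separations
≥ 4·psf_sigma, recall and precision exceed 0.95 and axial RMSE is
below 0.5 px (≈ 0.3 px typical).

Metrics per cell: with foci ordered by *s*, the left focus pairs with
pole a and the right with pole b — this left/right convention (rather
than nearest-pole pairing) guarantees *D* ≥ 0 and S ≤ 100 even when
both foci lie in the same cell half, a case whose original handling is
unrecorded. After relabeling so *D₁* ≤ *D₂*,
S = 100·*D*/(*D* + *D₂* − *D₁*) and D_min = 100·*D₁*/*L*. Conventions:
one focus → S = 0 by definition, D_min from the nearest pole; no
foci → both undefined; three or more foci → S undefined (such cells
are excluded from symmetry analyses), D_min from the focus nearest a
pole; exactly coincident pairs (*D* = 0) → S undefined and flagged,
since a coincident pair carries no symmetry information and a literal
evaluation would return a misleading "defined" S = 0 or 0/0. S and
D_min are invariant under mirror reflection (*s* → 1 − *s*) and under
uniform rescaling of the cell.

## Axial extents

Intervals are called on a profile at threshold
background + α·(max − background), α = 0.3 by default; runs separated
by ≤ 2 bins are merged, runs shorter than 3 bins are dropped, and
surviving interval ends are refined by linearly interpolating the
threshold crossing between bin centers (runs touching a profile end
extend to *s* = 0 or 1). The per-field background is the mode of
out-of-mask pixel values, which is robust to cell density.

Because a relative threshold on a PSF-blurred step edge crosses
|Φ⁻¹(α)|·σ ≈ 0.52 σ *outside* the true edge, raw extents overestimate
by ~1.4 px per interval — for 3-µm cells this alone nearly exhausts a
±0.03 fractional-error budget. When the PSF width is supplied
(`psf_sigma_s`, the PSF sigma as a fraction of cell length), each
interior interval end is pulled inward by that displacement, the
standard correction for threshold-based sizing under known blur; ends
at the cell poles are left untouched. The correction is off by default
so sharp-edged or unknown-PSF profiles are measured exactly as the
threshold rule states. Absolute fractions inevitably depend on α;
cross-condition comparisons at fixed α are the supported use.

Polarity classes: an interval is polar when its pole-proximal end
reaches within 0.15 of a pole; two polar intervals at opposite poles →
bipolar, one → unipolar, a single interval reaching both poles spans
the cell and is called diffuse; a non-polar interval overlapping
*s* ∈ [0.4, 0.6] → midcell; above-threshold signal without a
qualifying interval → diffuse; no signal → none. The 0.15/0.85 and
0.4–0.6 bands match subpolar patches of 1–2 µm in ~7 µm cells and are
configurable at module level.

Focus–nucleoid relations report the signed distance of each focus to
the nearest nucleoid edge in units of nucleoid length (negative
outside); multi-interval nucleoids are collapsed to their union span
and flagged. Integrated cell intensity (Σ of background-subtracted
pixels over the mask, floored at 0) emulates a DNA-content readout;
histograms of these values reproduce content bimodality (1× vs 2×)
when present.

## Colocalization

PCC is computed per cell over mask pixels (zero-variance channels give
an undefined, flagged value) and summarized as mean ± sample SD
(n − 1) over cells with defined values. Per-cell masks are the default
because whole-field PCC is dominated by the background/foreground
split; whole-field computation remains available by passing a field
mask. No Costes randomization or Manders coefficients — plain PCC is
the quantity of interest here.

## Population statistics

Box-plot summaries report median, quartiles, and the 5th/95th
percentiles (whisker convention), with percentiles by linear
interpolation between order statistics. Group comparisons use the
two-sided Mann–Whitney U test: exact null distribution when both
groups have ≤ 10 observations and the pooled sample is tie-free,
otherwise the normal approximation with tie and continuity
corrections; the method used is recorded in the result. The default
significance level is 0.001. No multiple-testing correction is
applied; the report states the number of comparisons so users can
adjust. Symmetry-coefficient comparisons are restricted to cells with
exactly two foci — the only population for which S is informative.

## Validation scope and problem sizes

The synthetic validation establishes parameter recovery under the
generator's assumptions: straight cells, isotropic Gaussian PSF,
Poisson + Gaussian noise, uniform-emission extended sources, and
well-separated foci. Real images add cell curvature, focal drift,
uneven illumination, autofluorescence, and touching cells — so passing
recovery tests bounds algorithmic error, not total experimental error.
Recovery suites use populations of 150–200 cells simulated as several
1024–1100 px tiles of ≤ 50 cells each (rejection-sampling placement
stays cheap at that density); property suites use 10⁴ random draws.
Detection recovery is assessed at SNR 10 with inter-focus separations
≥ 4 PSF sigma; closer pairs below the Rayleigh-like merge distance are
deliberately out of scope for the single-emitter fit.

## Known limitations

- No curved-cell axes, no 3D PSFs, no time-lapse/kymograph support.
- Segmentation is a convenience Otsu thresholder for synthetic fields;
  real-image segmentation must be supplied as a label mask.
- The single-Gaussian fit merges foci closer than ~2 PSF sigma.
- Absolute extent fractions depend on the threshold α and, without the
  PSF correction, carry a blur-dependent positive bias.
- DNA-content emulation is an integrated-intensity proxy, not a
  flow-cytometry model.
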
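# rodquant

Quantitative fluorescence-image analysis for rod-shaped bacteria:
demographs, sub-pixel focus detection, chromosome-segregation symmetry
metrics, axial signal extents, within-cell Pearson colocalization, and
population statistics — plus a ground-truth-emitting synthetic field
generator that lets every stage be validated by parameter recovery.

## Who it is for

Microbiologists quantifying single-cell fluorescence patterns in rods
such as *Myxococcus xanthus*: where do ParB·*parS* origin complexes sit
relative to the poles, how long are subpolar bactofilin scaffolds, how
far does the nucleoid extend, and do two labeled proteins colocalize?
The pipeline consumes multi-channel TIFF images with an integer label
mask per cell (segmentation of real DIC/phase images is out of scope;
a simple Otsu segmenter is included for synthetic fields) and emits
tidy CSV tables, demograph images, and statistical reports.

## The core statistics

For a cell of length *L* containing two fluorescent foci, let *D₁* and
*D₂* be the distances of the two foci from their respective poles
(relabeled so *D₁* ≤ *D₂*) and *D* = *L* − *D₁* − *D₂* the inter-focus
distance. The package computes per cell:

- **Segregation symmetry** S = 100 · *D* / (*D* + *D₂* − *D₁*) %, equal
  to 100 % for a perfectly symmetric pair and smaller the more
  one-sided the arrangement; for a cell with a single focus, S = 0 % by
  definition.
- **Pole proximity** D_min = 100 · *D₁* / *L* %, the smallest
  focus-to-pole distance normalized to cell length (∈ [0, 50]).

Foci are localized to sub-pixel precision with a
difference-of-Gaussians candidate step followed by a 2D Gaussian fit.
Axial extents (nucleoid, patches) are called on per-cell line profiles
with a relative threshold (α = 0.3 of the background-subtracted
maximum) and an optional correction for the known PSF-blur edge
displacement. Colocalization is the Pearson correlation coefficient
over the pixels of each cell mask, summarized as mean ± SD over cells.
Groups are compared with two-sided Mann–Whitney rank-sum tests
(α = 0.001) and box-plot summaries whose whiskers span the 5th–95th
percentiles.

## Worked example

Simulate a wild-type-like population (symmetric ParB-like focus pairs
drawn 15–25 % of cell length from the poles, SNR 10, plus a DAPI-like
nucleoid channel), then run detection and metrics:

```python
import rodquant as rq

amp = rq.focus_amplitude_for_snr(10, 100.0, 1.3)
cfg = rq.SimConfig(
    n_cells=40, field_shape=(1100, 1100), seed=7,
    channels=[
        dict(name="parb", kind="foci", rule="symmetric_pair",
             count_probs={2: 1.0}, amplitude=amp),
        dict(name="dapi", kind="nucleoid",
             amplitude=rq.extended_amplitude_for_snr(10, 100.0)),
    ],
)
truths, channels, labels = rq.simulate_field(cfg)
geoms, foci, metrics = rq.measure_segregation(channels, labels, cfg, "parb")
df, tally = rq.population_metrics(metrics)
two = df[df.n_foci == 2]
print(f"median S = {two.S.median():.1f}%   median D_min = {two.D_min.median():.1f}%")

summ = rq.summarize_pcc(rq.pcc_per_cell(channels[0], channels[1], labels))
print(f"PCC parb:dapi = {summ.mean:.2f} +/- {summ.sd:.2f} (n = {summ.n_cells})")
```

prints

```
median S = 99.7%   median D_min = 20.2%
PCC parb:dapi = -0.13 +/- 0.06 (n = 40)
```

All 40 cells are detected with two foci each. The median S of 99.7 %
reflects the generatively symmetric pairs (S = 100 % in truth; the
residual is sub-pixel localization error), and the median D_min of
20.2 % falls inside the generative 15–25 % polar band. The focus
channel and the centrally placed nucleoid are spatially anti-correlated
(foci sit at the nucleoid edges), hence the slightly negative PCC.

The same stages are available from the shell:

```sh
rodquant simulate --config sim.yaml --out field/
rodquant analyze --image field/field.tif --labels field/labels.tif \
    --config field/config.yaml --foci-channel parb --out results/
rodquant demograph --image field/field.tif --labels field/labels.tif \
    --config field/config.yaml --channel dapi --out demo/
rodquant coloc  --image field/field.tif --labels field/labels.tif \
    --config field/config.yaml --channels parb,dapi --out coloc/
rodquant report --metrics metrics.csv --group-col strain \
    --reference WT --metric S --out report/
```

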
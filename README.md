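# catsigma

Subcellular calcium-release dyssynchrony metrics and sarcoplasmic-reticulum
(SR) flux deconvolution for confocal line-scan recordings of cardiomyocytes.

## The problem

In a healthy ventricular myocyte, t-tubules bring L-type calcium channels
within nanometres of the SR ryanodine receptors, so every point along the
cell releases calcium almost simultaneously after an action potential. In
failing hearts the t-tubule network degrades, local release becomes
staggered, and the whole-cell calcium transient (CaT) shrinks and slows.
Quantifying *how* staggered the release is — and whether the stagger is a
fixed structural property of the cell or a beat-to-beat fluctuation — needs
analysis at the level of single pixels of a line-scan image (position ×
time, ~0.4 µm × ~2 ms per sample).

`catsigma` implements that analysis for Fluo-4 F/F₀ line-scans, plus the
six-epoch solution-switching protocol used to deconvolve the calcium fluxes
(RyR leak, SR content, SERCA, NCX, PMCA, fractional release) from a
whole-cell trace, and a ground-truthed synthetic-data generator that makes
every stage testable without any microscope.

## The statistics

For every pixel *x* the local CaT (locCaT) is measured inside one beat
frame: time-to-peak *t(x)* (from the global CaT onset), 66 %-recovery decay
time, and amplitude ΔF/F₀. Dyssynchrony is dispersion of these local time
courses:

- **spatial-σ** = population SD of *t(x)* across pixels, one beat — total
  release dyssynchrony;
- **temporal-σ** = mean over pixels of each pixel's SD of *t(x)* across k
  consecutive beats (k = 5, c₄-debiased) — beat-to-beat dyssynchrony;
- **structural-σ** = spatial-σ of the frame obtained by averaging the k
  stimulus-aligned beat frames, which cancels beat-to-beat jitter —
  dyssynchrony attributable to fixed structure (e.g. t-tubule loss);
- **synchrony efficiency** = global CaT amplitude / mean locCaT amplitude;
  1 for perfectly synchronous release, smaller when local transients are
  staggered so their spatial mean peaks below the local peaks.

Under the generator's additive latency model (fixed structural offset +
per-beat jitter) these satisfy spatial-σ² ≈ σ²_struct + σ²_beat,
temporal-σ ≈ σ_beat and structural-σ → σ_struct, which is exactly what the
test suite verifies by parameter recovery.

The flux protocol measures, per epoch: twitch CaT parameters (NT, paced);
the diastolic level drop on tetracaine in 0Na⁺/0Ca²⁺ (RyR leak); the
caffeine-transient amplitude (SR content); mono-exponential τ of the
caffeine decay (SERCA, literal mode, or the pathway-subtraction rate
k_SERCA = 1/τ_twitch − 1/τ_caffeine in corrected mode); the linear slope of
the caffeine + 0Na⁺/0Ca²⁺ decay (PMCA); and the decay acceleration on
restoring Na⁺/Ca²⁺ (k_NCX = 1/τ_f − 1/τ_e).

## Worked example

Simulate a healthy-like cell and a structurally dyssynchronous cell
(structural SD 20 ms, 25 % orphaned pixels), then analyse both:

```bash
catsigma simulate linescan --seed 7 --out cell01
echo '{"structural_sd": 20.0, "orphan_fraction": 0.25, "seed": 7}' > ko_cfg.json
catsigma simulate linescan --config ko_cfg.json --out cell02
catsigma dyssynchrony --input cell01/linescan.tif --out cell01_sigma.json
catsigma dyssynchrony --input cell02/linescan.tif --out cell02_sigma.json
```

The reference cell (σ_struct = 8 ms, σ_beat = 6 ms) reports

```
spatial_sigma_rise           8.76778
temporal_sigma_rise          5.72575
structural_sigma_rise        7.13235
synchrony_efficiency         0.954097
```

while the dyssynchronous cell reports

```
spatial_sigma_rise           22.4844
temporal_sigma_rise          6.0227
structural_sigma_rise        21.0549
synchrony_efficiency         0.857992
```

— spatial-σ and structural-σ rise together (the extra dispersion is fixed,
not beat-to-beat: temporal-σ is unchanged) and synchrony efficiency drops,
the signature of structurally dyssynchronous release. Flux deconvolution on
a simulated protocol trace (true rates k_SERCA = 0.01, k_NCX = 0.003,
k_PMCA = 0.0005 ms⁻¹, SR content 3.0, release fraction 0.6):

```bash
catsigma simulate flux --seed 7 --out fluxdir
catsigma flux --trace fluxdir/flux_trace.csv --protocol fluxdir/protocol.json \
         --serca-mode corrected --out flux_result.json
```

```
cat_amplitude                1.80888
ryr_leak                     0.154409
sr_content                   2.98667
serca_rate                   0.0099666
ncx_rate                     0.00300487
fractional_release           0.605651
```

Batch analysis over a manifest CSV (`cell_id, animal_id, group,
input_path, …`) with `catsigma batch`, and `catsigma report` renders any
result JSON.

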
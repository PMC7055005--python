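# ricstools

Quantitative fluorescence-fluctuation and single-molecule image analysis
for studies of protein and mRNA dynamics in living tissue — raster image
correlation spectroscopy (RICS), two-colour cross-correlation RICS
(ccRICS) with its interaction index, fluorescence correlation spectroscopy
(FCS) model fitting, and an smFISH voxel-colocalization pipeline with a
pixel-shuffle permutation null.  A Brownian-dynamics simulator of
raster-scanned diffusing fluorophores, stationary-beam photon traces and
3D smFISH-like stacks provides ground-truth data, so every stage of the
pipeline is testable end to end without any experimental download.

Intended users: microscopists and quantitative biologists analysing
photon-counting confocal series (diffusion coefficients, binding
fractions), FCS traces, and multi-channel smFISH stacks (spot detection,
colocalization significance).

## The models

**RICS.**  A raster scan encodes time in space: adjacent pixels are
`tau_p` apart (µs), adjacent lines `tau_l` (ms).  The spatial correlation
of intensity fluctuations

```
G(xi, psi) = <dI(x,y) dI(x+xi, y+psi)> / <I>^2
```

is fitted with the single-component diffusion model

```
G(xi,psi) = offset + G0 · S(xi,psi) · (1 + 4·D·tau/w0^2)^-1 (1 + 4·D·tau/wz^2)^-1/2
tau = tau_p·|xi| + tau_l·|psi|,
S   = exp(−(dr^2 (xi^2+psi^2)/w0^2) / (1 + 4·D·tau/w0^2))
```

yielding the diffusion coefficient D (µm²/s) and amplitude `G0 = gamma/N`
(`gamma = 2^-3/2`).  An immobile fraction is removed beforehand by
moving-average subtraction; the beam waist `w0` is calibrated by fitting a
fast dye series with D fixed (40 µm²/s).

**ccRICS.**  For simultaneous two-channel acquisitions, the amplitude
ratio of the fitted cross-correlation to the reference channel's fitted
auto-correlation, `G_cc / G_ref`, is an interaction index proportional to
the fraction of reference molecules co-diffusing in complexes with the
partner channel.  Computed with a 10-frame moving average the index
captures stable complexes; a 40-frame window additionally retains
transient (dynamic) interactions.

**FCS.**  Temporal autocorrelation of binned photon-count traces, fitted
with the standard 3D diffusion model

```
G(t_c) = offset + sum_k A_k [1+(t_c/tau_xy_k)^a_k]^-1 [1+(t_c/tau_xy_k)^a_k / AR_k^2]^-1/2
```

(defaults: one species, anomaly exponent a = 1, axial ratio AR = 5), with
`D = w0^2 / (4·tau_xy)`.

**Colocalization.**  Chromatic-shift application, rolling-ball background
subtraction, Otsu or Rényi-entropy thresholding of the reporter channel,
3D Gaussian centroiding of single-molecule spots, voxel co-occupancy, and
an equal-pixel-count shuffle null with an add-one empirical p-value.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Simulate a raster scan of a slow cytosolic protein (D = 0.84 µm²/s, the
regime of large RNP-granule complexes) under a photon-counting acquisition
(20 nm pixels, 8.19 µs dwell, 4.92 ms line time, 50 frames), then recover
the coefficient:

```python
from ricstools import ScanConfig, SpeciesSpec
from ricstools.synthetic import simulate_raster_series
from ricstools.rics import moving_average_subtract, spatial_acf, fit_rics

scan = ScanConfig(frame_shape=(96, 96), n_frames=50)
species = SpeciesSpec(D=0.84, brightness=2.0, n_particles=568)
series = simulate_raster_series(species, scan, seed=7)[1]

detrended = moving_average_subtract(series, M=10)   # remove immobile fraction
acf = spatial_acf(detrended, max_lag=(20, 36))
fit = fit_rics(acf, scan)
print(f"fitted D = {fit.D:.3f} um^2/s (simulated 0.84)")
print(f"G0 = {fit.G0:.4f}  ->  N_apparent = {fit.N_apparent:.1f}")
print(f"chi2 = {fit.chi2:.5f}, converged = {fit.converged}")
```

prints

```
fitted D = 0.840 um^2/s (simulated 0.84)
G0 = 0.3016  ->  N_apparent = 1.2
chi2 = 0.01235, converged = True
```

The fitted D is the protein's apparent diffusion coefficient; `G0` is the
zero-lag correlation amplitude, whose inverse (times the shape factor
2^-3/2) is the apparent number of molecules in the focal volume — here a
dilute, bright sample with ~1 molecule in focus.

The same operations are available from the shell:

```bash
ricstools simulate rics --d 0.84 --n-particles 568 --brightness 2 --seed 7 --out sim/
ricstools rics fit --input sim/series_ch1.tif --ma 10 --out fit/
ricstools simulate smfish --n-spots 40 --coloc-fraction 0.3 --seed 3 --out fish/
ricstools coloc --input fish/stack.tif --n-shuffles 999 --seed 1 --out coloc/
```

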
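# Methods

This note records the models implemented in `ricstools`, the assumptions
behind them, the defaults that matter, and the choices made where the design
was genuinely open.

## Raster-scan simulation

The simulator emulates a confocal photon-counting acquisition of point
emitters diffusing in three dimensions.  Pixel (f, r, c) is acquired at
`t = f·frame_time + r·line_time + c·dwell_time`; defaults follow a typical
photon-counting RICS protocol (20 nm pixels, 8.19 µs dwell, 4.92 ms line
time, 256×256 pixels, 50 frames).  The expected count at a pixel is

```
E[k] = background + Σ_p  b_p · exp(−2(Δx² + Δy²)/w0² − 2 z_p²/wz²)
```

with `b_p` the per-dwell brightness at beam centre, and observed counts are
Poisson.  Detection is point-sampled at the pixel time rather than
integrated over the dwell; at the default geometry a particle moves a small
fraction of `w0` within one dwell even at 40 µm²/s, so the distinction is
negligible.

Particle motion is Brownian with per-axis increment variance `2 D Δt` on the
per-pixel clock.  Two equivalent routes exist:

* an explicit-path route (`simulate_brownian_paths` / `render_raster_scan`)
  that materialises every position, used for small problems and oracle
  tests;
* a streaming engine (`simulate_raster_series`) that advances all particles
  at line resolution and refines particles near the current scan line to
  the per-pixel clock with an exact Brownian-bridge construction
  (`X(t) = W(t) − (t/T)(W(T) − Δ)` for a free path `W` started at the line
  head).  Because bridge refinement is distributionally exact, the two
  routes sample the same law; the streaming engine renders only particles
  within 2.5·w0 laterally / 2.2·wz axially of the line (plus a drift margin
  of three bridge standard deviations), discarding contributions below
  ~4·10⁻⁶ of a particle's peak signal.

Boundaries are periodic over a box extending 3·w0 beyond the scanned field
laterally and 3·wz axially, which keeps the concentration stationary and
avoids edge-depletion artefacts in the ACF amplitude.  The beam waist is
never reported by the instrument protocol the simulator mirrors, so the
defaults `w0 = 0.25 µm`, `AR = wz/w0 = 5` (a typical one-photon confocal
volume) are used everywhere and recovered by the calibration fitter in
tests.

Stable molecular complexes are modelled as dual-labelled particles: one
trajectory rendered into both channels with independent brightnesses, i.e.
a rigid complex with zero intra-complex offset.  Kinetic binding is a
two-state Markov switch per particle with exact exponential waiting times;
state changes are applied at line granularity (the line time is orders of
magnitude shorter than any realistic 1/k), and a particle snaps onto its
partner's position when it binds and diffuses freely from its current
position when it releases.

Simulated concentrations default to ~2 molecules in the effective volume
`V_eff = π^{3/2} w0² wz` (≈ the 10 nM calibration-dye regime) and a
brightness of 1–2 counts per dwell at beam centre, i.e. a bright but
realistic photon-counting signal.

What the generator deliberately omits: photobleaching, triplet blinking,
detector afterpulsing and dead time, optical aberrations, cellular
autofluorescence structure, and motion other than free diffusion (no flow,
no anomalous diffusion in the raster simulator).  Passing recovery tests
therefore demonstrate correctness of the estimators and fitters under the
model's own assumptions, not robustness to every artefact of real tissue.

## RICS and ccRICS

The spatial correlation of a detrended series is estimated per frame as

```
G(ξ, ψ) = ⟨δI_A(x, y) · δI_B(x+ξ, y+ψ)⟩ / (⟨I_A⟩⟨I_B⟩),   δI = I − frame mean
```

via zero-padded FFT (no circular wrap), normalised by the exact number of
contributing pixel pairs at each lag, then averaged over frames.  The
estimator is tested for equality (≤ 1e-10) with a direct double-loop oracle.

Immobile and slowly drifting structure is removed before correlation by
moving-average subtraction: frame i becomes `I_i − MA_i + c`, with `MA_i`
the per-pixel mean over a centred window of exactly M frames, clamped at
the series ends (so `M = n_frames` degenerates to subtracting the global
per-pixel temporal mean), and `c` the scalar mean of the MA stack, which
preserves the overall mean intensity exactly.  Re-adding a per-pixel mean
map instead would reinsert the static structure the subtraction exists to
remove.

The single-component model fitted to the surface is

```
G(ξ,ψ) = offset + G0 · exp(−(δr²(ξ²+ψ²)/w0²)/(1+4Dτ/w0²))
                · (1+4Dτ/w0²)^−1 (1+4Dτ/wz²)^−1/2,   τ = τ_p|ξ| + τ_l|ψ|
```

with `N_apparent = γ/G0`, `γ = 2^{−3/2}`.  Fitting choices: trust-region
least squares (via lmfit) over (D, G0, offset), multistart from
D ∈ {0.1, 1, 10} µm²/s with the lowest χ² kept; the default window is
|ξ| ≤ 32, |ψ| ≤ 16 lags; the (0,0) point is excluded for auto-correlations
(uncorrelated shot noise lives only there) and kept for cross-correlations,
where detector noise is independent between channels.  Calibration fixes D
at the dye value (40 µm²/s by convention) and frees w0, with wz tied as
AR·w0.

The ccRICS interaction index is the ratio of *fitted* amplitudes
`G_cc / G_ref` (cross-surface over reference-channel auto-surface, each fit
with its own free D); fitted amplitudes rather than raw G(0,0) suppress
noise at the single point that matters most.  With equal channel
concentrations, a stable bound fraction f of reference molecules yields an
index of f; with unequal concentrations the index scales by the
concentration ratio, which is why the recovery conditions use matched
particle numbers.  A longer moving-average window (40 versus 10 frames)
retains more of the slowly varying correlation contributed by transiently
bound, near-immobile complexes, so the 40-frame index bounds the total
(stable + dynamic) interaction from above; this ordering is verified by a
paired sign test on kinetic-binding simulations.

## FCS

The temporal autocorrelation of a binned photon trace is the linear-lag
estimator `G(t_c) = ⟨δI(t) δI(t+t_c)⟩/⟨I⟩²` over all valid pairs,
normalised by the full-trace mean, with lag zero excluded (tested against a
double-loop oracle at 1e-12).  The fitted model is the standard one-photon
3D (anomalous) diffusion form

```
G(t_c) = offset + Σ_k A_k [1+(t_c/τxy_k)^{α_k}]^{−1} [1+(t_c/τxy_k)^{α_k}/AR_k²]^{−1/2}
```

with defaults α = 1 and AR = 5 fixed, and `D = w0²/(4 τxy)` using the
calibrated waist (never a silent default).

Two numerical corrections matter in practice and are implemented in
`fit_fcs`:

* **bin smearing** — correlating counts integrated over bins of width Δ
  measures the triangular-kernel average `∫(1−|u|/Δ) G(t+u) du / Δ`; the
  model is smeared accordingly when a bin width is supplied.  At 1 ms bins
  this is essential for fast species (τxy ≈ 1 ms for GFP at the default
  waist) and irrelevant for slow ones.
* **window refinement** — the power-law tail of G carries almost no
  diffusion information, but its correlated finite-trace noise (and the
  near-constant negative bias from mean normalisation and the fixed total
  particle number in a closed box) tilts long-window fits.  After an
  initial full-window fit, the fit is repeated restricted to lags within 5
  fitted diffusion times (iterated to stability, never below six lags),
  where the bias is flat and absorbed by the free offset.

FCS simulations default to 10 s traces, 1 ms bins with 5 Brownian substeps
per bin, 120 particles in the stationary-beam box and 10 counts per bin at
beam centre per molecule (≈ 10 kHz molecular brightness).

## smFISH colocalization

Pipeline order: chromatic-shift application (trilinear interpolation,
median fill; shift estimation itself is an input), per-slice rolling-ball
background subtraction of the reporter channel (scikit-image, default
radius 50 pixels, clipped at zero), automatic thresholding, 3D Gaussian
spot detection on the single-molecule channel, voxel co-occupancy, and a
pixel-shuffle permutation null.

Thresholding uses a 256-bin histogram over [min, max] (the Auto-Threshold
convention): Otsu maximises between-class variance; the Rényi-entropy
threshold maximises summed foreground/background Rényi entropies at orders
ρ→1, ρ=0.5 and ρ=2 and combines the three candidates with the Sahoo
weighting rule.

Spot detection band-passes with a Laplacian-of-Gaussian at the expected
sigma, takes local maxima above a robust-noise threshold (default 5 MAD of
the filtered image), and refines each candidate with a least-squares 3D
Gaussian fit (amplitude, centroid, per-axis σ, constant background) in a
±2σ window — small enough that a neighbouring spot rarely contaminates the
fit.  Fits with σ outside [0.5, 2]× expected are discarded; duplicates
within 1σ keep the lower-residual fit.  Coordinates are (z, y, x), 0-based,
with a continuous position p belonging to voxel `floor(p)` and voxel
centres at i+0.5.

The permutation null shuffles mask voxels uniformly over the analysis
region (default: the whole stack; a region mask restricts it), preserving
the above-threshold voxel count exactly in every shuffle, and recomputes
the co-occupancy; the empirical p-value uses the add-one correction
`(1 + #{null ≥ observed})/(1 + n)`.  A one-sample t-test of the null
percentages against the observed value is reported as a secondary
statistic for comparability with per-specimen t-testing.

Transcription foci are scored in single-transcript units: the unit is the
median integrated intensity (analytic Gaussian volume of the fit) of spots
outside the nuclear mask (≥ 20 required), and each nuclear focus is its
integrated intensity divided by the unit.

The stack generator places the planted colocalized spots inside granule
supports eroded laterally by one voxel and the rest outside the support
dilated by two voxels, so that thresholding uncertainty at granule edges
does not leak into the planted fraction; spot centres keep ≥ 5σ pairwise
separation by default.

## Quantification and statistics

Intensity quantification takes the median of small square regions (1×1 µm
by default) on an average-intensity z-projection and summarises regions by
their median.  The Stokes–Einstein fold prediction is `mass_ratio^{1/3}`
reported to two significant figures (3-fold mass → 1.4-fold diffusion).
Synthesis-time arithmetic is `length/rate` per stage; note that 13,000
amino acids at 3 aa/s computes to ≈ 72 min.

The adaptive test harness applies Shapiro–Wilk per group at α = 0.05; if
all groups are consistent with normality, variance homogeneity is checked
(F test for two groups, Levene for more); normal + equal-variance data use
Student's t or one-way ANOVA with Tukey HSD, any non-normal group switches
to Wilcoxon rank-sum or Kruskal–Wallis with a Bonferroni-adjusted Dunn
post-hoc.  Two open corners were resolved as follows: the parametric branch
requires *all* groups to pass both checks; normal two-group data with
unequal variances fall back to Welch's t, and more than two such groups use
the rank-based branch.  The full procedure's two-group type-I error on
normal nulls is verified to stay within [0.03, 0.07] at nominal α = 0.05.

## Problem sizes used in the test suite and acceptance script

Full-size scans (256×256×50 at ~700 particles) simulate in ~1 min each;
the suites use the same pixel clock, optics and fitting procedure on
smaller fields, which leaves per-pixel correlation physics unchanged:
96×96 (acceptance script, single channel), 80×80 (two-channel index and
in-suite recovery), 48–64 px (property and kinetics tests).  Recovery runs
average 20 seeded replicates per condition.  Known consequences of the
reduced field: fewer independent pixel pairs raise the replicate-to-
replicate scatter of fitted D (CV ≈ 8% at 96×96) without measurable bias
for slow species and with a small (<7%) bias for fast ones, well inside
the stated recovery tolerances.

## Known limitations

* Single-component fits only (two-component RICS and multi-species FCS are
  out of scope); no spatial RICS maps or cell masking.
* The FCS module assumes pre-binned traces; photon-mode (arrival-time)
  correlation and multi-tau correlators are not implemented.
* The interaction index is reported raw; converting it to a percentage of
  interacting molecules requires brightness/concentration corrections that
  are deliberately not applied.
* The vendor `.fcs`/`.czi`/`.lsm` binary formats are not parsed; CSV/TIFF
  exports are the interchange formats.
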
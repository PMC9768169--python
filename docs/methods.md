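# Methods

This note documents the models, estimators and numerical choices behind
`txlive`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Conventions

Pixels are indexed 0-based; a spot center (r, c) in pixel units maps to
physical coordinates as 130·(r, c) nm, with the origin at the center of pixel
(0, 0) (130 nm/px is the camera pixel size of the emulated setup; it is a
parameter everywhere). All cluster and state-calling distances are 2D
Euclidean in nm. Times are minutes for burst/reporter kinetics and seconds
for FRAP and fast tracking. All stochastic routines take explicit integer
seeds; the staged pipeline expands one root seed deterministically per stage
(SHA-256 of `seed:stage`), so identical configs give byte-identical outputs.

## Synthetic-data generator

**Telegraph promoter.** The two-state promoter (OFF→ON at k_on, ON→OFF at
k_off, initiations at k_init while ON) is simulated by exact Gillespie
sampling of the switch times; the continuous-time path is then read out on
the sampling grid. This avoids the occupancy bias a fixed-step Markov
approximation would introduce at coarse dt. Initiations are a Poisson process
restricted to ON intervals. Burst kinetics for a pluripotency-class gene are
not published for the locus emulated here, so the defaults (k_on = 1/30
min⁻¹, k_off = 0.1 min⁻¹ — mean OFF 30 min, mean ON 10 min — k_init = 1
min⁻¹) are package parameters chosen as field-typical for a bursty mammalian
gene, not claims about any particular gene.

**Dual reporter traces.** Each initiating polymerase contributes unit
intensity to the TSS-proximal channel from its initiation time and to the
3'UTR channel after the travel time separation/rate; each transcript persists
for a dwell drawn once per transcript (exponential, mean 2 min by default)
and applied to both channels, so the 3'UTR trace is a transcript-wise shifted
copy of the TSS trace. This is the simplest signal model that reproduces the
onset-delay structure of dual-tag imaging; it ignores partial loop occupancy
during transit of the stem-loop array.

**Locus diffusion.** 2D trajectories with ensemble MSD(t) = 4·D_α·t^α are
generated per axis: plain Gaussian increments for α = 1, fractional Gaussian
noise with Hurst index α/2 for α ≠ 1, constructed by Davies–Harte circulant
embedding of the exact fGn autocovariance (a Cholesky fallback guards the
rare non-embeddable case). Localization error is i.i.d. Gaussian per frame
and axis, added after the physical path.

**Scene rendering.** Spots are 2D isotropic Gaussians (amplitude = peak above
background, default σ 1.3 px ≈ a diffraction-limited spot at 130 nm/px);
camera noise is Poisson shot noise on gain-scaled intensities followed by
additive Gaussian read noise, both optional and seeded. 3D PSFs, spectral
bleed-through and reporter photobleaching are deliberately not modeled.

**Cluster scenes.** A locus anchor (channel 0) is placed near the frame
center; the designated nearest regulatory-factor cluster (channel 1) is
placed at a distance drawn from a lognormal whose median is the configured
state-dependent value (defaults 289 nm ON, 456 nm OFF; log-SD 0.35). Decoy
clusters are scattered area-uniformly over the rest of the nucleus beyond
1.5× the near distance, with a 6 px minimum mutual separation — regulatory
factor clusters in nuclei are sparse, so every rendered focus is a resolvable
single emitter. The ground-truth nearest distance is recorded as the
brute-force minimum over all placed clusters.

**What passing tests show.** Recovery tests on these scenes demonstrate that
the detection/measurement/distance chain is unbiased under the stated
image-formation model. They do not exercise segmentation errors, overlapping
emitters, z-defocus, chromatic offsets, or intensity heterogeneity beyond the
modeled ±20% amplitude scatter, all of which add error on real data.

## Estimators

**Spot localization.** Candidates are local maxima (minimum distance = half
the expected diameter; ties resolved brightest-first, then lowest (row, col));
each is refined by least-squares fit of an isotropic 2D Gaussian plus
constant offset in a window of expected diameter + 2 px, with the center
constrained to ±1.5 px of the candidate so a neighbouring spot cannot capture
the fit. Candidates whose window crosses the image border are dropped rather
than padded (padding would bias the fit). Refined duplicates closer than
1.5 px are merged brightest-first. Failed fits fall back to the window
centroid and are flagged. Localization on noiseless rendered spots is exact
to < 0.05 px and degrades monotonically with read noise.

**Track linking.** Greedy nearest-neighbour linking: candidate links within
the search range (default 2 px) are assigned in order of increasing
displacement (ties by candidate index), gaps up to the memory (default 4
frames) are tolerated, and tracks whose longest consecutive run is ≤ 50
frames are discarded. Greedy assignment is deterministic and
order-independent given the tie-break; it is not globally optimal
(no Hungarian assignment), which matters only at spot densities far above
the single-locus regime this package targets.

**MSCD.** d(t) is the Euclidean distance between locus and nuclear center of
mass (2D or 3D according to input dimensionality); MSCD(Δt) averages
[d(t) − d(t+Δt)]² over all valid pairs, with SEM across pairs at the cell
level and SEM across cells after averaging. Referencing the center of mass
cancels rigid nuclear translation exactly (tested as an invariant).

**MSD fit.** Per-track time-averaged MSD, ensemble-averaged, fitted over lags
≤ 66 steps (2 s at 30 ms/frame) as log MSD = log 4D_α + α·log t by equally
weighted linear least squares. Log-space fitting stabilizes the power law
when MSD spans decades; a linear-space nonlinear option is provided. The
two-parameter model deliberately omits a constant localization-noise offset;
with noisy tracks this biases α downward and D_α upward at short lags — a
known property of the stated model, not corrected here.

**FRAP.** Curves are normalized by the mean pre-bleach intensity and zeroed
at the first post-bleach frame. The recovery model
I(t) = baseline + f_mobile·(1 − e^(−t/τ)) is fitted by bounded nonlinear
least squares with multi-start over τ ∈ {5, 20, 50, 150, 400} s, spanning
fast (tens of seconds) and slow (minutes) dissociation regimes; the best
residual wins. Degenerate (flat) curves return f_mobile = 0 with τ flagged
unidentifiable rather than a spurious number. The shared-baseline estimator
fits the per-condition mean curves (per-time-point average across cells
before fitting) with the baseline fixed at each point of a 0.00–0.80 grid
(step 0.01) and returns the argmin of S_a + S_b together with the full
profile; on noiseless shared-baseline inputs the profile is unimodal and the
argmin is exact to one grid step. A simple-ratio bleach correction (each
frame rescaled to the first frame's mean within the nucleus) stands in for
interactive bleach-correction tools; it assumes the bleached structure is a
negligible fraction of the normalization region.

**Cross-correlation.** Per cell, the Pearson-normalized cross-correlation
(full-trace means and SDs; per-lag overlap normalization to avoid edge bias)
is computed for lags up to ±20 min and averaged across cells; the 95% band is
1.96·SEM across cells. Positive lag means the 3'UTR trace lags the
TSS-proximal trace. Zero-variance cells are excluded with a warning. The
elongation delay is the discrete peak lag, optionally refined by a parabola
through the peak and its neighbours; the rate is tag separation / delay. The
exact averaging scheme of cross-correlation estimators varies across the
literature; the Pearson/overlap choice here is declared in the output header.

**Cluster statistics.** Only the single nearest cluster per cell enters the
distance analysis (all-cluster distributions are available behind a flag).
The 350-nm short/long stratification assigns the boundary value to the short
group (the choice is recorded in the output metadata). Rank-sum comparisons
use the exact Mann–Whitney null distribution for combined n ≤ 20 without
ties, and the tie-corrected normal approximation otherwise. Cluster size is
the FWHM (2√(2 ln 2)·σ) of a circular Gaussian fitted to the pixel-wise mean
of 19×19 ROIs centered on the nearest clusters.

**smFISH.** The single-molecule unit intensity is the median integrated
intensity of non-cluster spots (≥ 20 required); per-spot molecule counts are
the background-corrected intensity ratio rounded to the nearest integer
(minimum 1). Nuclear spots with ≥ 3 molecule-equivalents are transcription
sites; cells are classed No/Mono/Bi by transcription-site count, with > 2
sites flagged. Background correction before ratioing is on by default and
switchable. Dense-region decomposition of overlapping spots is out of scope.

**ChIP-qPCR.** %input = 2^((Ct_input − 5.64) − Ct_sample) × 100; the constant
5.64 encodes the 20% input fraction and dilution and is used verbatim, not
re-derived. Fold enrichment normalizes %input to a reference primer pair.

## State calling

Thresholds are literal: snapshot ON iff relative intensity ≥ 3; trace ON iff
any frame ≥ 5; proximity ON iff some nascent-RNA spot is ≤ 390 nm from the
anchor **and** strictly > 2-fold the 19×19-ROI mean (a nuclear-mean reference
is available by flag; the ROI mean is the default reference). Every call
records its rule, thresholds and supporting measurements so it can be
re-audited from raw numbers. A kernel-density valley finder is provided to
rederive thresholds from data, but the fixed values are the defaults. No
hidden-Markov smoothing is applied — calls are per-frame/per-trace
thresholding by design.

## Problem sizes used in validation

The bundled recovery checks run at: 20 cells × 240 one-minute frames for
delay recovery (20 replicates); 50 FRAP curves of 25 four-second points;
100 Brownian tracks of 400 thirty-millisecond frames for diffusion recovery;
1000 rendered two-channel scenes (64×64 px) for the cluster-distance
pipeline. These sizes make the Monte-Carlo error comfortably smaller than
the stated tolerances (5–20% depending on the quantity).

## Known limitations

- Single-emitter isotropic Gaussian fitting only; anisotropic PSFs and
  multi-emitter decomposition are out of scope.
- 2D distances only for cluster analysis (single-plane imaging); MSCD
  supports 3D input but the rendered scenes are 2D.
- The MSD fit's missing noise-offset term biases α at short lags on noisy
  data (documented above).
- Auto-segmentation of nuclei is a threshold fallback (Otsu + hole filling +
  area filter); externally produced label masks are the intended input.
- Bleach correction is the simple-ratio method; reaction–diffusion FRAP
  models and bleach-spot geometry corrections are not implemented.
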
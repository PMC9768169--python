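# txlive

Quantitative analysis of live-cell transcription imaging, for researchers who
tag an endogenous gene locus with a DNA label (TetO/TetR) and its nascent
transcripts with RNA stem-loop reporters (MS2/MCP, PP7/PCP), and who want to
turn multi-channel fluorescence movies into numbers: where the locus is, when
the gene is ON, how fast it moves, how fast the polymerase elongates, and
which regulatory-factor clusters sit next to it.

Because raw microscopy of this kind is rarely shareable, the package pairs
every analysis stage with a synthetic-data generator (`txlive.simgen`) that
reproduces the statistical structure of such experiments — telegraph-model
promoter bursting, elongation-delayed dual reporter traces, anomalous locus
diffusion, PSF-rendered spots with Poisson–Gaussian camera noise, exponential
FRAP recovery, and state-coupled cluster placement — with the ground truth
retained, so the whole pipeline is verifiable end to end.

## What it computes

| Stage | Model / statistic |
|---|---|
| `spots` | sub-pixel localization by 2D Gaussian least squares; 6-px-radius disk means; SNR = µ/σ_N; greedy nearest-neighbour track linking (search range 2 px, gap memory 4, >50 consecutive frames) |
| `states` | ON/OFF calls: snapshot (relative intensity ≥ 3), trace (any frame ≥ 5), or locus-proximity (nascent spot ≤ 390 nm of the anchor and > 2-fold the ROI mean) |
| `dynamics` | MSCD(Δt) = ⟨[d(t) − d(t+Δt)]²⟩ against the nuclear center of mass; ensemble MSD with an anomalous-diffusion fit MSD(t) = 4·D_α·t^α over lags ≤ 66 steps (2 s) |
| `frapfit` | FRAP normalization I/I_pre; recovery fit I(t) = baseline + f_mobile·(1 − e^(−t/τ)); joint two-condition shared-baseline estimation by grid scan of total squared offsets |
| `kinetics` | cell-averaged Pearson cross-correlation of TSS-proximal vs 3'UTR reporter traces; elongation delay from the peak lag; rate = separation / delay |
| `clusters` | nearest regulatory-factor cluster distance (2D, nm); 350-nm stratified comparisons with Wilcoxon rank-sum (exact for small n); averaged-image FWHM = 2√(2 ln 2)·σ |
| `assay_quant` | smFISH molecule counting (transcription site = nuclear spot of ≥ 3 molecule-equivalents; No/Mono/Bi allele classes); ChIP-qPCR %input = 2^((Ct_in − 5.64) − Ct_s)·100 |

Fitting stages follow the statsmodels convention — a model object built from
data whose `fit()` returns a results object with estimates, diagnostics and a
`summary()` — e.g. `FrapModel` → `FrapResults`, `AnomalousDiffusionModel` →
`MsdResults`, `CrossCorrelationModel` → `CcfResult`.

## Worked example

Fit one simulated FRAP curve of a fast-dissociating DNA-binding mutant, and
estimate the polymerase elongation rate from simulated dual-reporter traces:

```python
import numpy as np
from txlive import simgen, frapfit, kinetics

t, y = simgen.simulate_frap_curve(simgen.FrapSimParams(
    baseline=0.41, f_mobile=0.492, tau=26.3, dt=4.0, n_points=25,
    noise_sigma=0.05, seed=3))
print(frapfit.fit_frap(t, y, baseline=0.41).summary())

pairs = []
for c in range(20):
    tg = simgen.simulate_telegraph(simgen.TelegraphParams(
        k_on=1/30, k_off=0.1, k_init=1.0, duration=240, dt=1.0, seed=c))
    pairs.append(simgen.simulate_reporter_pair(
        tg.events, separation_kb=11.2, elongation_rate_kb_per_min=2.8,
        duration=240, noise_sigma=0.1, seed=100 + c))
ccf = kinetics.ccf_average(pairs, max_lag_min=20)
delay, rate = kinetics.delay_and_rate(ccf, separation_kb=11.2)
print(f"elongation delay: {delay:.1f} min -> rate: {rate:.2f} kb/min")
```

prints

```
FRAP fit: I(t) = baseline + f_mobile * (1 - exp(-t/tau))
  n_points   : 25
  baseline   : 0.41  (fixed)
  f_mobile   : 0.5207
  tau        : 31.68 s
  S (RSS)    : 0.0802
  converged  : True
elongation delay: 4.0 min -> rate: 2.80 kb/min
```

The FRAP fit recovers the generating parameters (mobile fraction 0.492,
τ 26.3 s) within the scatter expected from one noisy 25-point curve; the
cross-correlation peak sits at the elongation travel time between the two
RNA tags (11.2 kb / 2.8 kb min⁻¹ = 4 min), so dividing separation by delay
returns the elongation rate.

A `txlive` console script exposes the stages (`simulate`, `frap`, `xcorr`,
`msd`, `chip`, `run` for a JSON/YAML-configured pipeline); every output CSV
carries a provenance header with the package version, config hash and stage
seed, and a fixed seed reproduces byte-identical outputs.

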
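"""Synthetic ground-truthed data generators for transcription-imaging analyses.

Every analysis stage in this package (spot localization, state calling, mobility,
FRAP fitting, dual-reporter cross-correlation, cluster distances) can be exercised
end-to-end on data generated here, with the generating parameters retained as
ground truth.  The generators model:

* two-state (telegraph) promoter bursting with exact Gillespie event times,
* elongation-delayed dual reporter traces (TSS-proximal tag vs 3'UTR tag),
* confined/anomalous locus diffusion via fractional Gaussian increments,
* diffraction-limited spots rendered as 2D Gaussians with Poisson-Gaussian
  camera noise,
* single-exponential FRAP recovery,
* state-coupled placement of regulatory-factor clusters around a locus anchor.

All randomness is driven by explicit integer seeds; a fixed seed reproduces
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "TelegraphParams",
    "TelegraphTrace",
    "ReporterPairTrace",
    "SpotTruth",
    "GroundTruthScene",
    "FrapSimParams",
    "ClusterSceneTruth",
    "simulate_telegraph",
    "simulate_reporter_pair",
    "simulate_locus_track",
    "render_scene",
    "simulate_frap_curve",
    "simulate_cluster_scene",
]

PIXEL_SIZE_NM = 130.0  # camera pixel size of the imaging setup emulated here


# ---------------------------------------------------------------------------
# telegraph (two-state promoter) model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TelegraphParams:
    """Two-state promoter kinetics.

    Rates are per minute: ``k_on`` (OFF->ON switching), ``k_off`` (ON->OFF),
    ``k_init`` (transcript initiations while ON).  ``duration`` and ``dt`` set
    the sampling grid of the returned state trace.
    """

    k_on: float
    k_off: float
    k_init: float
    duration: float
    dt: float = 1.0
    seed: int = 0
    start_on: bool | None = None  # None -> draw from stationary distribution

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_init"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")


@dataclass(frozen=True)
class TelegraphTrace:
    """Output of :func:`simulate_telegraph`."""

    times: np.ndarray          # sampling grid, min
    state: np.ndarray          # 0/1 promoter state at each grid time
    events: np.ndarray         # initiation event times, min
    switch_times: np.ndarray   # exact state-switch times, min
    params: TelegraphParams

    @property
    def on_fraction(self) -> float:
        return float(np.mean(self.state))


def simulate_telegraph(params: TelegraphParams) -> TelegraphTrace:
    """Simulate the telegraph promoter by exact Gillespie sampling.

    State-switch waiting times are exponential with the exact rates; the
    continuous-time path is then read out on the ``dt`` grid, so the sampled
    occupancy carries no time-discretization bias.  Initiations are a Poisson
    process with rate ``k_init`` restricted to ON intervals.
    """
    rng = np.random.default_rng(params.seed)
    if params.start_on is None:
        total = params.k_on + params.k_off
        p_on = params.k_on / total if total > 0 else 0.0
        on = bool(rng.random() < p_on)
    else:
        on = bool(params.start_on)

    t = 0.0
    switch_times: list[float] = []
    events: list[float] = []
    # piecewise intervals (start, end, state)
    intervals: list[tuple[float, float, bool]] = []
    while t < params.duration:
        rate = params.k_off if on else params.k_on
        dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_end = min(t + dwell, params.duration)
        intervals.append((t, t_end, on))
        if on and params.k_init > 0:
            n = rng.poisson(params.k_init * (t_end - t))
            if n:
                events.extend(np.sort(rng.uniform(t, t_end, size=n)))
        if t_end < params.duration:
            switch_times.append(t_end)
            on = not on
        t = t_end

    times = np.arange(0.0, params.duration + 0.5 * params.dt, params.dt)
    times = times[times <= params.duration]
    state = np.zeros(times.size, dtype=np.int8)
    for start, end, s in intervals:
        if s:
            # grid point belongs to the interval that contains it: start <= t < end
            state[(times >= start) & (times < end)] = 1
    if intervals and intervals[-1][2]:
        state[times >= intervals[-1][0]] = 1  # include the final endpoint

    return TelegraphTrace(
        times=times,
        state=state,
        events=np.asarray(events, dtype=float),
        switch_times=np.asarray(switch_times, dtype=float),
        params=params,
    )


# ---------------------------------------------------------------------------
# dual-reporter (TSS-proximal / 3'UTR) traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReporterPairTrace:
    """Paired intensity traces of a TSS-proximal and a 3'UTR RNA tag.

    ``true_delay`` is the elongation delay separating the two signals
    (tag separation / elongation rate), in minutes.
    """

    times: np.ndarray  # min, uniform grid
    mcp: np.ndarray    # TSS-proximal reporter intensity (a.u.)
    pcp: np.ndarray    # 3'UTR reporter intensity (a.u.)
    true_delay: float  # min

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.mcp) == len(self.pcp)):
            raise ValueError("times, mcp, pcp must have equal lengths")
        steps = np.diff(self.times)
        if steps.size and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("times must be strictly increasing with constant step")


def simulate_reporter_pair(
    events: Sequence[float],
    separation_kb: float = 11.2,
    elongation_rate_kb_per_min: float = 2.8,
    dwell_min: float = 2.0,
    dt: float = 1.0,
    duration: float | None = None,
    noise_sigma: float = 0.0,
    stochastic_dwell: bool = True,
    seed: int = 0,
) -> ReporterPairTrace:
    """Build paired reporter traces from a list of initiation times.

    Each initiating polymerase lights up the TSS-proximal channel immediately
    and the 3'UTR channel after travelling ``separation_kb`` at
    ``elongation_rate_kb_per_min``; each transcript then persists for a dwell
    time (exponential with mean ``dwell_min`` when ``stochastic_dwell``, else
    exactly ``dwell_min``).  The same per-transcript dwell applies to both
    channels, so the 3'UTR trace is the TSS trace shifted by the elongation
    delay transcript-by-transcript.
    """
    if separation_kb < 0:
        raise ValueError("separation_kb must be >= 0")
    if not elongation_rate_kb_per_min > 0:
        raise ValueError("elongation_rate must be > 0")
    events = np.asarray(list(events), dtype=float)
    delay = separation_kb / elongation_rate_kb_per_min
    if duration is None:
        duration = (events.max() if events.size else 0.0) + delay + 5 * dwell_min
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    times = times[times <= duration]

    rng = np.random.default_rng(seed)
    if stochastic_dwell and events.size:
        dwells = rng.exponential(dwell_min, size=events.size)
    else:
        dwells = np.full(events.size, dwell_min)

    mcp = np.zeros(times.size)
    pcp = np.zeros(times.size)
    for t0, dw in zip(events, dwells):
        mcp += ((times >= t0) & (times < t0 + dw)).astype(float)
        pcp += ((times >= t0 + delay) & (times < t0 + delay + dw)).astype(float)
    if noise_sigma > 0:
        mcp = mcp + rng.normal(0.0, noise_sigma, size=times.size)
        pcp = pcp + rng.normal(0.0, noise_sigma, size=times.size)
    return ReporterPairTrace(times=times, mcp=mcp, pcp=pcp, true_delay=delay)


# ---------------------------------------------------------------------------
# locus diffusion tracks
# ---------------------------------------------------------------------------

def _fgn_increments(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance fractional Gaussian noise by circulant embedding.

    Davies-Harte construction: embed the fGn autocovariance in a circulant
    matrix, take its (non-negative) eigenvalues by FFT, and colour complex
    white noise.  Falls back to a Cholesky factor if the embedding is not
    non-negative definite (does not occur for 0 < H < 1 with this covariance).
    """
    k = np.arange(n + 1)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    eig = np.fft.fft(row).real
    if np.min(eig) < -1e-8:
        cov = np.empty((n, n))
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        cov[:] = gamma[idx]
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        return chol @ rng.standard_normal(n)
    eig = np.clip(eig, 0.0, None)
    m = row.size
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    z = np.fft.fft(np.sqrt(eig / (2.0 * m)) * w)
    return np.sqrt(2.0) * z.real[:n]


def simulate_locus_track(
    d_alpha: float,
    alpha: float = 1.0,
    n_frames: int = 400,
    dt_s: float = 0.030,
    localization_sigma_nm: float = 0.0,
    n_tracks: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Simulate 2D locus trajectories with MSD(t) = 4 * D_alpha * t**alpha.

    Returns positions in nm, shape ``(n_tracks, n_frames, 2)``.  ``alpha = 1``
    is Brownian motion; ``alpha != 1`` uses fractional Gaussian increments with
    Hurst index ``alpha / 2`` so the noise-free ensemble MSD follows the target
    power law exactly.  Independent Gaussian localization error of SD
    ``localization_sigma_nm`` is added per frame and axis.
    """
    if d_alpha < 0:
        raise ValueError("d_alpha must be >= 0")
    if not (0 < alpha <= 2):
        raise ValueError("alpha must be in (0, 2]")
    rng = np.random.default_rng(seed)
    n_steps = n_frames - 1
    pos = np.zeros((n_tracks, n_frames, 2))
    if d_alpha > 0 and n_steps > 0:
        # per-axis variance of x(t): 2 * D * t^alpha  (so 2D MSD = 4 D t^alpha)
        scale = np.sqrt(2.0 * d_alpha * dt_s ** alpha)  # µm per unit-fGn step
        for i in range(n_tracks):
            for ax in range(2):
                if alpha == 1.0:
                    inc = rng.standard_normal(n_steps)
                elif alpha == 2.0:
                    inc = np.full(n_steps, rng.standard_normal())  # ballistic
                else:
                    inc = _fgn_increments(n_steps, alpha / 2.0, rng)
                pos[i, 1:, ax] = np.cumsum(inc) * scale
    pos *= 1000.0  # µm -> nm
    if localization_sigma_nm > 0:
        pos += rng.normal(0.0, localization_sigma_nm, size=pos.shape)
    return pos


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotTruth:
    """Ground-truth description of one rendered spot."""

    frame: int
    channel: int
    y_px: float
    x_px: float
    amplitude: float
    psf_sigma_px: float = 1.3

    def __post_init__(self) -> None:
        if not self.psf_sigma_px > 0:
            raise ValueError("psf_sigma_px must be > 0")


@dataclass
class GroundTruthScene:
    """Scene description: geometry, spots, background and camera-noise model.

    ``poisson_gain`` converts intensity to expected photon counts for shot
    noise (0 disables it); ``read_sigma`` is the SD of additive Gaussian read
    noise.  ``nucleus_center_px``/``nucleus_radius_px`` define a disk nucleus
    used by downstream segmentation-free analyses.
    """

    shape: tuple[int, int] = (64, 64)       # (ny, nx)
    n_frames: int = 1
    n_channels: int = 1
    pixel_size_nm: float = PIXEL_SIZE_NM
    spots: list[SpotTruth] = field(default_factory=list)
    background: float = 10.0
    poisson_gain: float = 0.0
    read_sigma: float = 0.0
    nucleus_center_px: tuple[float, float] | None = None
    nucleus_radius_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        for s in self.spots:
            self._check_inside(s)

    def _check_inside(self, s: SpotTruth) -> None:
        ny, nx = self.shape
        if not (0 <= s.y_px <= ny - 1 and 0 <= s.x_px <= nx - 1):
            raise ValueError(f"spot center ({s.y_px}, {s.x_px}) outside frame {self.shape}")

    def add_spot(self, s: SpotTruth) -> None:
        self._check_inside(s)
        self.spots.append(s)

    def truth_table(self):
        """Ground truth as a pandas DataFrame (frame, channel, y_px, x_px, ...)."""
        import pandas as pd

        return pd.DataFrame([asdict(s) for s in self.spots])

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def render_scene(scene: GroundTruthScene) -> np.ndarray:
    """Render a scene into a pixel array of shape (channel, frame, ny, nx).

    Each spot is a 2D isotropic Gaussian of the given amplitude (peak height
    above background) and sigma; noise, when enabled, is Poisson shot noise on
    ``poisson_gain``-scaled intensities followed by additive Gaussian read
    noise, seeded from ``scene.seed``.
    """
    ny, nx = scene.shape
    img = np.full((scene.n_channels, scene.n_frames, ny, nx), float(scene.background))
    yy, xx = np.mgrid[0:ny, 0:nx]
    for s in scene.spots:
        g = s.amplitude * np.exp(
            -((yy - s.y_px) ** 2 + (xx - s.x_px) ** 2) / (2.0 * s.psf_sigma_px ** 2)
        )
        img[s.channel, s.frame] += g
    rng = np.random.default_rng(scene.seed)
    if scene.poisson_gain > 0:
        img = rng.poisson(np.clip(img, 0, None) * scene.poisson_gain) / scene.poisson_gain
    if scene.read_sigma > 0:
        img = img + rng.normal(0.0, scene.read_sigma, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# FRAP curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapSimParams:
    """Parameters of a simulated FRAP recovery curve.

    The recovery model is ``I(t) = baseline + f_mobile * (1 - exp(-t / tau))``
    with ``t = 0`` at the first post-bleach frame; ``noise_sigma`` adds i.i.d.
    Gaussian noise on the normalized intensity scale.
    """

    baseline: float = 0.41
    f_mobile: float = 0.492
    tau: float = 26.3          # s
    dt: float = 4.0            # s between post-bleach frames
    n_points: int = 25
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.baseline <= 1:
            raise ValueError("baseline must be in [0, 1]")
        if not 0 <= self.f_mobile <= 1:
            raise ValueError("f_mobile must be in [0, 1]")
        if self.baseline + self.f_mobile > 1.05:
            raise ValueError("baseline + f_mobile must be <= 1.05")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")


def simulate_frap_curve(params: FrapSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Return (times_s, normalized_intensity) for one simulated FRAP recovery."""
    t = np.arange(params.n_points) * params.dt
    curve = params.baseline + params.f_mobile * (1.0 - np.exp(-t / params.tau))
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        curve = curve + rng.normal(0.0, params.noise_sigma, size=t.size)
    return t, curve


# ---------------------------------------------------------------------------
# regulatory-factor cluster scenes
# ---------------------------------------------------------------------------

# generator defaults for the anchor-to-nearest-cluster distance by promoter state
# (median of the lognormal placement distribution, nm)
CLUSTER_MEDIAN_NM = {"ON": 289.0, "OFF": 456.0}


@dataclass(frozen=True)
class ClusterSceneTruth:
    """Ground truth accompanying a two-channel cluster scene."""

    scene: GroundTruthScene
    anchor_yx_px: tuple[float, float]
    cluster_yx_px: np.ndarray      # (n_clusters, 2)
    nearest_index: int
    nearest_distance_nm: float
    state: str


def simulate_cluster_scene(
    state: str = "ON",
    distance_median_nm: float | None = None,
    n_clusters: int = 4,
    dispersion: float = 0.35,
    shape: tuple[int, int] = (64, 64),
    psf_sigma_px: float = 1.3,
    anchor_amplitude: float = 120.0,
    cluster_amplitude: float = 100.0,
    background: float = 20.0,
    read_sigma: float = 0.0,
    poisson_gain: float = 0.0,
    seed: int = 0,
) -> ClusterSceneTruth:
    """Place a locus anchor (channel 0) and RF clusters (channel 1).

    The distance from the anchor to its designated nearest cluster is drawn
    from a lognormal whose median is ``distance_median_nm`` (default set by
    ``state``: 289 nm ON, 456 nm OFF) with log-SD ``dispersion``; decoy
    clusters are placed at strictly larger radii.  The ground-truth nearest
    distance (a brute-force minimum over all placed clusters) is recorded.
    """
    if distance_median_nm is None:
        distance_median_nm = CLUSTER_MEDIAN_NM[state]
    if distance_median_nm < 0:
        raise ValueError("distance_median_nm must be >= 0")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    px = PIXEL_SIZE_NM
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    # jitter the anchor off the exact center so nothing aligns with the grid
    ay = cy + rng.uniform(-2, 2)
    ax = cx + rng.uniform(-2, 2)

    if dispersion > 0:
        r_near_nm = float(np.exp(np.log(max(distance_median_nm, 1e-12))
                                 + dispersion * rng.standard_normal())) \
            if distance_median_nm > 0 else 0.0
    else:
        r_near_nm = distance_median_nm
    # keep the near cluster comfortably inside the frame
    r_max_nm = (min(ny, nx) / 2.0 - 6.0) * px
    r_near_nm = min(r_near_nm, r_max_nm)

    # decoy clusters are sparse foci scattered over the whole nucleus: radii
    # area-uniform between 1.5x the near distance and the nuclear rim, with a
    # minimum mutual separation so every focus is a resolvable single emitter
    min_sep_px = 6.0
    r_lo_px = max(1.5 * r_near_nm, r_near_nm + 2.0 * px) / px
    r_hi_px = min(ny, nx) / 2.0 - 5.0
    r_lo_px = min(r_lo_px, r_hi_px - 1.0)
    centers = np.empty((n_clusters, 2))
    theta = rng.uniform(0, 2 * np.pi)
    centers[0] = (ay + r_near_nm / px * np.sin(theta), ax + r_near_nm / px * np.cos(theta))
    for i in range(1, n_clusters):
        placed = None
        for _ in range(100):
            r_decoy = np.sqrt(rng.uniform(r_lo_px**2, r_hi_px**2))
            th = rng.uniform(0, 2 * np.pi)
            yy = ay + r_decoy * np.sin(th)
            xx = ax + r_decoy * np.cos(th)
            if not (3 <= yy <= ny - 4 and 3 <= xx <= nx - 4):
                continue
            if np.hypot(yy - ay, xx - ax) * px <= r_near_nm:
                continue
            if np.min(np.hypot(centers[:i, 0] - yy, centers[:i, 1] - xx)) < min_sep_px:
                continue
            placed = (yy, xx)
            break
        if placed is None:  # degenerate geometry: stack decoys on the far rim
            ang = 2 * np.pi * i / n_clusters
            placed = (np.clip(ay + r_hi_px * np.sin(ang), 3, ny - 4),
                      np.clip(ax + r_hi_px * np.cos(ang), 3, nx - 4))
        centers[i] = placed

    d_all = np.hypot(centers[:, 0] - ay, centers[:, 1] - ax) * px
    nearest = int(np.argmin(d_all))

    scene = GroundTruthScene(
        shape=shape,
        n_frames=1,
        n_channels=2,
        pixel_size_nm=px,
        background=background,
        read_sigma=read_sigma,
        poisson_gain=poisson_gain,
        nucleus_center_px=(cy, cx),
        nucleus_radius_px=min(ny, nx) / 2.0 - 1.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    scene.add_spot(SpotTruth(0, 0, ay, ax, anchor_amplitude, psf_sigma_px))
    for i, (yy, xx) in enumerate(centers):
        amp = cluster_amplitude * rng.uniform(0.8, 1.2)
        scene.add_spot(SpotTruth(0, 1, float(yy), float(xx), amp, psf_sigma_px))

    return ClusterSceneTruth(
        scene=scene,
        anchor_yx_px=(ay, ax),
        cluster_yx_px=centers,
        nearest_index=nearest,
        nearest_distance_nm=float(d_all[nearest]),
        state=state,
    )
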
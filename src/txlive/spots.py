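"""Spot detection, sub-pixel localization, measurement and linking.

Candidate spots are local intensity maxima; each candidate is refined by a
least-squares fit of a 2D isotropic Gaussian plus constant offset within a
square window, giving sub-pixel centers.  Spot brightness is summarized as
the mean intensity within a 6-pixel-radius disk, and as that disk mean
relative to the nuclear mean intensity.  Tracks are built by greedy
nearest-neighbour linking with a gap memory, and short tracks (by longest
consecutive run) are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage import morphology
from skimage.feature import peak_local_max

from .imgproc import ImageStack, NucleusRecord

__all__ = [
    "SpotRecord",
    "Track",
    "detect_and_refine",
    "measure_spot",
    "link_tracks",
    "compute_snr",
    "count_foci",
    "spots_table",
]

PIXEL_SIZE_NM = 130.0
DISK_RADIUS_PX = 6  # disk used for spot mean intensity


@dataclass
class SpotRecord:
    """One localized spot."""

    channel: str
    frame: int
    y_px: float
    x_px: float
    sigma_px: float
    amplitude: float
    offset: float = 0.0
    disk_mean: float = np.nan
    relative_intensity: float = np.nan
    nucleus_label: int = 0
    refined: bool = True          # False -> centroid fallback
    partial_disk: bool = False

    @property
    def y_nm(self) -> float:
        return self.y_px * PIXEL_SIZE_NM

    @property
    def x_nm(self) -> float:
        return self.x_px * PIXEL_SIZE_NM


@dataclass
class Track:
    """Linked spot series; ``gaps`` records the length of each internal gap."""

    track_id: int
    spots: list[SpotRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = self.frames
        if np.any(np.diff(frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def positions_px(self) -> np.ndarray:
        return np.array([[s.y_px, s.x_px] for s in self.spots])

    @property
    def positions_nm(self) -> np.ndarray:
        return self.positions_px * PIXEL_SIZE_NM

    @property
    def gaps(self) -> np.ndarray:
        return np.diff(self.frames) - 1

    def longest_consecutive_run(self) -> int:
        frames = self.frames
        if frames.size == 0:
            return 0
        runs, run = [], 1
        for d in np.diff(frames):
            if d == 1:
                run += 1
            else:
                runs.append(run)
                run = 1
        runs.append(run)
        return max(runs)


def _gaussian2d(params, yy, xx):
    amp, y0, x0, sigma, off = params
    return amp * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma**2)) + off


def _fit_gaussian(window: np.ndarray, y0: float, x0: float, center_slack: float = 1.5):
    """Least-squares 2D isotropic Gaussian + offset fit; returns params or None.

    The center is constrained to within ``center_slack`` px of the candidate
    maximum so neighbouring spots inside the window cannot capture the fit.
    """
    yy, xx = np.mgrid[0 : window.shape[0], 0 : window.shape[1]]
    off0 = float(np.median(window))
    amp0 = max(float(window.max() - off0), 1e-6)
    p0 = [amp0, y0, x0, 1.5, off0]
    lo = [0.0, y0 - center_slack, x0 - center_slack, 0.3, -np.inf]
    hi = [np.inf, y0 + center_slack, x0 + center_slack, window.shape[0], np.inf]
    try:
        res = least_squares(
            lambda p: (_gaussian2d(p, yy, xx) - window).ravel(),
            p0, bounds=(lo, hi), max_nfev=200,
        )
    except Exception:
        return None
    if not res.success and res.status <= 0:
        return None
    return res.x


def _plane_from(image) -> tuple[np.ndarray, float]:
    if isinstance(image, ImageStack):
        if image.pixels.ndim != 2:
            raise ValueError("expected a single 2D plane (project first)")
        return image.pixels, image.pixel_size_nm
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    return img, PIXEL_SIZE_NM


def detect_and_refine(
    image,
    expected_diameter_px: int = 5,
    threshold: float | None = None,
    max_candidates: int | None = None,
    roi: tuple[int, int, int, int] | None = None,
    window: int | None = None,
    channel: str = "",
    frame: int = 0,
    nucleus: NucleusRecord | None = None,
) -> list[SpotRecord]:
    """Detect local maxima and refine each to sub-pixel precision.

    ``roi`` restricts detection to ``(ymin, ymax, xmin, xmax)`` (half-open),
    e.g. a 19x19 analysis window centered on a locus anchor.  The refinement
    ``window`` defaults to roughly twice the expected diameter so that
    neighbouring spots stay outside the fit.  Candidates whose window would
    cross the image border are dropped with a warning.  Equal-intensity ties
    are ordered lowest (row, col) first.  Failed Gaussian fits fall back to
    the intensity centroid of the window and are flagged ``refined=False``.
    """
    img, _ = _plane_from(image)
    if expected_diameter_px < 3 or expected_diameter_px % 2 == 0:
        raise ValueError("expected_diameter_px must be an odd integer >= 3")
    if window is None:
        window = expected_diameter_px + 2
    search = img
    oy = ox = 0
    if roi is not None:
        ymin, ymax, xmin, xmax = roi
        search = img[ymin:ymax, xmin:xmax]
        oy, ox = ymin, xmin
    min_dist = max(expected_diameter_px // 2, 1)
    kwargs = {}
    if threshold is not None:
        kwargs["threshold_abs"] = threshold
    peaks = peak_local_max(search, min_distance=min_dist, exclude_border=False, **kwargs)
    if peaks.size == 0:
        return []
    # deterministic order: intensity desc, then (row, col) lexicographic
    vals = search[peaks[:, 0], peaks[:, 1]]
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -vals))
    peaks = peaks[order]
    if max_candidates is not None:
        peaks = peaks[:max_candidates]

    half = window // 2
    records: list[SpotRecord] = []
    for py, px in peaks:
        cy, cx = py + oy, px + ox
        if cy - half < 0 or cy + half >= img.shape[0] or cx - half < 0 or cx + half >= img.shape[1]:
            warnings.warn(
                f"candidate at ({cy}, {cx}) dropped: refinement window crosses border",
                stacklevel=2,
            )
            continue
        win = img[cy - half : cy + half + 1, cx - half : cx + half + 1]
        fit = _fit_gaussian(win, half, half)
        if fit is not None and 0 <= fit[1] <= window - 1 and 0 <= fit[2] <= window - 1:
            amp, y0, x0, sigma, off = fit
            rec = SpotRecord(
                channel=channel, frame=frame,
                y_px=cy - half + y0, x_px=cx - half + x0,
                sigma_px=float(sigma), amplitude=float(amp), offset=float(off),
            )
        else:
            w = np.clip(win - win.min(), 0, None)
            tot = w.sum()
            yy, xx = np.mgrid[0 : window, 0 : window]
            y0 = (yy * w).sum() / tot if tot > 0 else half
            x0 = (xx * w).sum() / tot if tot > 0 else half
            rec = SpotRecord(
                channel=channel, frame=frame,
                y_px=cy - half + float(y0), x_px=cx - half + float(x0),
                sigma_px=1.0, amplitude=float(win.max() - win.min()),
                offset=float(win.min()), refined=False,
            )
        if nucleus is not None:
            measure_spot(img, rec, nucleus=nucleus)
        records.append(rec)
    # refinement can pull two candidates of one blob onto the same center:
    # keep the brighter of any pair closer than the detection min-distance
    records.sort(key=lambda r: (-r.amplitude, r.y_px, r.x_px))
    dedupe = min(float(min_dist), 1.5)
    kept: list[SpotRecord] = []
    for rec in records:
        if all(np.hypot(rec.y_px - k.y_px, rec.x_px - k.x_px) > dedupe for k in kept):
            kept.append(rec)
    return kept


def _disk_pixels(shape, cy: float, cx: float, radius: float):
    ny, nx = shape
    y0, y1 = max(int(np.floor(cy - radius)), 0), min(int(np.ceil(cy + radius)) + 1, ny)
    x0, x1 = max(int(np.floor(cx - radius)), 0), min(int(np.ceil(cx + radius)) + 1, nx)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return yy[sel], xx[sel]


def measure_spot(
    image,
    spot: SpotRecord | tuple[float, float],
    radius_px: float = DISK_RADIUS_PX,
    nucleus: NucleusRecord | None = None,
) -> tuple[float, float]:
    """Mean intensity in a disk around the spot center, and its ratio to the
    nuclear mean.

    Returns ``(disk_mean, relative_intensity)``; ``relative_intensity`` is NaN
    when no nucleus is given.  If the disk extends past the image border, the
    in-frame part is used and the record is flagged ``partial_disk``.
    """
    img, _ = _plane_from(image)
    if isinstance(spot, SpotRecord):
        cy, cx = spot.y_px, spot.x_px
    else:
        cy, cx = spot
    full = (
        cy - radius_px >= -0.5 and cx - radius_px >= -0.5
        and cy + radius_px <= img.shape[0] - 0.5 and cx + radius_px <= img.shape[1] - 0.5
    )
    ys, xs = _disk_pixels(img.shape, cy, cx, radius_px)
    if ys.size == 0:
        raise ValueError("disk contains no pixels inside the image")
    disk_mean = float(img[ys, xs].mean())
    rel = np.nan
    if nucleus is not None:
        if nucleus.mean_intensity <= 0:
            raise ValueError("nucleus mean <= 0: relative intensity undefined")
        rel = disk_mean / nucleus.mean_intensity
    if isinstance(spot, SpotRecord):
        spot.disk_mean = disk_mean
        spot.relative_intensity = rel
        spot.partial_disk = not full
        if nucleus is not None:
            spot.nucleus_label = nucleus.label
    return disk_mean, rel


def link_tracks(
    frames: dict[int, list[SpotRecord]] | list[list[SpotRecord]],
    search_range_px: float = 2.0,
    memory_frames: int = 4,
    min_consecutive: int = 50,
) -> list[Track]:
    """Greedy nearest-neighbour linking with gap closing.

    A spot joins the track whose last position is nearest, provided the
    displacement is within ``search_range_px`` and the frame gap is at most
    ``memory_frames``.  Ties are broken by smallest displacement, then lowest
    candidate index.  Tracks whose longest consecutive run is <=
    ``min_consecutive`` frames are discarded (set ``min_consecutive=0`` to
    keep all).
    """
    if isinstance(frames, dict):
        items = sorted(frames.items())
    else:
        items = list(enumerate(frames))

    active: list[dict] = []   # {'spots': [...], 'last': (y,x), 'last_frame': int}
    done: list[list[SpotRecord]] = []
    for fidx, spots in items:
        # retire tracks that exceeded gap memory
        still = []
        for tr in active:
            if fidx - tr["last_frame"] - 1 > memory_frames:
                done.append(tr["spots"])
            else:
                still.append(tr)
        active = still
        # candidate links: (distance, spot_index, track_index)
        cands = []
        for si, s in enumerate(spots):
            for ti, tr in enumerate(active):
                d = float(np.hypot(s.y_px - tr["last"][0], s.x_px - tr["last"][1]))
                if d <= search_range_px:
                    cands.append((d, si, ti))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        used_s, used_t = set(), set()
        for d, si, ti in cands:
            if si in used_s or ti in used_t:
                continue
            tr = active[ti]
            tr["spots"].append(spots[si])
            tr["last"] = (spots[si].y_px, spots[si].x_px)
            tr["last_frame"] = fidx
            used_s.add(si)
            used_t.add(ti)
        for si, s in enumerate(spots):
            if si not in used_s:
                active.append({"spots": [s], "last": (s.y_px, s.x_px), "last_frame": fidx})
    done.extend(tr["spots"] for tr in active)

    tracks = [Track(track_id=i, spots=sp) for i, sp in enumerate(done)]
    return [t for t in tracks if t.longest_consecutive_run() > min_consecutive]


def compute_snr(image, center: tuple[float, float], nucleus: NucleusRecord,
                radius_px: float = 2.0) -> float:
    """Signal-to-noise ratio: spot mean intensity / nuclear intensity SD.

    The image is expected to be background-subtracted.  ``radius_px`` sets the
    disk over which the spot mean is taken (default ~0.5 um at 130 nm/px).
    """
    if nucleus.sd_intensity == 0:
        raise ValueError("nuclear SD is zero: SNR undefined")
    mu, _ = measure_spot(image, center, radius_px=radius_px)
    return mu / nucleus.sd_intensity


def count_foci(image, mask: np.ndarray, prominence: float = 10.0) -> tuple[int, float]:
    """Count prominence-thresholded intensity maxima within a nucleus mask.

    A focus is a connected component of the h-maxima transform (h =
    ``prominence``) whose peak also rises at least ``prominence`` above the
    in-mask minimum, so a flat nucleus yields zero foci.  Returns
    ``(count, mean focus peak intensity)`` (NaN mean when count is 0).
    """
    if not prominence > 0:
        raise ValueError("prominence must be > 0")
    img, _ = _plane_from(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape or not mask.any():
        raise ValueError("mask must be non-empty and aligned with the image")
    work = img.copy()
    floor = float(img[mask].min())
    work[~mask] = floor
    hmax = morphology.h_maxima(work, prominence)
    hmax &= mask
    from scipy import ndimage as ndi

    labels, n = ndi.label(hmax)
    peaks = []
    for lab in range(1, n + 1):
        peak = float(img[labels == lab].max())
        if peak >= floor + prominence:
            peaks.append(peak)
    return len(peaks), (float(np.mean(peaks)) if peaks else np.nan)


def spots_table(spots: list[SpotRecord], pixel_size_nm: float = PIXEL_SIZE_NM) -> pd.DataFrame:
    """Spot records as a DataFrame with both px and nm coordinates."""
    rows = []
    for s in spots:
        rows.append(
            {
                "channel": s.channel, "frame": s.frame,
                "y_px": s.y_px, "x_px": s.x_px,
                "y_nm": s.y_px * pixel_size_nm, "x_nm": s.x_px * pixel_size_nm,
                "sigma_px": s.sigma_px, "amplitude": s.amplitude, "offset": s.offset,
                "disk_mean": s.disk_mean, "relative_intensity": s.relative_intensity,
                "nucleus_label": s.nucleus_label, "refined": s.refined,
                "partial_disk": s.partial_disk,
            }
        )
    return pd.DataFrame(rows)
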
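"""Image containers, preprocessing and nucleus measurement.

The preprocessing steps mirror the standard ImageJ operations used in
live-cell transcription imaging work: median/Gaussian filtering, rolling-ball
background subtraction, max/average intensity projection, simple-ratio bleach
correction, and translational drift correction.  Steps are applied in the
order given and recorded as provenance on the output stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, restoration
from skimage.registration import phase_cross_correlation

__all__ = ["ImageStack", "NucleusRecord", "preprocess", "measure_nuclei", "segment_nuclei_auto"]

PIXEL_SIZE_NM = 130.0


@dataclass
class ImageStack:
    """Pixel data with physical calibration.

    ``axes`` names the dimensions of ``pixels`` using a subset of "TZYX" in
    that order (e.g. "TYX" for a single-plane time series, "YX" for one
    frame).  ``pixel_size_nm`` defaults to the 130 nm camera pixel of the
    emulated setup.
    """

    pixels: np.ndarray
    axes: str = "YX"
    pixel_size_nm: float = PIXEL_SIZE_NM
    frame_interval_s: float | None = None
    channel: str = ""
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != len(self.axes):
            raise ValueError(f"axes {self.axes!r} do not match array ndim {self.pixels.ndim}")
        if any(a not in "TZYX" for a in self.axes) or list(self.axes) != sorted(
            self.axes, key="TZYX".index
        ):
            raise ValueError(f"axes must be an ordered subset of 'TZYX', got {self.axes!r}")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if any(n < 1 for n in self.pixels.shape):
            raise ValueError("all axis lengths must be >= 1")

    def axis_index(self, name: str) -> int:
        i = self.axes.find(name)
        if i < 0:
            raise ValueError(f"stack has no {name!r} axis")
        return i

    def iter_planes(self):
        """Yield (index, 2D plane) over all leading axes."""
        lead = self.pixels.shape[:-2]
        for idx in np.ndindex(*lead) if lead else [()]:
            yield idx, self.pixels[idx]

    def with_pixels(self, pixels: np.ndarray, axes: str | None = None, step=None) -> "ImageStack":
        out = replace(self, pixels=pixels, axes=axes or self.axes)
        out.provenance = list(self.provenance) + ([step] if step else [])
        return out

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.pixels.astype(np.float32),
                         photometric="minisblack", metadata={"axes": self.axes})

    @classmethod
    def from_tiff(cls, path, **kwargs) -> "ImageStack":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            axes = kwargs.pop("axes", None)
            if axes is None:
                meta = tf.series[0].axes if tf.series else None
                axes = meta if meta and set(meta) <= set("TZYX") else "YX"[-arr.ndim:]
        return cls(pixels=arr, axes=axes, **kwargs)


@dataclass(frozen=True)
class NucleusRecord:
    """Per-nucleus intensity statistics and center of mass (nm)."""

    label: int
    n_pixels: int
    mean_intensity: float
    sd_intensity: float          # sigma_N used by the SNR statistic
    center_of_mass_nm: tuple[float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("mask must be non-empty")
        if self.sd_intensity < 0:
            raise ValueError("sd must be >= 0")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _per_plane(pixels: np.ndarray, fn) -> np.ndarray:
    out = np.empty_like(pixels, dtype=float)
    lead = pixels.shape[:-2]
    for idx in (np.ndindex(*lead) if lead else [()]):
        out[idx] = fn(pixels[idx])
    return out


def _step_median(stack: ImageStack, radius: int = 1) -> ImageStack:
    if radius <= 0:
        raise ValueError("radius must be > 0")
    fp = morphology.disk(radius)
    px = _per_plane(stack.pixels, lambda p: ndimage.median_filter(p, footprint=fp))
    return stack.with_pixels(px, step=("median", radius))


def _step_gaussian(stack: ImageStack, radius: float = 1.0) -> ImageStack:
    if radius <= 0:
        raise ValueError("radius must be > 0")
    px = _per_plane(stack.pixels, lambda p: filters.gaussian(p, sigma=radius, preserve_range=True))
    return stack.with_pixels(px, step=("gaussian", radius))


def _step_rolling_ball(stack: ImageStack, radius: float) -> ImageStack:
    if radius <= 0:
        raise ValueError("radius must be > 0")

    def rb(p):
        bg = restoration.rolling_ball(p, radius=radius)
        return np.clip(p - bg, 0.0, None)

    return stack.with_pixels(_per_plane(stack.pixels, rb), step=("rolling_ball", radius))


def _project(stack: ImageStack, reducer, name: str) -> ImageStack:
    z = stack.axis_index("Z")
    if stack.pixels.shape[z] <= 1:
        raise ValueError("projection requires z-axis length > 1")
    px = reducer(stack.pixels, axis=z)
    return stack.with_pixels(px, axes=stack.axes.replace("Z", ""), step=(name, None))


def _step_bleach_ratio(stack: ImageStack, mask: np.ndarray | None = None) -> ImageStack:
    """Simple-ratio bleach correction: rescale every frame so its mean (within
    ``mask`` if given) matches the first frame's mean."""
    t = stack.axis_index("T")
    px = np.moveaxis(stack.pixels.copy(), t, 0)
    ref = None
    for i in range(px.shape[0]):
        m = px[i][mask] if mask is not None else px[i]
        mean = float(np.mean(m))
        if i == 0:
            ref = mean
            continue
        if mean > 0:
            px[i] *= ref / mean
    px = np.moveaxis(px, 0, t)
    return stack.with_pixels(px, step=("bleach_ratio", None))


def _step_drift(stack: ImageStack, reference: str = "first", upsample: int = 1) -> ImageStack:
    """Translational drift correction by phase cross-correlation per frame."""
    t = stack.axis_index("T")
    px = np.moveaxis(stack.pixels.copy(), t, 0)
    ref = px[0]
    shifts = []
    for i in range(px.shape[0]):
        if i == 0:
            shifts.append((0.0, 0.0))
            continue
        shift, _, _ = phase_cross_correlation(ref, px[i], upsample_factor=upsample)
        px[i] = ndimage.shift(px[i], shift, order=1, mode="nearest")
        shifts.append(tuple(float(s) for s in shift))
        if reference == "previous":
            ref = px[i]
    px = np.moveaxis(px, 0, t)
    return stack.with_pixels(px, step=("drift", shifts))


_STEPS = {
    "median": _step_median,
    "gaussian": _step_gaussian,
    "rolling_ball": _step_rolling_ball,
    "max_project": lambda s: _project(s, np.max, "max_project"),
    "mean_project": lambda s: _project(s, np.mean, "mean_project"),
    "bleach_ratio": _step_bleach_ratio,
    "drift": _step_drift,
}


def preprocess(stack: ImageStack, steps) -> ImageStack:
    """Apply an ordered list of preprocessing steps.

    ``steps`` is a sequence of step names or ``(name, kwargs)`` pairs, e.g.
    ``[("gaussian", {"radius": 1}), ("rolling_ball", {"radius": 5}), "max_project"]``.
    """
    out = stack
    for step in steps:
        if isinstance(step, str):
            name, kwargs = step, {}
        else:
            name, kwargs = step
            if not isinstance(kwargs, dict):
                kwargs = dict(kwargs)
        if name not in _STEPS:
            raise ValueError(f"unknown preprocessing step {name!r}")
        out = _STEPS[name](out, **kwargs)
    return out


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

def segment_nuclei_auto(image: np.ndarray, min_area_px: int = 50) -> np.ndarray:
    """Threshold fallback segmentation: Otsu + hole filling + small-object removal.

    A stand-in for learned segmenters; externally produced label masks are the
    first-class input to :func:`measure_nuclei`.
    """
    thr = filters.threshold_otsu(image)
    mask = ndimage.binary_fill_holes(image > thr)
    labels, n = ndimage.label(mask)
    if n:
        areas = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if areas[lab] < min_area_px:
                labels[labels == lab] = 0
        labels, _ = ndimage.label(labels > 0)  # relabel consecutively
    return labels


def measure_nuclei(image: ImageStack | np.ndarray, masks="auto") -> list[NucleusRecord]:
    """Measure mean, SD and intensity-weighted center of mass per labelled nucleus.

    ``masks`` is a label image aligned with the (2D) intensity image, or
    ``"auto"`` to use the threshold fallback.  Centers of mass are converted
    to nm with the stack's pixel size (origin at the center of pixel (0, 0)).
    """
    if isinstance(image, ImageStack):
        px_nm = image.pixel_size_nm
        channel = image.channel
        img = image.pixels
    else:
        px_nm = PIXEL_SIZE_NM
        channel = ""
        img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("measure_nuclei expects a single 2D plane")
    if isinstance(masks, str) and masks == "auto":
        masks = segment_nuclei_auto(img)
    masks = np.asarray(masks)
    if masks.shape != img.shape:
        raise ValueError("mask/image shape mismatch")
    labels = np.unique(masks)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("label image contains no nuclei")
    records = []
    for lab in labels:
        sel = masks == lab
        vals = img[sel]
        total = float(vals.sum())
        ys, xs = np.nonzero(sel)
        if total > 0:
            com = (float((ys * vals).sum() / total), float((xs * vals).sum() / total))
        else:  # unweighted fallback for all-zero nuclei
            com = (float(ys.mean()), float(xs.mean()))
        records.append(
            NucleusRecord(
                label=int(lab),
                n_pixels=int(vals.size),
                mean_intensity=float(vals.mean()),
                sd_intensity=float(vals.std()),
                center_of_mass_nm=(com[0] * px_nm, com[1] * px_nm),
                channel=channel,
            )
        )
    return records


def nuclei_table(records: list[NucleusRecord]) -> pd.DataFrame:
    rows = [
        {
            "label": r.label,
            "n_pixels": r.n_pixels,
            "mean_intensity": r.mean_intensity,
            "sd_intensity": r.sd_intensity,
            "com_y_nm": r.center_of_mass_nm[0],
            "com_x_nm": r.center_of_mass_nm[1],
            "channel": r.channel,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
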
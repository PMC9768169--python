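"""Transcriptional ON/OFF state calling.

Three rules are supported, matching how live-cell reporter data are scored:

* **snapshot** — a single relative-intensity value; ON iff it is >= 3
  (the valley between the background mode and the spot mode of the
  relative-intensity histogram).
* **trace** — a time-lapse of relative intensities; ON iff any frame
  reaches the trace threshold (default 5, the histogram valley for the
  time-lapse assay).
* **rf_proximity** — frame-wise rule for regulatory-factor imaging: ON iff
  some nascent-RNA (MCP) spot lies within 390 nm of the locus anchor AND its
  mean intensity is more than two-fold the reference (ROI mean by default).

Thresholds and supporting measurements are recorded on every call so each
classification can be re-audited from raw numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .spots import SpotRecord

__all__ = ["StateCall", "classify_snapshot_or_trace", "classify_rf_frame", "histogram_valley"]

SNAPSHOT_THRESHOLD = 3.0
TRACE_THRESHOLD = 5.0
RF_MAX_DISTANCE_NM = 390.0
RF_MIN_FOLD = 2.0
PIXEL_SIZE_NM = 130.0


@dataclass(frozen=True)
class StateCall:
    """Result of one ON/OFF classification, with its audit trail."""

    state: str                      # "ON" | "OFF"
    rule: str                       # "snapshot" | "trace" | "rf_proximity"
    thresholds: dict = field(default_factory=dict)
    measurements: dict = field(default_factory=dict)

    @property
    def is_on(self) -> bool:
        return self.state == "ON"


def classify_snapshot_or_trace(values, mode: str = "snapshot",
                               threshold: float | None = None) -> StateCall:
    """Threshold a relative-intensity value (snapshot) or trace.

    Snapshot: ON iff the value is >= 3 ("3 or higher").  Trace: ON iff any
    frame's value is >= 5 (transcription observed at least once during the
    time-lapse).
    """
    vals = np.atleast_1d(np.asarray(values, dtype=float))
    if vals.size == 0:
        raise ValueError("empty trace")
    if not np.all(np.isfinite(vals)):
        raise ValueError("values must be finite")
    if mode == "snapshot":
        if vals.size != 1:
            raise ValueError("snapshot mode takes a single value")
        thr = SNAPSHOT_THRESHOLD if threshold is None else threshold
        on = bool(vals[0] >= thr)
        return StateCall(
            state="ON" if on else "OFF", rule="snapshot",
            thresholds={"relative_intensity": thr},
            measurements={"relative_intensity": float(vals[0])},
        )
    if mode == "trace":
        thr = TRACE_THRESHOLD if threshold is None else threshold
        on = bool(np.any(vals >= thr))
        return StateCall(
            state="ON" if on else "OFF", rule="trace",
            thresholds={"relative_intensity": thr},
            measurements={"max_relative_intensity": float(vals.max()),
                          "n_frames": int(vals.size)},
        )
    raise ValueError(f"unknown mode {mode!r}")


def classify_rf_frame(
    anchor: SpotRecord | None,
    mcp_spots: list[SpotRecord],
    roi_mean: float,
    max_distance_nm: float = RF_MAX_DISTANCE_NM,
    min_fold: float = RF_MIN_FOLD,
    pixel_size_nm: float = PIXEL_SIZE_NM,
) -> StateCall:
    """Frame-wise ON/OFF call from locus-anchor / nascent-spot proximity.

    ON iff any MCP spot is within ``max_distance_nm`` of the anchor (<=,
    2D Euclidean on sub-pixel centers) AND its mean (disk) intensity is
    strictly greater than ``min_fold`` times ``roi_mean`` — by default the
    mean of the 19x19 analysis window around the anchor.
    """
    if anchor is None:
        raise ValueError("missing anchor spot")
    if roi_mean <= 0:
        raise ValueError("roi_mean must be > 0")
    best = None
    on = False
    for s in mcp_spots:
        d = float(np.hypot(s.y_px - anchor.y_px, s.x_px - anchor.x_px)) * pixel_size_nm
        fold = (s.disk_mean / roi_mean) if np.isfinite(s.disk_mean) else np.nan
        if best is None or d < best[0]:
            best = (d, fold)
        if d <= max_distance_nm and np.isfinite(fold) and fold > min_fold:
            on = True
            best = (d, fold)
            break
    return StateCall(
        state="ON" if on else "OFF", rule="rf_proximity",
        thresholds={"max_distance_nm": max_distance_nm, "min_fold": min_fold},
        measurements={
            "distance_nm": best[0] if best else np.nan,
            "fold": best[1] if best else np.nan,
            "n_mcp_spots": len(mcp_spots),
        },
    )


def histogram_valley(values, bw_method=None, grid_size: int = 512) -> float:
    """Estimate the valley between the first two modes of a distribution.

    Kernel-density estimate; returns the location of the minimum between the
    first two local maxima.  Used to rederive state-calling thresholds from
    data; the fixed thresholds above remain the defaults.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 10:
        raise ValueError("need at least 10 values for a density estimate")
    kde = gaussian_kde(vals, bw_method=bw_method)
    grid = np.linspace(vals.min(), vals.max(), grid_size)
    dens = kde(grid)
    maxima = [i for i in range(1, grid_size - 1) if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]]
    if len(maxima) < 2:
        raise ValueError("fewer than two modes found")
    lo, hi = maxima[0], maxima[1]
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])


def state_table(calls: list[StateCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"state": c.state, "rule": c.rule}
        row.update({f"thr_{k}": v for k, v in c.thresholds.items()})
        row.update(c.measurements)
        rows.append(row)
    return pd.DataFrame(rows)
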
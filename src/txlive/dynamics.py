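"""Locus mobility: MSCD curves and anomalous-diffusion MSD fitting.

Two complementary statistics of locus motion are provided:

* **MSCD** (mean square change in distance): with ``d(t)`` the Euclidean
  distance between the locus and the nuclear center of mass at frame ``t``,
  ``MSCD(dt) = < [d(t) - d(t + dt)]^2 >`` over all valid pairs of frames.
  Referencing the nuclear center of mass compensates whole-nucleus movement,
  so slow minutes-scale locus mobility can be compared between
  transcriptional states.
* **MSD** with an anomalous-diffusion model ``MSD(t) = 4 * D_alpha * t**alpha``
  fitted over short lags (default up to 66 steps, 2 s at 30-ms frames).
  The fit follows the statsmodels convention: construct
  :class:`AnomalousDiffusionModel` from tracks, call :meth:`fit`, and read
  estimates off the returned :class:`MsdResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MscdCurve",
    "mscd_curve",
    "average_mscd_curves",
    "time_averaged_msd",
    "fit_power_law",
    "AnomalousDiffusionModel",
    "MsdResults",
    "msd_fit",
]


# ---------------------------------------------------------------------------
# MSCD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MscdCurve:
    """MSCD versus lag, with SEM and pair counts."""

    lags_s: np.ndarray
    mscd: np.ndarray          # nm^2
    sem: np.ndarray
    n_pairs: np.ndarray
    state: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags_s, "mscd_nm2": self.mscd, "sem_nm2": self.sem,
             "n_pairs": self.n_pairs, "state": self.state}
        )


def _distance_series(track_nm: np.ndarray, centers_nm: np.ndarray) -> np.ndarray:
    track_nm = np.asarray(track_nm, dtype=float)
    centers_nm = np.asarray(centers_nm, dtype=float)
    if track_nm.shape != centers_nm.shape:
        raise ValueError("track and centers must be time-aligned with equal shapes")
    return np.linalg.norm(track_nm - centers_nm, axis=1)


def mscd_curve(
    track_nm: np.ndarray,
    centers_nm: np.ndarray,
    dt_s: float = 15.0,
    lags: np.ndarray | None = None,
    state: str = "",
) -> MscdCurve:
    """MSCD of one cell's locus track against its nuclear center of mass.

    ``track_nm``/``centers_nm`` are (n_frames, k) position arrays in nm
    (k = 2 or 3 matching the imaging dimensionality); ``dt_s`` is the frame
    interval.  For each lag the average of ``(d(t) - d(t+lag))**2`` over all
    valid frame pairs is returned with the SEM across pairs.
    """
    d = _distance_series(track_nm, centers_nm)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 frames")
    if lags is None:
        lags = np.arange(0, n)
    lags = np.asarray(lags, dtype=int)
    vals, sems, counts = [], [], []
    for lag in lags:
        if lag == 0:
            vals.append(0.0); sems.append(0.0); counts.append(n)
            continue
        if lag >= n:
            vals.append(np.nan); sems.append(np.nan); counts.append(0)
            continue
        sq = (d[:-lag] - d[lag:]) ** 2
        vals.append(float(sq.mean()))
        sems.append(float(sq.std(ddof=1) / np.sqrt(sq.size)) if sq.size > 1 else 0.0)
        counts.append(int(sq.size))
    return MscdCurve(
        lags_s=lags * dt_s,
        mscd=np.asarray(vals), sem=np.asarray(sems),
        n_pairs=np.asarray(counts, dtype=int), state=state,
    )


def average_mscd_curves(curves: list[MscdCurve], state: str = "") -> MscdCurve:
    """Average per-cell MSCD curves; SEM is computed across cells per lag."""
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags_s
    for c in curves[1:]:
        if not np.array_equal(c.lags_s, lags):
            raise ValueError("curves must share a lag grid")
    stack = np.vstack([c.mscd for c in curves])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        nvalid = np.sum(np.isfinite(stack), axis=0)
        sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(nvalid, 1))
    sem[nvalid < 2] = np.nan
    return MscdCurve(lags_s=lags, mscd=mean, sem=sem, n_pairs=nvalid, state=state)


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def time_averaged_msd(track: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD of one track (positions in any consistent unit).

    Returns MSD for lags 1..max_lag (squared input units).
    """
    track = np.asarray(track, dtype=float)
    n = track.shape[0]
    out = np.full(max_lag, np.nan)
    for lag in range(1, max_lag + 1):
        if lag >= n:
            break
        disp = track[lag:] - track[:-lag]
        out[lag - 1] = float(np.mean(np.sum(disp**2, axis=1)))
    return out


def fit_power_law(lags_s, msd, fit_space: str = "log") -> tuple[float, float, float]:
    """Fit ``MSD(t) = 4 * D_alpha * t**alpha``; returns (D_alpha, alpha, RSS).

    ``'log'`` fits a straight line to log(MSD) vs log(t) with equal weights;
    ``'linear'`` runs nonlinear least squares on the raw values.
    """
    lags = np.asarray(lags_s, dtype=float)
    msd = np.asarray(msd, dtype=float)
    if fit_space == "log":
        pos = msd > 0
        x, y = np.log(lags[pos]), np.log(msd[pos])
        A = np.vstack([np.ones_like(x), x]).T
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        alpha = float(coef[1])
        d_alpha = float(np.exp(coef[0]) / 4.0)
        rss = float(res[0]) if res.size else float(np.sum((A @ coef - y) ** 2))
        return d_alpha, alpha, rss
    if fit_space == "linear":
        popt, _ = curve_fit(
            lambda t, d, a: 4.0 * d * t**a, lags, msd,
            p0=[msd[0] / (4.0 * lags[0]), 1.0], maxfev=10000,
        )
        d_alpha, alpha = float(popt[0]), float(popt[1])
        rss = float(np.sum((4.0 * d_alpha * lags**alpha - msd) ** 2))
        return d_alpha, alpha, rss
    raise ValueError("fit_space must be 'log' or 'linear'")


@dataclass
class MsdResults:
    """Fitted anomalous-diffusion parameters and the underlying MSD curve."""

    d_alpha: float             # um^2 / s^alpha
    alpha: float
    lags_s: np.ndarray
    msd_um2: np.ndarray        # ensemble-averaged MSD over the fitted window
    residual: float            # RSS of the fit (log or linear space)
    n_tracks: int
    fit_space: str = "log"
    degenerate: bool = False   # all-zero MSD: alpha undefined, D = 0

    def predicted(self, t: np.ndarray | None = None) -> np.ndarray:
        t = self.lags_s if t is None else np.asarray(t, dtype=float)
        return 4.0 * self.d_alpha * t**self.alpha

    def summary(self) -> str:
        lines = [
            "Anomalous diffusion fit: MSD(t) = 4 * D_alpha * t^alpha",
            f"  n_tracks        : {self.n_tracks}",
            f"  fit window      : {self.lags_s[0]:.3g}-{self.lags_s[-1]:.3g} s "
            f"({self.lags_s.size} lags)",
            f"  D_alpha         : {self.d_alpha:.4g} um^2/s^alpha",
            f"  alpha           : {self.alpha:.4g}",
            f"  residual ({self.fit_space}): {self.residual:.4g}",
        ]
        if self.degenerate:
            lines.append("  WARNING: degenerate (all-zero MSD); alpha undefined")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(self.lags_s, self.msd_um2, "o", label="ensemble MSD")
        if not self.degenerate:
            ax.loglog(self.lags_s, self.predicted(), "-",
                      label=rf"$4 D_\alpha t^\alpha$ ($\alpha$={self.alpha:.2f})")
        ax.set_xlabel("lag (s)")
        ax.set_ylabel(r"MSD ($\mu m^2$)")
        ax.legend()
        return ax


class AnomalousDiffusionModel:
    """Ensemble MSD model for a set of single-locus tracks.

    Parameters
    ----------
    tracks : list of (n_frames, 2) position arrays in um (or nm with
        ``unit='nm'``).
    dt_s : frame interval in seconds.
    """

    def __init__(self, tracks, dt_s: float, unit: str = "um"):
        if len(tracks) < 1:
            raise ValueError("need at least one track")
        scale = 1e-3 if unit == "nm" else 1.0
        self.tracks = [np.asarray(t, dtype=float) * scale for t in tracks]
        self.dt_s = float(dt_s)

    def ensemble_msd(self, max_lag_steps: int) -> tuple[np.ndarray, np.ndarray]:
        curves = np.vstack(
            [time_averaged_msd(t, max_lag_steps) for t in self.tracks]
        )
        with np.errstate(invalid="ignore"):
            msd = np.nanmean(curves, axis=0)
        lags = np.arange(1, max_lag_steps + 1) * self.dt_s
        ok = np.isfinite(msd)
        return lags[ok], msd[ok]

    def fit(self, max_lag_steps: int = 66, fit_space: str = "log") -> MsdResults:
        """Least-squares fit of ``4 D_alpha t^alpha``.

        ``fit_space='log'`` (default) fits a line to log(MSD) vs log(t) with
        equal weights, which stabilizes the power law; ``'linear'`` performs
        nonlinear least squares on the raw values.
        """
        lags, msd = self.ensemble_msd(max_lag_steps)
        if np.all(msd <= 0):
            return MsdResults(
                d_alpha=0.0, alpha=np.nan, lags_s=lags, msd_um2=msd,
                residual=0.0, n_tracks=len(self.tracks), fit_space=fit_space,
                degenerate=True,
            )
        d_alpha, alpha, rss = fit_power_law(lags, msd, fit_space=fit_space)
        return MsdResults(
            d_alpha=d_alpha, alpha=alpha, lags_s=lags, msd_um2=msd,
            residual=rss, n_tracks=len(self.tracks), fit_space=fit_space,
        )


def msd_fit(tracks, dt_s: float, max_lag_steps: int = 66, unit: str = "um",
            fit_space: str = "log") -> MsdResults:
    """Functional wrapper: ensemble MSD + anomalous-diffusion fit."""
    return AnomalousDiffusionModel(tracks, dt_s, unit=unit).fit(
        max_lag_steps=max_lag_steps, fit_space=fit_space
    )
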
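"""Per-track features: TA-MSD, anomalous exponent, confinement radius, jumps.

The time-averaged mean squared displacement (TA-MSD) of a track at lag τ
(frames) is the mean squared Euclidean displacement over all pairs of
localizations τ frames apart, using every overlapping pair. The anomalous
exponent α is the log-log slope of the TA-MSD over a short lag window
(default lags 1-4, where short experimental tracks carry most information);
the confinement radius Rc is obtained from the saturating confined-diffusion
model MSD(τ) = Rc²·(1 − exp(−4·D·τ·Δt / Rc²)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .tracks_io import Track, TrackSet

__all__ = [
    "MsdCurve",
    "TrackFeatures",
    "FeatureConfig",
    "InsufficientDataError",
    "time_averaged_msd",
    "fit_anomalous_exponent",
    "fit_confinement_radius",
    "mean_jump",
    "compute_features",
    "features_frame",
]

FEATURE_COLUMNS = [
    "track_id",
    "parent_id",
    "duration",
    "alpha",
    "r_conf_um",
    "mean_jump_um",
    "motion_class",
    "fit_ok",
]


class InsufficientDataError(ValueError):
    """Track too short for the requested statistic."""


@dataclass(frozen=True)
class MsdCurve:
    """TA-MSD of one track: lag (frames), MSD (µm²), pair counts."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    frame_interval_s: float = 0.01

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags)
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(np.asarray(self.msd) < 0):
            raise ValueError("msd values must be >= 0")


@dataclass
class TrackFeatures:
    """Two-parameter record for one track or butterfly segment."""

    track_id: str
    parent_id: str = ""
    duration: int = 0
    alpha: float = math.nan
    r_conf_um: float = math.nan
    mean_jump_um: float = math.nan
    motion_class: str = ""
    fit_ok: bool = False


@dataclass(frozen=True)
class FeatureConfig:
    """Estimator settings for :func:`compute_features`."""

    max_lag: int = 50
    alpha_lag_min: int = 1
    alpha_lag_max: int = 4
    min_duration: int = 2

    def __post_init__(self) -> None:
        if self.alpha_lag_min < 1 or self.alpha_lag_max < self.alpha_lag_min:
            raise ValueError("invalid alpha lag window")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")


def time_averaged_msd(track: Track, max_lag: int | None = None,
                      frame_interval_s: float = 0.01) -> MsdCurve:
    """TA-MSD over all overlapping same-track pairs.

    Lags are frame differences, so tracks with linking gaps contribute only
    the pairs that exist; lags with zero pairs are omitted.
    """
    if track.duration < 2:
        raise InsufficientDataError(
            f"track {track.track_id!r} has {track.duration} localizations; need >= 2"
        )
    frames = np.asarray(track.frames)
    pos = track.positions()
    span = int(frames[-1] - frames[0])
    top = span if max_lag is None else min(max_lag, span)
    gap_free = span == track.duration - 1
    lags, msds, counts = [], [], []
    for tau in range(1, top + 1):
        if gap_free:
            d = pos[tau:] - pos[:-tau]
        else:
            i_idx = np.nonzero(np.isin(frames + tau, frames))[0]
            if i_idx.size == 0:
                continue
            j_idx = np.searchsorted(frames, frames[i_idx] + tau)
            d = pos[j_idx] - pos[i_idx]
        lags.append(tau)
        msds.append(float(np.mean(np.sum(d * d, axis=1))))
        counts.append(len(d))
    return MsdCurve(
        lags=np.array(lags, dtype=int),
        msd=np.array(msds, dtype=float),
        n_pairs=np.array(counts, dtype=int),
        frame_interval_s=frame_interval_s,
    )


def fit_anomalous_exponent(
    curve: MsdCurve, lag_range: tuple[int, int] = (1, 4)
) -> tuple[float, bool]:
    """Log-log slope of the TA-MSD over an inclusive lag window.

    Returns ``(alpha, fit_ok)``. Lags with MSD ≤ 0 are excluded; fewer than
    two usable lags flags the fit as failed (alpha = NaN).
    """
    lo, hi = lag_range
    sel = (curve.lags >= lo) & (curve.lags <= hi) & (curve.msd > 0)
    if sel.sum() < 2:
        return math.nan, False
    slope = np.polyfit(np.log(curve.lags[sel]), np.log(curve.msd[sel]), 1)[0]
    return float(slope), True


def _confined_model(tau: np.ndarray, rc: float, d: float, dt: float) -> np.ndarray:
    rc2 = rc * rc
    return rc2 * (1.0 - np.exp(-4.0 * d * tau * dt / rc2))


def fit_confinement_radius(curve: MsdCurve) -> tuple[float, bool]:
    """Confinement radius Rc (µm) from the saturating confined-MSD model.

    Fits MSD(τ) = Rc²·(1 − exp(−4·D·τ·Δt/Rc²)) by nonlinear least squares.
    Returns ``(r_conf, converged)``; if the fit fails, the fallback is the
    square root of the mean MSD over the last quartile of lags (the plateau
    estimate) with ``converged = False``. An all-zero curve gives 0.
    """
    if len(curve.lags) < 3:
        raise InsufficientDataError("need >= 3 lags to estimate a confinement radius")
    dt = curve.frame_interval_s
    msd = curve.msd
    if np.all(msd <= 0):
        return 0.0, False
    n_tail = max(1, len(msd) // 4)
    plateau = float(np.mean(msd[-n_tail:]))
    rc0 = math.sqrt(max(plateau, 1e-12))
    d0 = max(msd[0] / (4.0 * curve.lags[0] * dt), 1e-9)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda tau, rc, d: _confined_model(tau, rc, d, dt),
                curve.lags.astype(float),
                msd,
                p0=(rc0, d0),
                bounds=((1e-9, 1e-12), (np.inf, np.inf)),
                maxfev=10_000,
            )
        rc = float(popt[0])
        if not math.isfinite(rc) or rc <= 0:
            raise RuntimeError("degenerate fit")
        return rc, True
    except (RuntimeError, ValueError):
        return math.sqrt(max(plateau, 0.0)), False


def mean_jump(track: Track) -> tuple[float, bool]:
    """Mean frame-to-frame displacement (µm) over consecutive-frame pairs.

    Pairs separated by a linking gap are excluded ("frame-to-frame" is
    literal). Returns ``(value, ok)``; ``ok`` is False when the track has no
    consecutive-frame pair at all.
    """
    if track.duration < 2:
        raise InsufficientDataError("mean jump needs >= 2 localizations")
    frames = np.asarray(track.frames)
    pos = track.positions()
    consec = np.diff(frames) == 1
    if not consec.any():
        return math.nan, False
    d = np.diff(pos, axis=0)[consec]
    return float(np.mean(np.hypot(d[:, 0], d[:, 1]))), True


def compute_features(
    track: Track,
    config: FeatureConfig | None = None,
    *,
    parent_id: str = "",
    frame_interval_s: float = 0.01,
) -> TrackFeatures:
    """Populate a :class:`TrackFeatures` record (motion class left unset)."""
    config = config or FeatureConfig()
    feats = TrackFeatures(
        track_id=track.track_id, parent_id=parent_id, duration=track.duration
    )
    if track.duration < max(2, config.min_duration):
        return feats
    curve = time_averaged_msd(
        track, max_lag=config.max_lag, frame_interval_s=frame_interval_s
    )
    alpha, alpha_ok = fit_anomalous_exponent(
        curve, (config.alpha_lag_min, config.alpha_lag_max)
    )
    feats.alpha = alpha
    jump, jump_ok = mean_jump(track)
    feats.mean_jump_um = jump
    if len(curve.lags) >= 3:
        rc, _ = fit_confinement_radius(curve)
        feats.r_conf_um = rc
    feats.fit_ok = alpha_ok and jump_ok
    return feats


def features_frame(features: list[TrackFeatures]) -> pd.DataFrame:
    """Stack feature records into the canonical two-parameter table."""
    if not features:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    return pd.DataFrame(
        [
            {
                "track_id": f.track_id,
                "parent_id": f.parent_id,
                "duration": f.duration,
                "alpha": f.alpha,
                "r_conf_um": f.r_conf_um,
                "mean_jump_um": f.mean_jump_um,
                "motion_class": f.motion_class,
                "fit_ok": f.fit_ok,
            }
            for f in features
        ],
        columns=FEATURE_COLUMNS,
    )
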
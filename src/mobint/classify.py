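"""Motion-class assignment, butterfly segmentation, filters, down-sampling.

Tracks are classified from the anomalous exponent α of their TA-MSD:
α ≤ 0.7 Confined, 0.7 < α < 1 Brownian, α ≥ 1 Directed. Tracks mixing
confined and free behaviour ("butterfly" tracks, after their appearance in
a position-time plot) are detected by an outlier jump and split into
sub-trajectories that re-enter feature extraction and classification on
their own. Quality filters: tracks shorter than five frames are discarded
up front, and Confined tracks (including confined butterfly segments) with
a mean frame-to-frame jump above 100 nm are removed. Final tables are
randomly down-sampled to a fixed per-replicate track budget (default
20,000, in triplicate) so conditions with different track yields are
compared on equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msd import FeatureConfig, compute_features, features_frame
from .tracks_io import Track, TrackSet

__all__ = [
    "ClassifyConfig",
    "ClassificationResult",
    "classify_alpha",
    "detect_butterfly_splits",
    "segment_butterfly",
    "apply_duration_filter",
    "apply_confined_jump_filter",
    "downsample_tracks",
    "run_classification",
]

CONFINED = "Confined"
BROWNIAN = "Brownian"
DIRECTED = "Directed"
BUTTERFLY = "Butterfly"

_BUTTERFLY_RULES = ("relative", "additive_sd", "absolute")


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds of the classification pipeline.

    Defaults quote the published analysis: α bands at 0.7 and 1.0, a
    relative butterfly jump threshold of 1.5 (an outlier jump exceeds the
    track's mean jump by 150%, i.e. jump > 2.5× mean), a 5-frame minimum
    duration, a 100 nm confined-jump ceiling and 20,000-track triplicate
    down-sampling.
    """

    alpha_confined_max: float = 0.7
    alpha_directed_min: float = 1.0
    butterfly_rule: str = "relative"
    butterfly_threshold: float = 1.5
    min_duration: int = 5
    confined_jump_max_um: float = 0.1
    downsample_n: int = 20_000
    downsample_reps: int = 3
    seed: int = 0
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha_confined_max < self.alpha_directed_min:
            raise ValueError("need 0 < alpha_confined_max < alpha_directed_min")
        if self.butterfly_rule not in _BUTTERFLY_RULES:
            raise ValueError(f"butterfly_rule must be one of {_BUTTERFLY_RULES}")
        if self.butterfly_threshold <= 0:
            raise ValueError("butterfly_threshold must be > 0")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.confined_jump_max_um <= 0:
            raise ValueError("confined_jump_max_um must be > 0")
        if self.downsample_n < 0 or self.downsample_reps < 1:
            raise ValueError("invalid down-sampling settings")


def classify_alpha(alpha: float, config: ClassifyConfig | None = None) -> str:
    """Motion class from the anomalous exponent (boundaries as published)."""
    config = config or ClassifyConfig()
    if not np.isfinite(alpha):
        raise ValueError("cannot classify a non-finite anomalous exponent")
    if alpha <= config.alpha_confined_max:
        return CONFINED
    if alpha < config.alpha_directed_min:
        return BROWNIAN
    return DIRECTED


def _jumps(track: Track) -> np.ndarray:
    pos = track.positions()
    d = np.diff(pos, axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def detect_butterfly_splits(
    track: Track, config: ClassifyConfig | None = None
) -> list[int]:
    """Indices of outlier steps that split a track into sub-trajectories.

    Step ``i`` is the displacement between localizations ``i`` and ``i+1``.
    Under the default ``relative`` rule a step is an outlier when it exceeds
    the track's mean jump by the threshold as a fraction (1.5 → 2.5× mean);
    ``additive_sd`` uses mean + threshold·s.d. of the jumps; ``absolute``
    compares against a fixed length in µm. Tracks shorter than the minimum
    duration yield no splits.
    """
    config = config or ClassifyConfig()
    if track.duration < max(2, config.min_duration):
        return []
    jumps = _jumps(track)
    if config.butterfly_rule == "relative":
        cutoff = jumps.mean() * (1.0 + config.butterfly_threshold)
    elif config.butterfly_rule == "additive_sd":
        cutoff = jumps.mean() + config.butterfly_threshold * jumps.std(ddof=0)
    else:
        cutoff = config.butterfly_threshold
    return [int(i) for i in np.nonzero(jumps > cutoff)[0]]


def segment_butterfly(
    track: Track, splits: list[int], *, min_duration: int = 1
) -> list[Track]:
    """Partition a track at outlier steps into sub-trajectories.

    The outlier displacement itself belongs to neither segment: a split at
    step ``i`` ends one segment at localization ``i`` and starts the next at
    ``i+1``. Segments shorter than ``min_duration`` are discarded. With no
    splits the original track is returned unchanged.
    """
    if not splits:
        return [track]
    bad = [s for s in splits if not 0 <= s < track.duration - 1]
    if bad:
        raise ValueError(f"split indices out of range: {bad}")
    bounds = [0] + [s + 1 for s in sorted(splits)] + [track.duration]
    segments = []
    for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if b - a >= min_duration:
            segments.append(
                Track(
                    track_id=f"{track.track_id}:seg{k}",
                    localizations=track.localizations[a:b],
                )
            )
    return segments


def apply_duration_filter(trackset: TrackSet, min_duration: int = 5) -> TrackSet:
    """Discard tracks with fewer localizations than ``min_duration``."""
    return trackset.with_tracks(
        t for t in trackset if t.duration >= min_duration
    )


def apply_confined_jump_filter(
    features: pd.DataFrame, max_um: float = 0.1
) -> pd.DataFrame:
    """Drop Confined rows (incl. confined segments) with mean jump > max_um.

    Non-confined rows pass through untouched; the operation is idempotent.
    """
    if features.empty:
        return features
    drop = (features["motion_class"] == CONFINED) & (
        features["mean_jump_um"] > max_um
    )
    return features.loc[~drop].reset_index(drop=True)


def downsample_tracks(
    features: pd.DataFrame, n: int = 20_000, reps: int = 3, seed: int = 0
) -> list[pd.DataFrame]:
    """``reps`` uniform random subsets of ``min(n, len)`` rows each.

    Replicate ``i`` draws without replacement from an independent generator
    seeded ``seed + i``, so a single master seed reproduces the triplicate.
    """
    out = []
    for i in range(reps):
        rng = np.random.default_rng(seed + i)
        k = min(n, len(features))
        idx = rng.choice(len(features), size=k, replace=False)
        out.append(features.iloc[np.sort(idx)].reset_index(drop=True))
    return out


@dataclass
class ClassificationResult:
    """Output of :func:`run_classification`."""

    features: pd.DataFrame
    replicates: list[pd.DataFrame]
    butterfly_parents: list[str]
    stage_log: dict[str, int]


def run_classification(
    trackset: TrackSet, config: ClassifyConfig | None = None
) -> ClassificationResult:
    """Full classification pipeline for one TrackSet.

    Stage order: duration filter → feature extraction → butterfly detection
    and segmentation → segment feature extraction → α classification →
    confined-jump filter → down-sampling. Butterfly parents are excluded
    from the final two-parameter table; their qualifying segments carry
    ``parent_id`` and are classified individually.
    """
    config = config or ClassifyConfig()
    log: dict[str, int] = {"input_tracks": len(trackset)}

    kept = apply_duration_filter(trackset, config.min_duration)
    log["after_duration_filter"] = len(kept)

    feat_cfg = config.features
    records = []
    butterfly_parents: list[str] = []
    for track in kept:
        splits = detect_butterfly_splits(track, config)
        if splits:
            butterfly_parents.append(track.track_id)
            pieces = segment_butterfly(
                track, splits, min_duration=config.min_duration
            )
            for seg in pieces:
                records.append(
                    compute_features(
                        seg,
                        feat_cfg,
                        parent_id=track.track_id,
                        frame_interval_s=kept.frame_interval_s,
                    )
                )
        else:
            records.append(
                compute_features(
                    track, feat_cfg, frame_interval_s=kept.frame_interval_s
                )
            )
    log["butterfly_parents"] = len(butterfly_parents)

    for rec in records:
        if rec.fit_ok:
            rec.motion_class = classify_alpha(rec.alpha, config)
    table = features_frame(records)
    n_unfit = int((~table["fit_ok"]).sum()) if len(table) else 0
    table = table[table["fit_ok"]].reset_index(drop=True)
    log["dropped_fit_failures"] = n_unfit
    log["classified_rows"] = len(table)

    table = apply_confined_jump_filter(table, config.confined_jump_max_um)
    log["after_confined_jump_filter"] = len(table)

    replicates = downsample_tracks(
        table, n=config.downsample_n, reps=config.downsample_reps, seed=config.seed
    )
    log["replicate_size"] = len(replicates[0]) if replicates else 0
    return ClassificationResult(
        features=table,
        replicates=replicates,
        butterfly_parents=butterfly_parents,
        stage_log=log,
    )
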
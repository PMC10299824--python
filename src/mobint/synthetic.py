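"""Synthetic trajectory and proteomics generators with known ground truth.

Every downstream stage of the package is testable against data generated
here: 2D single-molecule trajectories drawn from confined / Brownian /
directed / switching ("butterfly") motion models with Gaussian localization
error, and label-free proteomics intensity matrices with planted interactor
effects and intensity-dependent (left-censored) missingness.

The default motion parameters describe a chromatin-bound transcription
factor imaged stroboscopically at 100 Hz:

* confined — D = 0.05 µm²/s inside a reflecting disk of radius 50 nm, so a
  track explores its confinement zone within a few frames (4DΔt/Rc² ≈ 0.8)
  and its MSD exponent sits well below the 0.7 gate;
* brownian — D = 0.3 µm²/s, free diffusion;
* directed — D = 0.02 µm²/s plus 5 µm/s drift, so the drift term dominates
  the short-lag MSD and the exponent sits well above 1;
* butterfly — confined until a switch frame, directed afterwards, joined
  continuously.

Localization error defaults to 30 nm per coordinate, typical of dye-based
single-molecule imaging; it adds a constant 4σ² offset to every MSD curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks_io import Localization, Track, TrackSet

__all__ = [
    "MotionSpec",
    "ExperimentSpec",
    "ProteomicsSpec",
    "DEFAULT_CLASS_SPECS",
    "simulate_track",
    "simulate_experiment",
    "simulate_h2b_reference",
    "simulate_proteomics",
]

MOTION_CLASSES = ("brownian", "confined", "directed", "butterfly")


@dataclass(frozen=True)
class MotionSpec:
    """Parameters of one generative motion model.

    D is the diffusion coefficient (µm²/s), Rc the confinement radius (µm,
    confined/butterfly only), v the drift speed (µm/s, directed/butterfly),
    heading the drift direction (rad), sigma_loc the per-coordinate
    localization error s.d. (µm) and switch_frame the frame at which a
    butterfly track changes regime (None = mid-track).
    """

    motion_class: str
    D: float = 0.1
    Rc: float | None = None
    v: float = 0.0
    heading: float = 0.0
    sigma_loc: float = 0.0
    switch_frame: int | None = None

    def __post_init__(self) -> None:
        if self.motion_class not in MOTION_CLASSES:
            raise ValueError(f"unknown motion class {self.motion_class!r}")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.motion_class in ("confined", "butterfly"):
            if self.Rc is None or self.Rc <= 0:
                raise ValueError("Rc must be > 0 for confined/butterfly motion")


#: Well-separated per-class defaults used by :func:`simulate_experiment`.
DEFAULT_CLASS_SPECS: Mapping[str, MotionSpec] = {
    "confined": MotionSpec("confined", D=0.05, Rc=0.05, sigma_loc=0.03),
    "brownian": MotionSpec("brownian", D=0.3, sigma_loc=0.03),
    "directed": MotionSpec("directed", D=0.02, v=5.0, sigma_loc=0.03),
    "butterfly": MotionSpec("butterfly", D=0.05, Rc=0.05, v=5.0, sigma_loc=0.03),
}


@dataclass(frozen=True)
class ExperimentSpec:
    """A mixture experiment: how many tracks, of which classes, how long."""

    n_tracks: int = 1000
    mixture_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "confined": 0.4,
            "brownian": 0.3,
            "directed": 0.2,
            "butterfly": 0.1,
        }
    )
    class_specs: Mapping[str, MotionSpec] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SPECS)
    )
    #: geometric success parameter of the track-length law (photobleaching
    #: survival); mean length = 1/p above the minimum.
    length_geom_p: float = 0.05
    min_length: int = 1
    fixed_length: int | None = None
    frame_interval_s: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 0:
            raise ValueError("n_tracks must be >= 0")
        w = self.mixture_weights
        if any(v < 0 for v in w.values()):
            raise ValueError("mixture weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        unknown = set(w) - set(MOTION_CLASSES)
        if unknown:
            raise ValueError(f"unknown motion classes in weights: {unknown}")
        if not 0 < self.length_geom_p <= 1:
            raise ValueError("length_geom_p must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def _reflect_radius(r: float, rc: float) -> float:
    # mirror at the circle; repeat for (rare) steps longer than the diameter
    for _ in range(64):
        if r <= rc:
            return r
        r = abs(2.0 * rc - r)
    return min(r, rc)


def _confined_path(
    n: int, d: float, rc: float, dt: float, rng: np.random.Generator,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Random walk reflected at a circle of radius ``rc`` about the start."""
    centre = np.zeros(2) if start is None else np.asarray(start, float)
    pos = np.empty((n, 2))
    pos[0] = centre
    steps = rng.normal(0.0, math.sqrt(2.0 * d * dt), size=(n - 1, 2)) if n > 1 else None
    p = centre.copy()
    for i in range(1, n):
        p = p + steps[i - 1]
        rel = p - centre
        r = math.hypot(rel[0], rel[1])
        if r > rc:
            r_new = _reflect_radius(r, rc)
            rel *= r_new / r
            p = centre + rel
        pos[i] = p
    return pos


def _free_path(
    n: int, d: float, dt: float, rng: np.random.Generator,
    drift: np.ndarray | None = None, start: np.ndarray | None = None,
) -> np.ndarray:
    pos = np.zeros((n, 2)) if start is None else np.tile(np.asarray(start, float), (n, 1))
    if n > 1:
        steps = rng.normal(0.0, math.sqrt(2.0 * d * dt), size=(n - 1, 2))
        if drift is not None:
            steps = steps + drift
        pos[1:] += np.cumsum(steps, axis=0)
    return pos


def simulate_track(
    spec: MotionSpec,
    n_frames: int,
    rng: np.random.Generator,
    *,
    frame_interval_s: float = 0.01,
    track_id: str = "sim",
) -> Track:
    """Simulate one 2D trajectory of ``n_frames`` localizations.

    Per-axis displacement variance per frame is 2·D·Δt; confined motion is
    reflected at a circle of radius Rc about the start; directed motion adds
    v·Δt drift along ``heading``; butterfly tracks are confined before
    ``switch_frame`` and directed afterwards, continuous at the switch.
    Independent Gaussian noise (s.d. sigma_loc) is added to every reported
    coordinate.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    dt = frame_interval_s
    cls = spec.motion_class
    if cls == "brownian":
        pos = _free_path(n_frames, spec.D, dt, rng)
    elif cls == "directed":
        drift = spec.v * dt * np.array([math.cos(spec.heading), math.sin(spec.heading)])
        pos = _free_path(n_frames, spec.D, dt, rng, drift=drift)
    elif cls == "confined":
        pos = _confined_path(n_frames, spec.D, spec.Rc, dt, rng)
    elif cls == "butterfly":
        switch = spec.switch_frame if spec.switch_frame is not None else n_frames // 2
        if not 0 < switch < n_frames:
            raise ValueError(f"switch_frame must lie inside the track, got {switch}")
        first = _confined_path(switch + 1, spec.D, spec.Rc, dt, rng)
        drift = spec.v * dt * np.array([math.cos(spec.heading), math.sin(spec.heading)])
        second = _free_path(n_frames - switch, spec.D, dt, rng, drift=drift, start=first[-1])
        pos = np.vstack([first[:-1], second])
    else:  # pragma: no cover - guarded by MotionSpec validation
        raise ValueError(cls)
    if spec.sigma_loc > 0:
        pos = pos + rng.normal(0.0, spec.sigma_loc, size=pos.shape)
    locs = tuple(
        Localization(frame=i, x=float(pos[i, 0]), y=float(pos[i, 1]))
        for i in range(n_frames)
    )
    return Track(track_id=track_id, localizations=locs)


def _draw_length(spec: ExperimentSpec, rng: np.random.Generator) -> int:
    if spec.fixed_length is not None:
        return int(spec.fixed_length)
    return int(spec.min_length - 1 + rng.geometric(spec.length_geom_p))


def simulate_experiment(
    spec: ExperimentSpec, *, condition: str = "synthetic"
) -> tuple[TrackSet, pd.DataFrame]:
    """Simulate a mixture of tracks; return the TrackSet and a truth table.

    The truth table is keyed by track_id and records the generating class
    and parameters. Class assignment is multinomial with the spec weights;
    directed and butterfly headings are drawn uniformly per track.
    """
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.mixture_weights)
    probs = np.array([spec.mixture_weights[c] for c in classes])
    tracks: list[Track] = []
    rows: list[dict] = []
    for i in range(spec.n_tracks):
        cls = classes[rng.choice(len(classes), p=probs)]
        base = spec.class_specs[cls]
        if cls in ("directed", "butterfly"):
            base = replace(base, heading=float(rng.uniform(0.0, 2.0 * math.pi)))
        n = max(_draw_length(spec, rng), 1)
        if cls == "butterfly" and n < 4:
            n = 4  # a switching track needs room for both regimes
        if cls == "butterfly":
            base = replace(base, switch_frame=n // 2)
        tid = f"t{i:06d}"
        tracks.append(
            simulate_track(
                base, n, rng, frame_interval_s=spec.frame_interval_s, track_id=tid
            )
        )
        rows.append(
            {
                "track_id": tid,
                "motion_class": cls,
                "n_frames": n,
                "D": base.D,
                "Rc": base.Rc if base.Rc is not None else np.nan,
                "v": base.v,
                "sigma_loc": base.sigma_loc,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["track_id", "motion_class", "n_frames", "D", "Rc", "v", "sigma_loc"],
    )
    ts = TrackSet(
        tracks=tuple(tracks),
        frame_interval_s=spec.frame_interval_s,
        condition=condition,
    )
    return ts, truth


def simulate_h2b_reference(
    n_tracks: int,
    rng: np.random.Generator | int | None = 0,
    *,
    confined_fraction: float = 0.85,
    confined_spec: MotionSpec = MotionSpec("confined", D=0.03, Rc=0.04, sigma_loc=0.03),
    mobile_spec: MotionSpec = MotionSpec("brownian", D=0.3, sigma_loc=0.03),
    length_geom_p: float = 0.02,
    min_length: int = 10,
    frame_interval_s: float = 0.01,
) -> tuple[TrackSet, pd.DataFrame]:
    """Histone H2B-like calibration data: mostly chromatin-incorporated.

    Histone tracks are dominated by nucleosome-bound molecules with a small
    confinement radius and small jumps; a minor free fraction provides the
    mobile tail of the two-parameter distribution.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    weights = {
        "confined": confined_fraction,
        "brownian": 1.0 - confined_fraction,
        "directed": 0.0,
        "butterfly": 0.0,
    }
    spec = ExperimentSpec(
        n_tracks=n_tracks,
        mixture_weights=weights,
        class_specs={**dict(DEFAULT_CLASS_SPECS),
                     "confined": confined_spec, "brownian": mobile_spec},
        length_geom_p=length_geom_p,
        min_length=min_length,
        frame_interval_s=frame_interval_s,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ts, truth = simulate_experiment(spec, condition="H2B")
    return ts, truth


# --------------------------------------------------------------------------
# Proteomics
# --------------------------------------------------------------------------

#: Canonical TurboID pulldown design: two bait groups and two controls.
CANONICAL_GROUPS = ("WT", "R35A", "TurboID", "noDox")


@dataclass(frozen=True)
class ProteomicsSpec:
    """Synthetic label-free proteomics experiment (4 groups × 4 replicates).

    Baseline protein abundances are log-normal (log2 ~ Normal(baseline
    mean, sd)); ``planted`` adds per-group log2 effects for chosen protein
    indices; ``missing_x0``/``missing_scale`` parameterize logistic
    left-censoring, P(missing | log2 x) = expit((missing_x0 − x) /
    missing_scale), so low-intensity values are preferentially lost.
    """

    n_proteins: int = 1000
    groups: Sequence[str] = CANONICAL_GROUPS
    n_replicates: int = 4
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    replicate_log2_sd: float = 0.3
    #: list of (protein index, {group: log2 effect})
    planted: Sequence[tuple[int, Mapping[str, float]]] = ()
    #: fix the baseline log2 abundance of planted proteins (None = drawn
    #: like any other protein). Pinning it at or above the cohort mean
    #: keeps the planted enrichment measurable: a control-group abundance
    #: below the detection floor would be censored and re-appear at the
    #: imputation floor, compressing the realized fold change.
    planted_baseline_log2: float | None = None
    missing_enabled: bool = True
    missing_x0: float = 22.0
    missing_scale: float = 1.0
    contaminant_rate: float = 0.0
    reverse_rate: float = 0.0
    only_by_site_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        if self.n_replicates != 4:
            raise ValueError(
                "the canonical design has four replicates per group"
            )
        for rate in (self.contaminant_rate, self.reverse_rate, self.only_by_site_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("flag rates must be probabilities")
        for idx, effects in self.planted:
            if not 0 <= idx < self.n_proteins:
                raise ValueError(f"planted protein index {idx} out of range")
            unknown = set(effects) - set(self.groups)
            if unknown:
                raise ValueError(f"planted effects name unknown groups: {unknown}")


def simulate_proteomics(spec: ProteomicsSpec):
    """Generate an :class:`~mobint.interactome.IntensityMatrix` plus truth.

    Returns ``(matrix, truth)`` where truth has one row per protein with its
    baseline log2 mean and any planted per-group effect.
    """
    from .interactome import IntensityMatrix

    rng = np.random.default_rng(spec.seed)
    proteins = [f"P{i:05d}" for i in range(spec.n_proteins)]
    samples = [f"{g}_{r + 1}" for g in spec.groups for r in range(spec.n_replicates)]
    design = pd.Series(
        {s: s.rsplit("_", 1)[0] for s in samples}, name="group", dtype=object
    )

    base = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_proteins)
    effects = np.zeros((spec.n_proteins, len(samples)))
    planted_map: dict[int, Mapping[str, float]] = {i: e for i, e in spec.planted}
    if spec.planted_baseline_log2 is not None and planted_map:
        base[list(planted_map)] = spec.planted_baseline_log2
    for idx, per_group in planted_map.items():
        for j, s in enumerate(samples):
            effects[idx, j] = per_group.get(design[s], 0.0)
    log2 = (
        base[:, None]
        + effects
        + rng.normal(0.0, spec.replicate_log2_sd, (spec.n_proteins, len(samples)))
    )

    intensities = pd.DataFrame(
        np.exp2(log2), index=proteins, columns=samples, dtype=float
    )
    if spec.missing_enabled and spec.n_proteins:
        from scipy.special import expit

        p_missing = expit((spec.missing_x0 - log2) / spec.missing_scale)
        mask = rng.random(log2.shape) < p_missing
        intensities = intensities.mask(mask)

    flags = pd.DataFrame(
        {
            "contaminant": rng.random(spec.n_proteins) < spec.contaminant_rate,
            "reverse": rng.random(spec.n_proteins) < spec.reverse_rate,
            "only_by_site": rng.random(spec.n_proteins) < spec.only_by_site_rate,
        },
        index=proteins,
    )

    truth = pd.DataFrame(
        {
            "protein": proteins,
            "baseline_log2": base,
            "is_planted": [i in planted_map for i in range(spec.n_proteins)],
        }
    )
    for g in spec.groups:
        truth[f"effect_{g}"] = [
            planted_map.get(i, {}).get(g, 0.0) for i in range(spec.n_proteins)
        ]
    matrix = IntensityMatrix(intensities=intensities, flags=flags, design=design)
    return matrix, truth
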
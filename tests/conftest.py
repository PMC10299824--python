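import numpy as np
import pandas as pd
import pytest

from mobint import (
    ExperimentSpec,
    IntensityMatrix,
    Localization,
    ProteomicsSpec,
    Track,
    TrackSet,
    simulate_experiment,
    simulate_proteomics,
)


def make_track(points, track_id="t", frames=None):
    """Build a Track from (x, y) pairs; frames default to 0..n-1."""
    if frames is None:
        frames = range(len(points))
    return Track(
        track_id=track_id,
        localizations=tuple(
            Localization(frame=f, x=float(x), y=float(y))
            for f, (x, y) in zip(frames, points)
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trackset():
    t1 = make_track([(0.0, 0.0), (0.1, 0.0), (0.1, 0.1)], "t1")
    t2 = make_track([(1.0, 1.0), (1.2, 1.0)], "t2")
    return TrackSet(tracks=(t1, t2), condition="unit")


@pytest.fixture(scope="session")
def mixture_run():
    """A moderately sized well-separated mixture with truth, shared by tests."""
    spec = ExperimentSpec(n_tracks=300, fixed_length=500, seed=42)
    return simulate_experiment(spec)


@pytest.fixture(scope="session")
def planted_proteomics():
    """1,000-protein matrix with 20 planted 8-fold interactors plus truth."""
    planted = [(i, {"WT": 3.0, "R35A": 3.0}) for i in range(20)]
    spec = ProteomicsSpec(
        n_proteins=1000,
        planted=planted,
        planted_baseline_log2=28.0,
        contaminant_rate=0.02,
        reverse_rate=0.01,
        only_by_site_rate=0.01,
        seed=7,
    )
    return simulate_proteomics(spec)


def tiny_matrix(values, design=None, flags=None):
    """IntensityMatrix from a proteins x samples array of linear values."""
    df = pd.DataFrame(values)
    df.index = [f"P{i}" for i in range(len(df))]
    if design is None:
        design = {c: "G1" for c in df.columns}
    if flags is None:
        flags = pd.DataFrame(
            {k: [False] * len(df) for k in ("contaminant", "reverse", "only_by_site")},
            index=df.index,
        )
    return IntensityMatrix(
        intensities=df, flags=flags, design=pd.Series(design, dtype=object)
    )
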
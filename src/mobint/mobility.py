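"""Two-parameter chromatin-mobility gating against an H2B reference.

Each retained track or segment contributes a point in the (radius of
confinement, mean frame-to-frame jump) plane. Low-mobility chromatin
(LoMC, compact) and high-mobility chromatin (HiMC, open) are axis-aligned
rectangular gates calibrated on the two-parameter distribution of histone
H2B tracks: LoMC is the region below a low percentile of both H2B
marginals, HiMC the region above a high percentile of both. Gate fractions
per down-sampled replicate, summarized as mean ± s.d., quantify how much a
factor occupies compact versus open chromatin in each condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "MobilityGate",
    "MobilitySummary",
    "CalibrationError",
    "calibrate_gates",
    "assign_gate",
    "summarize_mobility",
    "compare_conditions",
]

LOMC = "LoMC"
HIMC = "HiMC"
NEITHER = "neither"


class CalibrationError(ValueError):
    """Calibration data insufficient or percentile settings degenerate."""


@dataclass(frozen=True)
class MobilityGate:
    """Axis-aligned rectangle in (r_conf, mean_jump) space; bounds in µm.

    ``None`` bounds are open (±∞); membership is boundary-inclusive.
    """

    name: str
    r_conf_min: float | None = None
    r_conf_max: float | None = None
    mean_jump_min: float | None = None
    mean_jump_max: float | None = None

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.r_conf_min, self.r_conf_max),
            (self.mean_jump_min, self.mean_jump_max),
        ):
            if lo is not None and hi is not None and lo >= hi:
                raise ValueError(f"gate {self.name!r}: lower bound must be < upper")

    def contains(self, r_conf: float, mean_jump: float) -> bool:
        if not (np.isfinite(r_conf) and np.isfinite(mean_jump)):
            return False
        for v, lo, hi in (
            (r_conf, self.r_conf_min, self.r_conf_max),
            (mean_jump, self.mean_jump_min, self.mean_jump_max),
        ):
            if lo is not None and v < lo:
                return False
            if hi is not None and v > hi:
                return False
        return True


def calibrate_gates(
    h2b_features: pd.DataFrame, lo_pct: float = 75.0, hi_pct: float = 95.0
) -> tuple[MobilityGate, MobilityGate]:
    """Calibrate the LoMC and HiMC gates on an H2B feature table.

    LoMC = both features at or below their ``lo_pct`` H2B percentile;
    HiMC = both features at or above their ``hi_pct`` percentile. With
    ``lo_pct < hi_pct`` the rectangles are disjoint by construction.
    Requires at least 100 calibration rows.
    """
    if not lo_pct < hi_pct:
        raise CalibrationError(
            f"lo_pct ({lo_pct}) must be strictly below hi_pct ({hi_pct})"
        )
    rows = h2b_features.dropna(subset=["r_conf_um", "mean_jump_um"])
    if len(rows) < 100:
        raise CalibrationError(
            f"need >= 100 calibration rows, got {len(rows)}"
        )
    r = rows["r_conf_um"].to_numpy(float)
    j = rows["mean_jump_um"].to_numpy(float)
    lomc = MobilityGate(
        LOMC,
        r_conf_max=float(np.percentile(r, lo_pct)),
        mean_jump_max=float(np.percentile(j, lo_pct)),
    )
    himc = MobilityGate(
        HIMC,
        r_conf_min=float(np.percentile(r, hi_pct)),
        mean_jump_min=float(np.percentile(j, hi_pct)),
    )
    return lomc, himc


def assign_gate(
    features: pd.DataFrame, gates: tuple[MobilityGate, MobilityGate]
) -> pd.Series:
    """Label each feature row LoMC / HiMC / neither (boundaries inclusive).

    Rows with missing feature values are labelled ``neither``. When a
    degenerate calibration makes the rectangles overlap, LoMC wins.
    """
    lomc, himc = gates
    labels = []
    for r_conf, jump in zip(features["r_conf_um"], features["mean_jump_um"]):
        if lomc.contains(r_conf, jump):
            labels.append(LOMC)
        elif himc.contains(r_conf, jump):
            labels.append(HIMC)
        else:
            labels.append(NEITHER)
    return pd.Series(labels, index=features.index, name="mobility_gate")


@dataclass(frozen=True)
class MobilitySummary:
    """Per-replicate gate fractions plus across-replicate mean ± s.d."""

    per_replicate: pd.DataFrame  # columns: replicate, gate, fraction, n
    stats: pd.DataFrame  # index: gate; columns: mean, sd, n_replicates


def summarize_mobility(
    replicates: list[pd.DataFrame], gates: tuple[MobilityGate, MobilityGate]
) -> MobilitySummary:
    """Gate fractions per down-sampled replicate, then mean ± s.d. per gate.

    The s.d. uses the n−1 denominator; a single replicate reports s.d. 0.
    Empty replicates yield NaN fractions and are flagged by ``n = 0``.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    rows = []
    for i, rep in enumerate(replicates):
        labels = assign_gate(rep, gates) if len(rep) else pd.Series(dtype=object)
        n = len(rep)
        for gate in (LOMC, HIMC):
            frac = float((labels == gate).sum()) / n if n else math.nan
            rows.append({"replicate": i, "gate": gate, "fraction": frac, "n": n})
    per_rep = pd.DataFrame(rows)
    stats_rows = {}
    for gate in (LOMC, HIMC):
        vals = per_rep.loc[per_rep["gate"] == gate, "fraction"].dropna().to_numpy()
        mean = float(np.mean(vals)) if vals.size else math.nan
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        stats_rows[gate] = {"mean": mean, "sd": sd, "n_replicates": int(vals.size)}
    return MobilitySummary(
        per_replicate=per_rep, stats=pd.DataFrame(stats_rows).T
    )


def compare_conditions(
    summaries: dict[str, MobilitySummary]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy long table of gate fractions plus pairwise condition differences.

    Returns ``(long, diffs)`` where ``long`` has one row per (condition,
    replicate, gate) — the input a two-way ANOVA with multiple comparisons
    consumes — and ``diffs`` lists mean-fraction differences for every
    condition pair and gate.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 conditions to compare")
    long_rows = []
    for cond, summ in summaries.items():
        df = summ.per_replicate.copy()
        df.insert(0, "condition", cond)
        long_rows.append(df)
    long = pd.concat(long_rows, ignore_index=True)

    diff_rows = []
    for a, b in combinations(summaries, 2):
        for gate in (LOMC, HIMC):
            da = summaries[a].stats.loc[gate, "mean"]
            db = summaries[b].stats.loc[gate, "mean"]
            diff_rows.append(
                {
                    "condition_a": a,
                    "condition_b": b,
                    "gate": gate,
                    "mean_fraction_a": da,
                    "mean_fraction_b": db,
                    "difference": da - db,
                }
            )
    return long, pd.DataFrame(diff_rows)


def plot_two_parameter(
    features: pd.DataFrame,
    gates: tuple[MobilityGate, MobilityGate] | None = None,
    path: str | None = None,
    bins: int = 60,
):
    """2D histogram of the (r_conf, mean_jump) distribution with gate boxes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist2d(
        features["r_conf_um"], features["mean_jump_um"], bins=bins, cmap="viridis"
    )
    if gates is not None:
        for gate, color in zip(gates, ("red", "lime")):
            x0 = gate.r_conf_min or 0.0
            x1 = gate.r_conf_max or features["r_conf_um"].max()
            y0 = gate.mean_jump_min or 0.0
            y1 = gate.mean_jump_max or features["mean_jump_um"].max()
            ax.add_patch(
                plt.Rectangle(
                    (x0, y0), x1 - x0, y1 - y0,
                    fill=False, edgecolor=color, linestyle="--", label=gate.name,
                )
            )
        ax.legend()
    ax.set_xlabel("radius of confinement (µm)")
    ax.set_ylabel("mean frame-to-frame jump (µm)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
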
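"""TurboID proximity-labeling differential-interactome calling.

Input is a label-free proteomics protein-group table (MaxQuant style):
protein intensities across four experimental groups — two bait pulldowns
(a wild-type and a mutant bait) and two controls (free biotin ligase, and
uninduced "noDox" cells) — with four replicates each. The calling pipeline
follows the standard Perseus-style workflow: remove contaminant / reverse /
only-by-site rows, keep proteins quantified in all four replicates of at
least one group, log2-transform, impute left-censored missing values from a
narrowed down-shifted normal per sample column, test each bait group
against both controls with per-protein t-tests and Benjamini-Hochberg
correction, and call interactors that are >2-fold enriched with adjusted
p < 0.05 against *both* controls. Differential (bait-preferential)
interactors are proteins whose WT/mutant log2 ratio lies more than three
standard deviations from the cohort mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IntensityMatrix",
    "InteractomeConfig",
    "InteractomeResult",
    "DesignError",
    "ImputationError",
    "qc_filter",
    "valid_values_filter",
    "log2_transform",
    "impute_missing",
    "test_enrichment",
    "call_significant",
    "score_differential",
    "differential_interactome",
    "read_protein_groups",
    "write_protein_groups",
]

FLAG_COLUMNS = ("contaminant", "reverse", "only_by_site")

#: MaxQuant proteinGroups.txt column names for the QC flags.
MAXQUANT_FLAGS = {
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "only_by_site": "Only identified by site",
}


class DesignError(ValueError):
    """Sample-to-group design violates the four-replicate requirement."""


class ImputationError(ValueError):
    """A sample column lacks enough observed values for imputation."""


@dataclass(frozen=True)
class IntensityMatrix:
    """Proteins × samples intensities with QC flags and a group design.

    ``intensities`` holds raw (linear) values with NaN for missing cells;
    ``flags`` is boolean with columns contaminant / reverse / only_by_site;
    ``design`` maps each sample column to its experimental group.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if not self.flags.index.equals(self.intensities.index):
            raise ValueError("flags must be indexed by the same proteins")
        missing_cols = set(self.intensities.columns) - set(self.design.index)
        if missing_cols:
            raise DesignError(f"samples without a group assignment: {missing_cols}")
        for col in FLAG_COLUMNS:
            if col not in self.flags.columns:
                raise ValueError(f"flags table lacks column {col!r}")
        vals = self.intensities.to_numpy(float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("intensities must be > 0 where present")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.design[self.intensities.columns]))

    def samples_of(self, group: str) -> list[str]:
        return [c for c in self.intensities.columns if self.design[c] == group]

    def require_replicates(self, n: int = 4) -> None:
        for g in self.groups:
            k = len(self.samples_of(g))
            if k != n:
                raise DesignError(f"group {g!r} has {k} replicates; expected {n}")


def qc_filter(matrix: IntensityMatrix) -> IntensityMatrix:
    """Remove contaminant, reverse and only-identified-by-site rows."""
    bad = matrix.flags[list(FLAG_COLUMNS)].any(axis=1)
    keep = matrix.intensities.index[~bad]
    return IntensityMatrix(
        intensities=matrix.intensities.loc[keep],
        flags=matrix.flags.loc[keep],
        design=matrix.design,
    )


def valid_values_filter(matrix: IntensityMatrix, n_valid: int = 4) -> IntensityMatrix:
    """Keep proteins quantified in all replicates of at least one group."""
    matrix.require_replicates(n_valid)
    ok = pd.Series(False, index=matrix.intensities.index)
    for g in matrix.groups:
        cols = matrix.samples_of(g)
        ok |= matrix.intensities[cols].notna().sum(axis=1) == n_valid
    keep = matrix.intensities.index[ok]
    return IntensityMatrix(
        intensities=matrix.intensities.loc[keep],
        flags=matrix.flags.loc[keep],
        design=matrix.design,
    )


def log2_transform(matrix: IntensityMatrix) -> pd.DataFrame:
    """Element-wise log2 of present intensities; missing stays missing."""
    vals = matrix.intensities.to_numpy(float)
    bad = np.argwhere(~np.isnan(vals) & (vals <= 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            "non-positive intensity at "
            f"({matrix.intensities.index[i]}, {matrix.intensities.columns[j]})"
        )
    return np.log2(matrix.intensities)


def impute_missing(
    log2: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Perseus-style left-shifted imputation, per sample column.

    Each missing cell in column ``s`` is drawn from
    Normal(mean_s − downshift·sd_s, (width·sd_s)²) where mean_s and sd_s
    are the observed mean and standard deviation of that column. Observed
    cells are untouched; the draw order is fixed so a seed reproduces the
    matrix bit-identically.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = log2.copy()
    for col in log2.columns:
        observed = log2[col].dropna()
        n_missing = int(log2[col].isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ImputationError(
                f"column {col!r} has {len(observed)} observed values; "
                "need >= 2 to impute"
            )
        mu = float(observed.mean())
        sd = float(observed.std(ddof=1))
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
        out.loc[log2[col].isna(), col] = draws
    return out


def test_enrichment(
    log2: pd.DataFrame,
    design: pd.Series,
    case: str,
    control: str,
    *,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein case-vs-control t-test on a complete log2 matrix.

    Returns a frame indexed by protein with ``log2fc`` (mean case − mean
    control), ``p`` (two-sided t-test) and ``adj_p`` (Benjamini-Hochberg
    across all tested proteins). Proteins with zero variance in both groups
    get p = 1 when the means agree, else the smallest positive float, and
    are marked in ``zero_variance``.
    """
    case_cols = [c for c in log2.columns if design[c] == case]
    ctrl_cols = [c for c in log2.columns if design[c] == control]
    if not case_cols or not ctrl_cols:
        raise DesignError(f"no samples for {case!r} vs {control!r}")
    if log2[case_cols + ctrl_cols].isna().any().any():
        raise ValueError("matrix must be complete (impute first)")
    a = log2[case_cols].to_numpy(float)
    b = log2[ctrl_cols].to_numpy(float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    zero_var = ~np.isfinite(p)
    tiny = np.nextafter(0.0, 1.0)
    p = np.where(zero_var, np.where(np.isclose(log2fc, 0.0), 1.0, tiny), p)
    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "adj_p": adj_p, "zero_variance": zero_var},
        index=log2.index,
    )


def call_significant(
    vs_turboid: pd.DataFrame,
    vs_nodox: pd.DataFrame,
    fold_min: float = 2.0,
    adj_p_max: float = 0.05,
) -> pd.Series:
    """Significant-interactor flag: both folds and both adjusted p must pass.

    A protein is significant iff its linear fold change exceeds ``fold_min``
    against *both* controls and its BH-adjusted p is below ``adj_p_max`` in
    *both* tests (strict inequalities).
    """
    shared = vs_turboid.index.intersection(vs_nodox.index)
    log2_min = math.log2(fold_min)
    sig = (
        (vs_turboid.loc[shared, "log2fc"] > log2_min)
        & (vs_nodox.loc[shared, "log2fc"] > log2_min)
        & (vs_turboid.loc[shared, "adj_p"] < adj_p_max)
        & (vs_nodox.loc[shared, "adj_p"] < adj_p_max)
    )
    sig.name = "significant"
    return sig


def score_differential(
    ratio_log2fc: pd.Series, sd_cutoff: float = 3.0
) -> pd.Series:
    """Label proteins whose WT/mutant log2 ratio is a ±sd_cutoff·σ outlier.

    The cohort mean μ and s.d. σ are computed over the supplied ratios;
    values strictly above μ + cutoff·σ are ``WT_preferential``, strictly
    below μ − cutoff·σ ``R35A_preferential``, otherwise ``none``. A
    zero-spread cohort labels nothing.
    """
    if len(ratio_log2fc) < 2:
        raise ValueError("need >= 2 proteins to define the cohort mean and s.d.")
    mu = float(ratio_log2fc.mean())
    sigma = float(ratio_log2fc.std(ddof=1))
    labels = pd.Series("none", index=ratio_log2fc.index, name="differential")
    if sigma == 0:
        return labels
    labels[ratio_log2fc > mu + sd_cutoff * sigma] = "WT_preferential"
    labels[ratio_log2fc < mu - sd_cutoff * sigma] = "R35A_preferential"
    return labels


@dataclass(frozen=True)
class InteractomeConfig:
    """Thresholds of the calling pipeline (defaults as published)."""

    case_groups: Sequence[str] = ("WT", "R35A")
    control_groups: Sequence[str] = ("TurboID", "noDox")
    fold_min: float = 2.0
    adj_p_max: float = 0.05
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    sd_cutoff: float = 3.0
    equal_var: bool = True
    #: cohort used for the differential μ/σ: all quantified proteins
    #: ("all", as in a volcano over shared proteins) or significant only.
    differential_cohort: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_min <= 1:
            raise ValueError("fold_min must be > 1")
        if not 0 < self.adj_p_max < 1:
            raise ValueError("adj_p_max must be in (0, 1)")
        if self.impute_width <= 0 or self.impute_downshift < 0:
            raise ValueError("invalid imputation parameters")
        if self.differential_cohort not in ("all", "significant"):
            raise ValueError("differential_cohort must be 'all' or 'significant'")


@dataclass
class InteractomeResult:
    """Calls table, per-comparison statistics and stage row counts."""

    calls: pd.DataFrame
    enrichment: dict[tuple[str, str], pd.DataFrame]
    imputed_log2: pd.DataFrame
    stage_log: dict[str, int]


def differential_interactome(
    matrix: IntensityMatrix, config: InteractomeConfig | None = None
) -> InteractomeResult:
    """Run the full caller: QC → valid values → log2 → impute → tests → calls.

    A single imputation pass feeds every comparison. The calls table has,
    per protein, the log2 fold changes and adjusted p values of each case
    group against both controls, a per-case ``significant`` flag, the
    WT/R35A log2 ratio and the differential label.
    """
    config = config or InteractomeConfig()
    log: dict[str, int] = {"input_proteins": len(matrix.intensities)}

    m = qc_filter(matrix)
    log["after_qc_filter"] = len(m.intensities)
    m = valid_values_filter(m)
    log["after_valid_values_filter"] = len(m.intensities)

    log2 = log2_transform(m)
    imputed = impute_missing(
        log2,
        width=config.impute_width,
        downshift=config.impute_downshift,
        rng=np.random.default_rng(config.seed),
    )

    enrichment: dict[tuple[str, str], pd.DataFrame] = {}
    for case in config.case_groups:
        for control in config.control_groups:
            enrichment[(case, control)] = test_enrichment(
                imputed, m.design, case, control, equal_var=config.equal_var
            )

    calls = pd.DataFrame(index=imputed.index)
    for case in config.case_groups:
        ctrl_a, ctrl_b = config.control_groups
        res_a, res_b = enrichment[(case, ctrl_a)], enrichment[(case, ctrl_b)]
        calls[f"log2fc_{case}_vs_{ctrl_a}"] = res_a["log2fc"]
        calls[f"adj_p_{case}_vs_{ctrl_a}"] = res_a["adj_p"]
        calls[f"log2fc_{case}_vs_{ctrl_b}"] = res_b["log2fc"]
        calls[f"adj_p_{case}_vs_{ctrl_b}"] = res_b["adj_p"]
        calls[f"significant_{case}"] = call_significant(
            res_a, res_b, config.fold_min, config.adj_p_max
        )
        log[f"significant_{case}"] = int(calls[f"significant_{case}"].sum())

    wt, mut = config.case_groups
    wt_cols = [c for c in imputed.columns if m.design[c] == wt]
    mut_cols = [c for c in imputed.columns if m.design[c] == mut]
    calls["wt_r35a_log2fc"] = (
        imputed[wt_cols].mean(axis=1) - imputed[mut_cols].mean(axis=1)
    )

    if config.differential_cohort == "significant":
        cohort_idx = calls.index[
            calls[[f"significant_{c}" for c in config.case_groups]].any(axis=1)
        ]
    else:
        cohort_idx = calls.index
    if len(cohort_idx) >= 2:
        labels = score_differential(
            calls.loc[cohort_idx, "wt_r35a_log2fc"], config.sd_cutoff
        )
        calls["differential"] = labels.reindex(calls.index, fill_value="none")
    else:
        calls["differential"] = "none"
    log["differential_labels"] = int((calls["differential"] != "none").sum())

    return InteractomeResult(
        calls=calls.reset_index(names="protein"),
        enrichment=enrichment,
        imputed_log2=imputed,
        stage_log=log,
    )


# --------------------------------------------------------------------------
# MaxQuant-style I/O
# --------------------------------------------------------------------------

def read_protein_groups(
    path: str | Path,
    design: Mapping[str, str],
    *,
    id_column: str = "Protein IDs",
    intensity_prefix: str = "Intensity ",
) -> IntensityMatrix:
    """Read a tab-delimited protein-group table into an IntensityMatrix.

    ``design`` maps sample names (as they appear after the intensity column
    prefix) to group labels. Intensities of 0 are treated as missing, the
    MaxQuant convention; flag columns use "+" for flagged rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}")
    idx = df[id_column]
    samples = list(design)
    cols = {}
    for s in samples:
        col = f"{intensity_prefix}{s}"
        if col not in df.columns:
            raise ValueError(f"missing intensity column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        cols[s] = vals.where(vals > 0)
    intensities = pd.DataFrame(cols)
    intensities.index = idx
    flags = pd.DataFrame(
        {
            key: (df[col].fillna("") == "+").to_numpy()
            if col in df.columns
            else np.zeros(len(df), dtype=bool)
            for key, col in MAXQUANT_FLAGS.items()
        },
        index=idx,
    )
    return IntensityMatrix(
        intensities=intensities,
        flags=flags,
        design=pd.Series(dict(design), dtype=object),
    )


def write_protein_groups(matrix: IntensityMatrix, path: str | Path) -> Path:
    """Write an IntensityMatrix as a MaxQuant-style tab-delimited table."""
    path = Path(path)
    out = pd.DataFrame({"Protein IDs": matrix.intensities.index})
    for s in matrix.intensities.columns:
        out[f"Intensity {s}"] = matrix.intensities[s].fillna(0.0).to_numpy()
    for key, col in MAXQUANT_FLAGS.items():
        out[col] = np.where(matrix.flags[key].to_numpy(), "+", "")
    out.to_csv(path, sep="\t", index=False)
    return path
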
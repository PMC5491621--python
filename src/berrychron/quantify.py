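"""Quantification and normalization of raw omics measurements.

Turns raw spectral counts and peak areas into the normalized, filtered,
stage-averaged matrices that all downstream statistics operate on:

* NSAF (normalized spectral abundance factor) for label-free protein
  quantification: ``NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)`` per
  sample, where SpC is the spectral count and L the sequence length.
* Metabolite normalization to fresh weight times an internal standard
  (GC-MS, dodecane) or the total ion intensity (LC-MS).
* Presence filtering: a feature is kept iff it is non-zero in every
  biological replicate of at least one stage.
* Kovats retention-index conversion against spiked n-alkanes (C12-C40).
* Replicate averaging per stage, optional per-feature z-scoring, and
  integration of metabolite and protein series into one matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AbundanceMatrix, SampleDesign

NORMALIZATION_MODES = ("internal_standard", "total_ion")


@dataclass
class SpectralCountTable:
    """Raw protein spectral counts with sequence lengths.

    ``counts``: proteins x samples, non-negative integers.
    ``lengths``: protein sequence length in residues (>= 1).
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("spectral counts must be non-negative")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            arr = self.counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("spectral counts must be integral")
            self.counts = self.counts.round().astype(int)
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.lengths < 1).any():
            bad = self.lengths.index[self.lengths < 1][0]
            raise ValueError(f"sequence length must be >= 1 residue (protein {bad!r})")


@dataclass
class StageSeries:
    """Feature x ordered-stage matrix, the substrate of clustering/PCA/Granger.

    ``values`` columns follow the design's stage order. If ``zscored``,
    every non-constant row has mean 0 and sample variance 1 (ddof=1);
    constant rows are listed in ``constant_features`` and left untouched.
    """

    values: pd.DataFrame
    zscored: bool = False
    constant_features: list[str] = field(default_factory=list)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)


@dataclass
class AlkaneCalibration:
    """Retention times of spiked n-alkanes, (carbon number, RT in minutes)."""

    points: list[tuple[int, float]]

    def __post_init__(self) -> None:
        self.points = sorted(self.points)
        ns = [n for n, _ in self.points]
        rts = [rt for _, rt in self.points]
        if len(ns) < 2:
            raise ValueError("calibration needs at least two alkanes")
        if min(ns) < 12 or max(ns) > 40:
            raise ValueError("alkane carbon numbers must lie in [12, 40]")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing with carbon number")


def compute_nsaf(table: SpectralCountTable) -> AbundanceMatrix:
    """Normalized spectral abundance factors, per sample.

    SAF_i = SpC_i / L_i; NSAF_i = SAF_i / sum_j SAF_j. Per sample the
    NSAF values sum to exactly 1; proteins with zero counts get NSAF 0.
    A sample with no counts at all has no defined NSAF and is an error.
    """
    saf = table.counts.div(table.lengths, axis=0)
    colsum = saf.sum(axis=0)
    zero = colsum.index[colsum == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total spectral counts; NSAF undefined")
    nsaf = saf.div(colsum, axis=1)
    return AbundanceMatrix(nsaf, pd.Series("protein", index=nsaf.index))


def normalize_metabolites(
    raw: AbundanceMatrix, design: SampleDesign, mode: str
) -> AbundanceMatrix:
    """Divide each sample column by fresh weight x reference intensity.

    ``mode='internal_standard'`` uses the spiked internal standard
    (dodecane for GC-MS); ``mode='total_ion'`` uses total ion intensity
    (LC-MS). Normalization is multiplicative: value' = value / (fw * ref).
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}, got {mode!r}")
    ref_col = "internal_standard_intensity" if mode == "internal_standard" else "total_ion_intensity"
    fw = design.table["fresh_weight"]
    ref = design.table[ref_col]
    for name, series in (("fresh_weight", fw), (ref_col, ref)):
        bad = series.index[~(series > 0)]
        if len(bad):
            raise ValueError(f"sample {bad[0]!r} has non-positive {name}: {series[bad[0]]}")
    denom = (fw * ref).reindex(raw.values.columns)
    return AbundanceMatrix(raw.values.div(denom, axis=1), raw.kinds)


def presence_mask(matrix: AbundanceMatrix, design: SampleDesign, stages=None) -> pd.Series:
    """True for features non-zero in all replicates of >= 1 (given) stage."""
    stages = design.stage_order if stages is None else list(stages)
    keep = pd.Series(False, index=matrix.values.index)
    for stage in stages:
        cols = design.samples_of_stage(stage)
        keep |= (matrix.values[cols] > 0).all(axis=1)
    return keep


def presence_filter(matrix: AbundanceMatrix, design: SampleDesign) -> AbundanceMatrix:
    """Keep features present (value > 0) in every replicate of >= 1 stage.

    This mirrors the standard proteomics rule that a candidate must be
    detected in all biological replicates of at least one condition to
    enter statistical analysis. Input feature order is preserved.
    """
    keep = presence_mask(matrix, design)
    return matrix.subset(matrix.values.index[keep])


def retention_index(rt: float, cal: AlkaneCalibration) -> float:
    """Kovats retention index by linear interpolation on the bracketing alkanes.

    RI = 100 * (n + (rt - RT_n) / (RT_{n+1} - RT_n)). No extrapolation:
    rt outside [RT(C_min), RT(C_max)] is an error.
    """
    ns = np.array([n for n, _ in cal.points], dtype=float)
    rts = np.array([t for _, t in cal.points], dtype=float)
    if rt < rts[0] or rt > rts[-1]:
        raise ValueError(
            f"retention time {rt} outside calibrated range [{rts[0]}, {rts[-1]}]; refusing to extrapolate"
        )
    i = int(np.searchsorted(rts, rt, side="right")) - 1
    i = min(i, len(rts) - 2)
    frac = (rt - rts[i]) / (rts[i + 1] - rts[i])
    # bracketing alkanes need not be consecutive carbons (e.g. C12, C14)
    return 100.0 * (ns[i] + frac * (ns[i + 1] - ns[i]))


def zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each row to mean 0, sample variance 1 (ddof=1).

    Rows with zero variance cannot be standardized; they are returned
    unchanged and reported in the second element.
    """
    mean = values.mean(axis=1)
    std = values.std(axis=1, ddof=1)
    constant = list(values.index[std == 0])
    safe = std.replace(0, 1.0)
    out = values.sub(mean, axis=0).div(safe, axis=0)
    out.loc[constant] = values.loc[constant]
    return out, constant


def stage_average(
    matrix: AbundanceMatrix, design: SampleDesign, zscore: bool = False
) -> StageSeries:
    """Arithmetic mean over biological replicates, per stage, per feature."""
    cols = {}
    for stage in design.stage_order:
        cols[stage] = matrix.values[design.samples_of_stage(stage)].mean(axis=1)
    series = pd.DataFrame(cols)[design.stage_order]
    if zscore:
        series, constant = zscore_rows(series)
        return StageSeries(series, zscored=True, constant_features=constant)
    return StageSeries(series, zscored=False)


def integrate(metabolites: StageSeries, proteins: StageSeries) -> StageSeries:
    """Row-concatenate metabolite and protein series after z-scoring.

    Peak areas and NSAFs live on incommensurable scales, so each feature
    is standardized before concatenation. Feature ids are prefixed by
    kind (``met:`` / ``prot:``) to guarantee uniqueness.
    """
    if metabolites.stages != proteins.stages:
        raise ValueError(
            f"stage axes differ: {metabolites.stages} vs {proteins.stages}"
        )
    parts, constants = [], []
    for prefix, series in (("met", metabolites), ("prot", proteins)):
        vals = series.values
        if not series.zscored:
            vals, const = zscore_rows(vals)
        else:
            const = list(series.constant_features)
        vals = vals.rename(index=lambda f, p=prefix: f"{p}:{f}")
        parts.append(vals)
        constants.extend(f"{prefix}:{c}" for c in const)
    return StageSeries(pd.concat(parts, axis=0), zscored=True, constant_features=constants)
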
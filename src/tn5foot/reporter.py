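"""Reporter-expression quantification.

Bulk assays report Luciferase luminescence normalized to total protein (from
a BSA standard curve); single-cell flow assays express each sample in units
of the undifferentiated promoter-only line via a spiked, CFSE-labelled
internal standard measured in the same tube:

    b_sample = f_PUER * f_samples / f_PUERs
    L_sample = (f_sample - b_sample) / (f_samples - b_sample)

where f_sample / f_samples are the median stained-Luciferase fluorescence of
the sample and the spiked standard, and f_PUER / f_PUERs the medians of
Luciferase-negative cells and of the standard spiked with them.  By
construction L is exactly 1 for the standard itself and exactly 0 for pure
background.  Enhancer activity is the fold change of an enhancer-bearing
reporter over the promoter-only reporter at matched timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def protein_from_standard_curve(
    absorbances: np.ndarray | list[float],
    standards: list[tuple[float, float]],
) -> np.ndarray:
    """Inverse-predict protein mass (μg) from an OLS albumin standard curve.

    ``standards`` are (μg, absorbance) pairs; the line absorbance = a·μg + c
    is fitted by ordinary least squares and inverted.
    """
    if len(standards) < 2:
        raise ValueError("need at least two standards")
    ug = np.asarray([s[0] for s in standards], dtype=float)
    ab = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(ug) == 0:
        raise ValueError("standards must span more than one protein mass")
    slope, intercept = np.polyfit(ug, ab, 1)
    if slope == 0:
        raise ValueError("degenerate standard curve (zero slope)")
    return (np.asarray(absorbances, dtype=float) - intercept) / slope


def bulk_expression(luminescence: float, protein_ug: float) -> float:
    """Luminescence per μg of total protein."""
    if protein_ug <= 0:
        raise ValueError("protein mass must be positive")
    return luminescence / protein_ug


@dataclass(frozen=True)
class FlowSample:
    """Median fluorescences feeding the internal-standard normalization."""

    f_sample: float
    f_sample_std: float  # spiked promoter internal standard in the same tube
    f_puer: float  # Luciferase-negative PUER cells
    f_puer_std: float  # internal standard spiked with PUER cells

    def __post_init__(self) -> None:
        if self.f_puer_std <= 0:
            raise ValueError("f_puer_std must be positive")
        for name in ("f_sample", "f_sample_std", "f_puer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def flow_background(sample: FlowSample) -> float:
    """b_sample = f_PUER · f_samples / f_PUERs."""
    return sample.f_puer * sample.f_sample_std / sample.f_puer_std


def flow_expression(sample: FlowSample) -> float:
    """L_sample = (f_sample − b_sample) / (f_samples − b_sample).

    The same background estimate is subtracted in numerator and denominator,
    anchoring L at 0 for pure background and 1 for the internal standard.
    """
    b = flow_background(sample)
    denom = sample.f_sample_std - b
    if denom == 0:
        raise ValueError("internal standard equals estimated background; L undefined")
    return (sample.f_sample - b) / denom


@dataclass
class ExpressionSeries:
    """Expression values over strictly increasing timepoints (hours)."""

    timepoints: np.ndarray
    values: np.ndarray
    units: str = "arbitrary"
    label: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.shape != self.values.shape:
            raise ValueError("timepoints and values must align")
        if (np.diff(self.timepoints) <= 0).any():
            raise ValueError("timepoints must be strictly increasing")

    def value_at(self, timepoint: float) -> float:
        hits = np.flatnonzero(self.timepoints == timepoint)
        if hits.size != 1:
            raise ValueError(f"timepoint {timepoint} not present exactly once")
        return float(self.values[hits[0]])


def fold_change(crm: ExpressionSeries, promoter: ExpressionSeries) -> ExpressionSeries:
    """Pointwise enhancer/promoter ratio at matched timepoints.

    A zero promoter value yields NaN at that timepoint (undefined fold
    change) with a warning rather than failing the whole series.
    """
    if not np.array_equal(crm.timepoints, promoter.timepoints):
        raise ValueError("fold change requires matched timepoints")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = crm.values / promoter.values
    undefined = promoter.values == 0
    if undefined.any():
        warnings.warn("zero promoter expression; fold change undefined at some timepoints")
        ratio = np.where(undefined, np.nan, ratio)
    return ExpressionSeries(
        timepoints=crm.timepoints.copy(),
        values=ratio,
        units="fold over promoter",
        label=f"{crm.label}/{promoter.label}",
    )


def normalize_to_undifferentiated(
    series: ExpressionSeries, reference_timepoint: float
) -> ExpressionSeries:
    """Scale a series by its value at the undifferentiated reference.

    The reference is 0 h for IL3 (macrophage) series and −48 h for GCSF
    (neutrophil) series, where cells have not yet been induced.
    """
    ref = series.value_at(reference_timepoint)
    if ref == 0:
        raise ValueError("reference value is zero; cannot normalize")
    return ExpressionSeries(
        timepoints=series.timepoints.copy(),
        values=series.values / ref,
        units=f"relative to t={reference_timepoint:g}",
        label=series.label,
        metadata=dict(series.metadata, reference_timepoint=reference_timepoint),
    )


def aggregate_bulk_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of bulk expression across replicates.

    Expects columns line, condition, timepoint, replicate, luminescence,
    protein_ug; returns per (line, condition, timepoint) the replicate mean
    expression (luminescence per μg), its standard error, and n.
    """
    required = {"line", "condition", "timepoint", "luminescence", "protein_ug"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (table["protein_ug"] <= 0).any():
        raise ValueError("protein mass must be positive")
    work = table.assign(expression=table["luminescence"] / table["protein_ug"])
    grouped = work.groupby(["line", "condition", "timepoint"])["expression"]
    out = grouped.agg(mean="mean", sem="sem", n="count").reset_index()
    return out
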
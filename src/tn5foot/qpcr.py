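"""Location-specific accessibility by ATAC-qPCR ΔCq analysis.

Tn5-generated fragments amplified with a location-specific primer are
quantified by qPCR; the quantification cycle difference against a loading
control (the endogenous promoter, whose accessibility changes little)

    ΔCq = Cq_enhancer − Cq_promoter,    fold = 2^−ΔCq

converts to relative accessibility.  Technical replicates whose ΔCq falls
outside 1.5× the interquartile range are removed before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def iqr_filter(values: list[float] | np.ndarray, method: str = "tukey") -> np.ndarray:
    """Drop values outside 1.5×IQR; returns the kept values in input order.

    Quartiles use linear interpolation between order statistics (the common
    "type 7" scheme).  ``method="tukey"`` (default) keeps values inside the
    Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; ``method="median"`` is the
    alternate reading that keeps values with |x − median| ≤ 1.5·IQR.  Fewer
    than three values pass through unfiltered with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        warnings.warn("fewer than 3 replicates; skipping outlier filtering")
        return values.copy()
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    if method == "tukey":
        keep = (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)
    elif method == "median":
        keep = np.abs(values - med) <= 1.5 * iqr
    else:
        raise ValueError("method must be 'tukey' or 'median'")
    return values[keep]


@dataclass(frozen=True)
class DeltaCqResult:
    """ΔCq and fold change for one target in one biological sample."""

    delta_cq: float
    fold: float
    enhancer_kept: tuple[float, ...] = ()
    enhancer_removed: tuple[float, ...] = ()
    promoter_kept: tuple[float, ...] = ()
    promoter_removed: tuple[float, ...] = ()


def delta_cq(
    enhancer_cqs: list[float] | np.ndarray,
    promoter_cqs: list[float] | np.ndarray,
    outlier_filter: bool = True,
    method: str = "tukey",
) -> DeltaCqResult:
    """ΔCq = mean(kept enhancer Cq) − mean(kept promoter Cq); fold = 2^−ΔCq.

    The 1.5×IQR fence is applied to per-replicate ΔCq values computed
    against the mean promoter Cq of the same biological sample; promoter
    replicates are fenced on their own Cq values.
    """
    enhancer_cqs = np.asarray(enhancer_cqs, dtype=float)
    promoter_cqs = np.asarray(promoter_cqs, dtype=float)
    if enhancer_cqs.size == 0 or promoter_cqs.size == 0:
        raise ValueError("both targets need at least one technical replicate")
    if outlier_filter:
        prom_kept = iqr_filter(promoter_cqs, method=method)
    else:
        prom_kept = promoter_cqs.copy()
    if prom_kept.size == 0:
        raise ValueError("all promoter replicates removed by the outlier filter")
    prom_mean = float(prom_kept.mean())
    per_rep_delta = enhancer_cqs - prom_mean
    if outlier_filter:
        kept_delta = iqr_filter(per_rep_delta, method=method)
    else:
        kept_delta = per_rep_delta.copy()
    if kept_delta.size == 0:
        raise ValueError("all enhancer replicates removed by the outlier filter")
    kept_mask = np.isin(per_rep_delta, kept_delta)
    dcq = float(kept_delta.mean())
    prom_mask = np.isin(promoter_cqs, prom_kept)
    return DeltaCqResult(
        delta_cq=dcq,
        fold=float(2.0**-dcq),
        enhancer_kept=tuple(enhancer_cqs[kept_mask]),
        enhancer_removed=tuple(enhancer_cqs[~kept_mask]),
        promoter_kept=tuple(promoter_cqs[prom_mask]),
        promoter_removed=tuple(promoter_cqs[~prom_mask]),
    )


def location_ratio_series(
    rosa: list[DeltaCqResult],
    endo: list[DeltaCqResult],
    timepoints: list[float],
) -> pd.DataFrame:
    """Accessibility ratio between the knock-in and endogenous locations.

    Per timepoint: ΔΔCq = ΔCq_ROSA26 − ΔCq_endogenous and the corresponding
    ratio 2^−ΔΔCq, plus each location's fold series normalized to its first
    timepoint.  A constant ΔΔCq over time indicates that the two genomic
    locations share the same accessibility dynamics.
    """
    if not (len(rosa) == len(endo) == len(timepoints)):
        raise ValueError("rosa, endo, and timepoints must have matched lengths")
    if len(rosa) == 0:
        raise ValueError("empty series")
    records = []
    rosa0, endo0 = rosa[0].fold, endo[0].fold
    for t, r, e in zip(timepoints, rosa, endo):
        ddcq = r.delta_cq - e.delta_cq
        records.append(
            {
                "timepoint": t,
                "delta_delta_cq": ddcq,
                "ratio": float(2.0**-ddcq),
                "rosa_fold_rel_initial": r.fold / rosa0,
                "endo_fold_rel_initial": e.fold / endo0,
            }
        )
    return pd.DataFrame.from_records(records)


def delta_cq_from_table(
    table: pd.DataFrame,
    enhancer_target: str,
    promoter_target: str = "promoter_control",
    outlier_filter: bool = True,
    method: str = "tukey",
) -> pd.DataFrame:
    """ΔCq per biological sample from a long-format qPCR table.

    Expects columns sample, timepoint, target, replicate, cq; returns one
    row per (sample, timepoint) with ΔCq, fold, and replicate bookkeeping.
    """
    required = {"sample", "timepoint", "target", "cq"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records = []
    for (sample, timepoint), grp in table.groupby(["sample", "timepoint"]):
        enh = grp.loc[grp["target"] == enhancer_target, "cq"].to_numpy()
        prom = grp.loc[grp["target"] == promoter_target, "cq"].to_numpy()
        res = delta_cq(enh, prom, outlier_filter=outlier_filter, method=method)
        records.append(
            {
                "sample": sample,
                "timepoint": timepoint,
                "delta_cq": res.delta_cq,
                "fold": res.fold,
                "enhancer_kept": len(res.enhancer_kept),
                "enhancer_removed": len(res.enhancer_removed),
                "promoter_kept": len(res.promoter_kept),
                "promoter_removed": len(res.promoter_removed),
            }
        )
    return pd.DataFrame.from_records(records)
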
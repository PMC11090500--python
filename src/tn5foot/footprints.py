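"""Protected-region (footprint) calling and accessibility dynamics.

A footprint is a run of 5-50 consecutive nucleotides whose pooled cut count
stays strictly below a region-specific threshold, bordered on both sides by
positions with strictly more cuts than the threshold — the high-low-high
pattern left where a bound transcription factor shields DNA from Tn5.
Calling operates on raw pooled counts because the thresholds are absolute
cut counts (400 for the promoter, 100/40/200 for CRMs 7/16/18 in the study
this reproduces); normalized profiles feed the dynamics summaries instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cuts import CutProfile


@dataclass(frozen=True)
class FootprintParams:
    """Threshold (absolute cuts) and allowed footprint lengths in bp."""

    threshold: float
    min_len: int = 5
    max_len: int = 50

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("require 1 <= min_len <= max_len")


#: region-specific default thresholds from the study's four elements
DEFAULT_THRESHOLDS = {"promoter": 400, "crm7": 100, "crm16": 40, "crm18": 200}


@dataclass(frozen=True)
class ProtectedRegion:
    """A called footprint: low-count run with its high-count borders."""

    contig: str
    start: int
    end: int
    left_border: int
    left_count: float
    right_border: int
    right_count: float
    max_internal: float

    @property
    def run_length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def call_protected_regions(
    pooled: CutProfile, params: FootprintParams
) -> list[ProtectedRegion]:
    """Call maximal sub-threshold runs flanked by above-threshold positions.

    Run membership requires count < T strictly; borders require count > T
    strictly, so a position with count exactly T both terminates a run and
    disqualifies itself as a border (the run is discarded).  Runs touching
    either end of the profile have no border there and are discarded.
    Output is sorted by start; coordinates are genomic (profile.start-based).
    """
    if pooled.state not in ("raw", "pooled"):
        raise ValueError("footprints are called on raw pooled counts")
    counts = pooled.counts
    n = len(counts)
    if n < params.min_len + 2:
        warnings.warn("profile shorter than min_len + 2; no footprint can be called")
        return []
    below = counts < params.threshold
    # run boundaries from transitions of the below-threshold indicator
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = [0] if below[0] else []
    starts += [int(e) + 1 for e in edges if not below[e]]
    regions: list[ProtectedRegion] = []
    for s in starts:
        e = s
        while e < n and below[e]:
            e += 1
        if s == 0 or e == n:
            continue  # touches the interval edge: no border exists
        if not params.min_len <= e - s <= params.max_len:
            continue
        if counts[s - 1] <= params.threshold or counts[e] <= params.threshold:
            continue
        regions.append(
            ProtectedRegion(
                contig=pooled.contig,
                start=pooled.start + s,
                end=pooled.start + e,
                left_border=pooled.start + s - 1,
                left_count=float(counts[s - 1]),
                right_border=pooled.start + e,
                right_count=float(counts[e]),
                max_internal=float(counts[s:e].max()),
            )
        )
    return regions


@dataclass
class BinSeries:
    """Per-bin mean accessibility for each sample over one region.

    Bins partition [start, end) into ``n_bins`` contiguous near-equal pieces;
    the first ``length mod n_bins`` bins are one bp wider.  ``means`` is a
    DataFrame with one row per sample and one column per bin (1-based labels).
    """

    contig: str
    start: int
    end: int
    boundaries: np.ndarray
    means: pd.DataFrame

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1


def bin_boundaries(start: int, end: int, n_bins: int) -> np.ndarray:
    length = end - start
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > length:
        raise ValueError("more bins than positions in the region")
    base, rem = divmod(length, n_bins)
    widths = np.full(n_bins, base, dtype=np.int64)
    widths[:rem] += 1
    return start + np.concatenate([[0], np.cumsum(widths)])


def bin_region(
    profiles: list[CutProfile], start: int, end: int, n_bins: int
) -> BinSeries:
    """Mean accessibility per uniform bin, per sample, over [start, end)."""
    if not profiles:
        raise ValueError("at least one profile is required")
    bounds = bin_boundaries(start, end, n_bins)
    rows = {}
    for prof in profiles:
        vals = [float(prof.slice(int(a), int(b)).mean()) for a, b in zip(bounds[:-1], bounds[1:])]
        rows[prof.sample_id] = vals
    means = pd.DataFrame.from_dict(rows, orient="index", columns=range(1, n_bins + 1))
    return BinSeries(contig=profiles[0].contig, start=start, end=end, boundaries=bounds, means=means)


def site_adjacent_change(
    profiles_by_time: list[CutProfile],
    sites: list[tuple[int, int]],
    flank: int = 5,
) -> pd.DataFrame:
    """Accessibility change near binding sites vs the rest of the region.

    For each consecutive pair of timepoints, computes the mean absolute
    change per nucleotide over the union of site ± flank intervals and over
    the remainder of the region, and their ratio.  The ratio is NaN when the
    remainder does not change (an undefined-ratio signal, flagged with a
    warning), and raises if the site mask swallows the whole region.
    """
    if len(profiles_by_time) < 2:
        raise ValueError("need at least two timepoints")
    first = profiles_by_time[0]
    for p in profiles_by_time[1:]:
        if not first.same_interval(p):
            raise ValueError("profiles must cover identical intervals")
    n = len(first)
    site_mask = np.zeros(n, dtype=bool)
    for s, e in sites:
        if not (first.start <= s < e <= first.end):
            raise ValueError(f"site [{s}, {e}) outside the region")
        lo = max(first.start, s - flank) - first.start
        hi = min(first.end, e + flank) - first.start
        site_mask[lo:hi] = True
    if site_mask.all():
        raise ValueError("site vicinity covers the whole region; remainder is empty")
    if not site_mask.any():
        raise ValueError("no site positions inside the region")
    records = []
    for a, b in zip(profiles_by_time[:-1], profiles_by_time[1:]):
        delta = np.abs(b.counts.astype(float) - a.counts.astype(float))
        near = float(delta[site_mask].mean())
        away = float(delta[~site_mask].mean())
        if away == 0.0:
            warnings.warn("no change in the remainder; site/remainder ratio undefined")
            ratio = np.nan
        else:
            ratio = near / away
        records.append(
            {
                "from": a.sample_id,
                "to": b.sample_id,
                "site_mean_abs_change": near,
                "remainder_mean_abs_change": away,
                "ratio": ratio,
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U (rank-sum) comparison of two count groups."""

    statistic: float
    pvalue: float
    n_in: int
    n_out: int


def compare_in_out_sites(
    pooled: CutProfile,
    sites: list[tuple[int, int]],
    alternative: str = "two-sided",
) -> RankSumResult:
    """Rank-sum test of per-nucleotide counts, in-site vs out-of-site.

    Uses the Mann-Whitney U statistic (exact distribution for small
    tie-free samples, normal approximation otherwise); U and the Wilcoxon
    rank-sum W differ by an additive constant and share the p-value.  Use
    ``alternative="less"`` for the one-sided test that in-site counts are
    lower.
    """
    if not sites:
        raise ValueError("at least one site interval is required")
    mask = np.zeros(len(pooled), dtype=bool)
    for s, e in sites:
        if not (pooled.start <= s < e <= pooled.end):
            raise ValueError(f"site [{s}, {e}) outside the profile")
        mask[s - pooled.start : e - pooled.start] = True
    inside = pooled.counts[mask].astype(float)
    outside = pooled.counts[~mask].astype(float)
    if inside.size == 0 or outside.size == 0:
        raise ValueError("both in-site and out-of-site groups must be non-empty")
    res = stats.mannwhitneyu(inside, outside, alternative=alternative)
    return RankSumResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_in=int(inside.size),
        n_out=int(outside.size),
    )


def overlap_known_sites(
    regions: list[ProtectedRegion], known: list[tuple[int, int]]
) -> pd.DataFrame:
    """Whether each known site shares >= 1 bp with any called region.

    The returned frame has one row per known site plus an ``overlapped``
    flag; the overall fraction is ``frame["overlapped"].mean()``.
    """
    records = []
    for s, e in known:
        hit = any(r.overlaps(s, e) for r in regions)
        records.append({"start": s, "end": e, "overlapped": hit})
    return pd.DataFrame.from_records(records, columns=["start", "end", "overlapped"])


def read_bed_intervals(path: str | Path) -> list[tuple[int, int]]:
    """Half-open intervals from the first three BED columns."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((int(fields[1]), int(fields[2])))
    return out


def write_bed(regions: list[ProtectedRegion], path: str | Path) -> None:
    """BED of called footprints; the score is the larger border count."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            score = max(r.left_count, r.right_count)
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\tfootprint_{i + 1}\t{score:g}\n")
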
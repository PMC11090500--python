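"""Per-nucleotide Tn5 cut profiles from aligned paired-end reads.

Each retained read contributes one cut.  Tn5 duplicates 9 bp at the insertion
point, so the two reads of a pair start 8 bp apart; shifting the +strand 5'
end by +4 and the -strand 5' end by -4 maps both onto the central (5th)
nucleotide of the overhang.  The widely used +4/-5 shift does NOT do this —
it leaves the two mates one base apart — and is available here only for
demonstrating that failure.

Coordinates are 0-based half-open throughout; SAM input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam
from scipy import stats

#: +strand cut = 5' start + PLUS_SHIFT; -strand cut = 5' start - MINUS_SHIFT
PLUS_SHIFT = 4
MINUS_SHIFT = 4
#: default library-size normalization scale (cuts per million)
CPM_SCALE = 1e6

STATES = ("raw", "normalized", "pooled", "corrected", "smoothed")


@dataclass
class CutProfile:
    """Tn5 cut counts over one genomic interval.

    ``counts[i]`` holds the cuts at genomic position ``start + i`` on
    ``contig``.  ``library_size`` is the total number of retained cuts in the
    whole alignment source (not just this interval), which anchors both
    library-size normalization and the Poisson gate's genome-wide mean.
    """

    contig: str
    start: int
    counts: np.ndarray
    library_size: float
    state: str = "raw"
    sample_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(
            self.counts, dtype=np.int64 if self.state in ("raw", "pooled") else float
        )
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if (self.counts < 0).any():
            raise ValueError("cut counts must be non-negative")

    @property
    def end(self) -> int:
        return self.start + len(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def same_interval(self, other: "CutProfile") -> bool:
        return (
            self.contig == other.contig
            and self.start == other.start
            and len(self) == len(other)
        )

    def slice(self, start: int, end: int) -> np.ndarray:
        """Counts on the genomic sub-interval [start, end)."""
        if not (self.start <= start <= end <= self.end):
            raise ValueError(f"[{start}, {end}) not within [{self.start}, {self.end})")
        return self.counts[start - self.start : end - self.start]


def _passes_filters(read: pysam.AlignedSegment) -> bool:
    # properly paired, mapped, primary, non-duplicate, passing QC
    return (
        read.is_paired
        and read.is_proper_pair
        and not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_duplicate
        and not read.is_qcfail
    )


def cut_position(read: pysam.AlignedSegment, shifts: tuple[int, int] = (PLUS_SHIFT, MINUS_SHIFT)) -> int:
    """0-based cut position of one read under a (+shift, -shift) rule."""
    plus, minus = shifts
    if read.is_reverse:
        return read.reference_end - 1 - minus
    return read.reference_start + plus


def count_cuts(
    alignments: str | Path | pysam.AlignmentFile,
    contig: str,
    start: int,
    end: int,
    sample_id: str | None = None,
    shifts: tuple[int, int] = (PLUS_SHIFT, MINUS_SHIFT),
) -> CutProfile:
    """Count one Tn5 cut per retained read over [start, end) on ``contig``.

    Retained reads are properly paired, mapped, primary, non-duplicate and
    pass QC.  ``library_size`` counts retained cuts over the whole file so
    profiles over sub-intervals normalize correctly.

    Pass ``shifts=(4, 5)`` to reproduce the conventional +4/-5 shift, which
    assigns the two mates of a pair to different positions.
    """
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        close = True
    try:
        lengths = dict(zip(alignments.references, alignments.lengths))
        if contig not in lengths:
            raise ValueError(f"contig {contig!r} not in alignment header")
        if not (0 <= start < end <= lengths[contig]):
            raise ValueError(f"interval [{start}, {end}) off contig {contig!r}")
        counts = np.zeros(end - start, dtype=np.int64)
        library_size = 0
        for read in alignments.fetch(until_eof=True):
            if not _passes_filters(read):
                continue
            library_size += 1
            if read.reference_name != contig:
                continue
            pos = cut_position(read, shifts)
            if start <= pos < end:
                counts[pos - start] += 1
    finally:
        if close:
            alignments.close()
    meta = {"shifts": shifts}
    return CutProfile(
        contig=contig,
        start=start,
        counts=counts,
        library_size=library_size,
        state="raw",
        sample_id=sample_id,
        metadata=meta,
    )


def normalize_library(profile: CutProfile, scale: float = CPM_SCALE) -> CutProfile:
    """Divide counts by the sample's library size and multiply by ``scale``.

    With the default scale the units are cuts per million retained cuts.
    """
    if profile.state not in ("raw", "pooled"):
        raise ValueError(f"can only normalize raw or pooled profiles, got {profile.state!r}")
    if profile.library_size <= 0:
        raise ValueError("cannot normalize a profile with zero library size")
    counts = profile.counts.astype(float) * (scale / profile.library_size)
    meta = dict(profile.metadata, normalization_scale=scale)
    return replace(profile, counts=counts, state="normalized", metadata=meta)


def pool_profiles(profiles: list[CutProfile]) -> CutProfile:
    """Sum raw profiles position-wise over identical intervals."""
    if not profiles:
        raise ValueError("cannot pool an empty list of profiles")
    first = profiles[0]
    for p in profiles:
        if p.state not in ("raw", "pooled"):
            raise ValueError("pooling requires raw (or previously pooled) profiles")
        if not first.same_interval(p):
            raise ValueError("pooling requires identical intervals")
    counts = np.sum([p.counts for p in profiles], axis=0).astype(np.int64)
    library_size = float(sum(p.library_size for p in profiles))
    samples = [p.sample_id for p in profiles]
    return CutProfile(
        contig=first.contig,
        start=first.start,
        counts=counts,
        library_size=library_size,
        state="pooled",
        sample_id="+".join(str(s) for s in samples),
        metadata={"pooled_from": samples},
    )


def sliding_mean(profile: CutProfile, window: int) -> CutProfile:
    """Centered moving average; edges use a truncated (shrinking) window."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(profile):
        raise ValueError("window longer than the profile interval")
    x = profile.counts.astype(float)
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    denom = np.convolve(np.ones_like(x), kernel, mode="same")
    meta = dict(profile.metadata, sliding_window=window, smoothed_from=profile.state)
    return replace(profile, counts=sums / denom, state="smoothed", metadata=meta)


def pearson_between(a: CutProfile, b: CutProfile, window: int = 1) -> float:
    """Pearson r between two window-averaged profiles on one interval."""
    if not a.same_interval(b):
        raise ValueError("profiles must cover identical intervals")
    xa = sliding_mean(a, window).counts if window > 1 else a.counts.astype(float)
    xb = sliding_mean(b, window).counts if window > 1 else b.counts.astype(float)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("Pearson correlation undefined for a zero-variance profile")
    return float(stats.pearsonr(xa, xb).statistic)


def total_accessibility(profile: CutProfile, start: int | None = None, end: int | None = None) -> float:
    """Sum of cuts over [start, end); defaults to the whole profile."""
    start = profile.start if start is None else start
    end = profile.end if end is None else end
    if start == end:
        return 0.0
    return float(profile.slice(start, end).sum())


def coverage_per_nt(profile: CutProfile, start: int | None = None, end: int | None = None) -> float:
    """Mean cuts per nucleotide over [start, end)."""
    start = profile.start if start is None else start
    end = profile.end if end is None else end
    if end <= start:
        raise ValueError("coverage requires a non-empty interval")
    return total_accessibility(profile, start, end) / (end - start)


def write_bedgraph(profile: CutProfile, path: str | Path) -> None:
    """Run-length-merged bedGraph of the profile (zero runs skipped)."""
    counts = profile.counts
    with open(path, "w") as fh:
        i = 0
        n = len(counts)
        while i < n:
            j = i + 1
            while j < n and counts[j] == counts[i]:
                j += 1
            if counts[i] != 0:
                value = counts[i]
                rendered = int(value) if float(value).is_integer() else value
                fh.write(f"{profile.contig}\t{profile.start + i}\t{profile.start + j}\t{rendered}\n")
            i = j
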
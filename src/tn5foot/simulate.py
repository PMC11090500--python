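"""Synthetic Tn5 transposition data with known ground truth.

Generates random genomes, accessibility landscapes with planted protected
regions (footprints), and paired-end transposition events honouring the 9-bp
5' overhang geometry: the two reads of a pair start 8 bp apart and both map
back to the central (5th) overhang nucleotide under a +4/-4 shift.

Every downstream stage — cut counting, bias estimation and correction,
footprint calling, accessibility dynamics — is testable against the truth
stored in these objects without any external sequencing data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .hexamers import FLANK, N_HEXAMERS, hexamer_ids, hexamer_index

#: read 5' starts sit at event_position -/+ OVERHANG_SHIFT on the +/- strand
OVERHANG_SHIFT = 4
#: simulated reads span exactly the 9-bp duplicated overhang
READ_LENGTH = 2 * OVERHANG_SHIFT + 1
DEFAULT_CONTIG = "synth"


@dataclass(frozen=True)
class SyntheticGenome:
    """A random A/C/G/T sequence regenerable from its seed."""

    sequence: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.sequence) < 6:
            raise ValueError("genome length must be >= 6")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("genome may contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)


def generate_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> SyntheticGenome:
    """IID random genome with the requested GC content.

    Deterministic for a fixed seed; base composition is binomial around
    ``gc_fraction``.
    """
    if length < 6:
        raise ValueError("genome length must be >= 6")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=[at, gc, gc, at])
    return SyntheticGenome(sequence=bases.tobytes().decode("ascii"), seed=seed)


@dataclass
class AccessibilityLandscape:
    """Per-position relative transposition propensity with planted footprints.

    ``propensity[i]`` is the relative rate at which Tn5 inserts at position
    ``i`` before sequence bias; inside a planted footprint with depletion
    ``d`` the propensity is ``baseline * d`` (exactly 0 for ``d = 0``).
    """

    propensity: np.ndarray
    planted_footprints: list[tuple[tuple[int, int], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.propensity = np.asarray(self.propensity, dtype=float)
        if (self.propensity < 0).any():
            raise ValueError("propensity must be non-negative everywhere")


def plant_landscape(
    genome: SyntheticGenome,
    footprints: list[tuple[tuple[int, int], float]] | None = None,
    baseline: float = 1.0,
) -> AccessibilityLandscape:
    """Uniform landscape at ``baseline`` with depleted footprint intervals.

    ``footprints`` is a list of ``((start, end), depletion)`` with half-open
    0-based intervals; intervals must be in-bounds and non-overlapping, and
    depletion must lie in [0, 1].
    """
    footprints = list(footprints or [])
    if baseline < 0:
        raise ValueError("baseline must be non-negative")
    prop = np.full(genome.length, float(baseline))
    occupied = np.zeros(genome.length, dtype=bool)
    for (start, end), depletion in footprints:
        if not (0 <= start < end <= genome.length):
            raise ValueError(f"footprint [{start}, {end}) out of genome bounds")
        if not 0.0 <= depletion <= 1.0:
            raise ValueError("depletion must lie in [0, 1]")
        if occupied[start:end].any():
            raise ValueError(f"footprint [{start}, {end}) overlaps another footprint")
        occupied[start:end] = True
        prop[start:end] = baseline * depletion
    return AccessibilityLandscape(propensity=prop, planted_footprints=footprints)


@dataclass
class BiasModel:
    """Generator-side hexamer cutting preference (4096 positive entries)."""

    preferences: np.ndarray

    def __post_init__(self) -> None:
        self.preferences = np.asarray(self.preferences, dtype=float)
        if self.preferences.shape != (N_HEXAMERS,):
            raise ValueError(f"preferences must have {N_HEXAMERS} entries")
        if (self.preferences <= 0).any():
            raise ValueError("all hexamer preferences must be positive")

    @classmethod
    def uniform(cls) -> "BiasModel":
        return cls(np.ones(N_HEXAMERS))

    @classmethod
    def with_preference(cls, hexamer: str, fold: float) -> "BiasModel":
        """Uniform model except one hexamer cut ``fold`` times as readily."""
        prefs = np.ones(N_HEXAMERS)
        prefs[hexamer_index(hexamer)] = fold
        return cls(prefs)

    def position_weights(self, genome: SyntheticGenome) -> np.ndarray:
        """Per-position preference; 0 where the hexamer window exits."""
        ids = hexamer_ids(genome.sequence)
        weights = np.zeros(genome.length)
        valid = ids >= 0
        weights[valid] = self.preferences[ids[valid]]
        return weights


@dataclass
class FragmentSet:
    """Simulated transposition events and the read pairs they emit.

    ``events[i]`` is the 0-based reference coordinate of the central overhang
    nucleotide; the pair for that event has +strand 5' start ``events[i] - 4``
    and -strand 5' start ``events[i] + 4``, so the -strand 5' minus the
    +strand 5' is always exactly 8.  Each read counts as one Tn5 cut
    downstream, so ``library_size`` (total cuts) is ``2 * len(events)``.
    """

    events: np.ndarray
    read_pairs: np.ndarray
    sample_id: str = "sim"
    contig: str = DEFAULT_CONTIG

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int64)
        self.read_pairs = np.asarray(self.read_pairs, dtype=np.int64).reshape(-1, 2)
        if self.read_pairs.shape[0] != self.events.shape[0]:
            raise ValueError("one read pair per event required")

    @property
    def n_events(self) -> int:
        return int(self.events.size)

    @property
    def library_size(self) -> int:
        return 2 * self.n_events


def simulate_fragments(
    genome: SyntheticGenome,
    landscape: AccessibilityLandscape,
    bias_model: BiasModel | None = None,
    n_events: int = 0,
    seed: int = 0,
    sample_id: str = "sim",
    contig: str = DEFAULT_CONTIG,
) -> FragmentSet:
    """Draw transposition events with probability ∝ propensity × hexamer bias.

    Positions whose hexamer window or 9-bp read span would exit the genome
    get zero weight (equivalent to reject-and-redraw).  Deterministic for a
    fixed seed.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if landscape.propensity.size != genome.length:
        raise ValueError("landscape does not match genome length")
    bias_model = bias_model or BiasModel.uniform()
    weights = landscape.propensity * bias_model.position_weights(genome)
    # read span [p-4, p+5) must fit; stricter than the hexamer window
    weights[:OVERHANG_SHIFT] = 0.0
    weights[genome.length - OVERHANG_SHIFT :] = 0.0
    if n_events == 0:
        return FragmentSet(
            events=np.empty(0, dtype=np.int64),
            read_pairs=np.empty((0, 2), dtype=np.int64),
            sample_id=sample_id,
            contig=contig,
        )
    total = weights.sum()
    if total <= 0:
        raise ValueError("no position has positive sampling weight")
    rng = np.random.default_rng(seed)
    # inverse-CDF draw over the propensity x bias product
    cdf = np.cumsum(weights / total)
    events = np.searchsorted(cdf, rng.random(n_events), side="right")
    events = np.sort(events).astype(np.int64)
    read_pairs = np.column_stack([events - OVERHANG_SHIFT, events + OVERHANG_SHIFT])
    return FragmentSet(events=events, read_pairs=read_pairs, sample_id=sample_id, contig=contig)


def usable_positions(genome: SyntheticGenome) -> int:
    """Number of positions a simulated event can occupy."""
    return max(0, genome.length - 2 * OVERHANG_SHIFT)


def write_fasta(genome: SyntheticGenome, path: str | Path, contig: str = DEFAULT_CONTIG) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_truth_bed(
    landscape: AccessibilityLandscape, path: str | Path, contig: str = DEFAULT_CONTIG
) -> None:
    """BED of planted footprints; score column carries the depletion."""
    with open(path, "w") as fh:
        for (start, end), depletion in sorted(landscape.planted_footprints):
            fh.write(f"{contig}\t{start}\t{end}\tfootprint\t{depletion}\n")


def write_alignments(
    fragments: FragmentSet, genome: SyntheticGenome, path: str | Path
) -> None:
    """Write the read pairs as a properly-paired, coordinate-sorted SAM.

    Each event emits a forward/reverse pair of 9-bp reads covering the
    duplicated overhang: both alignments start at ``p - 4`` and the -strand
    read's 5' end (its rightmost base) is ``p + 4``.  MAPQ is fixed at 60.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": fragments.contig, "LN": genome.length}],
        "RG": [{"ID": fragments.sample_id, "SM": fragments.sample_id}],
    }
    order = np.argsort(fragments.events, kind="stable")
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rank, idx in enumerate(order):
            p = int(fragments.events[idx])
            start = p - OVERHANG_SHIFT
            seq = genome.sequence[start : start + READ_LENGTH]
            for is_reverse in (False, True):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"event{rank}"
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{READ_LENGTH}M"
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * READ_LENGTH)
                a.next_reference_id = 0
                a.next_reference_start = start
                a.is_paired = True
                a.is_proper_pair = True
                a.is_reverse = is_reverse
                a.mate_is_reverse = not is_reverse
                a.is_read1 = not is_reverse
                a.is_read2 = is_reverse
                a.template_length = -READ_LENGTH if is_reverse else READ_LENGTH
                a.set_tag("RG", fragments.sample_id)
                out.write(a)


def write_run_config(params: dict, path: str | Path) -> None:
    """Record the exact simulation parameters alongside the outputs."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
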
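"""Tn5 hexamer cutting bias: estimation and three correction methods.

Tn5 does not cut naked DNA uniformly; it prefers certain sequence motifs.
The bias of hexamer ``w`` is estimated from purified-DNA (naked) libraries as

    b(w) = pc(w) / p(w),

the ratio of the hexamer's share of observed cuts to its share of genomic
positions.  Three per-position corrections of an observed profile ``y`` are
provided:

* ``correct_hint`` — x_i = (y_i + 1) / (ŷ_i · b̂(w(i)) + 1), where ŷ_i is the
  mean cut count over the 50-bp window [i-25, i+24] and b̂(w(i)) the bias at
  i relative to the window's total bias.  Smooth, but adds one cut to every
  position, including positions that had none.
* ``correct_bagfoot`` — x_i = y_i / b(w(i)) at every position.  Single-
  nucleotide resolution, but amplifies noise where counts are low.
* ``correct_poisson_gated`` — x_i = y_i / b(w(i)) only where the count is
  incompatible with the genome-wide background, i.e. where the Poisson
  probability mass P(y_i; λ) falls below α/G (Bonferroni over the G genomic
  positions), with λ the mean cuts per position across the genome.  Positions
  at background level are left untouched, so low-count noise is never
  amplified and true zeros stay zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .cuts import CutProfile
from .hexamers import N_HEXAMERS, hexamer_from_index, hexamer_ids, hexamer_index

#: size of the mouse genome (bp), the G of the Bonferroni gate
MOUSE_GENOME_SIZE = 2_730_000_000
HINT_WINDOW = 50
#: HINT window at i is [i - HINT_BACK, i + HINT_FWD] inclusive
HINT_BACK = 25
HINT_FWD = 24


@dataclass
class BiasTable:
    """Cutting-preference ratio b(w) for all 4096 hexamers.

    ``pc`` and ``p`` are the cut-frequency and genomic-frequency vectors the
    ratio was formed from (may be None for synthetic tables).  Hexamers with
    zero genomic frequency have undefined bias and are flagged in
    ``undefined``; the correctors refuse to divide by a zero bias.
    """

    b: np.ndarray
    pc: np.ndarray | None = None
    p: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if self.b.shape != (N_HEXAMERS,):
            raise ValueError(f"bias table must have {N_HEXAMERS} entries")
        if (self.b < 0).any() or not np.isfinite(self.b).all():
            raise ValueError("bias values must be finite and non-negative")

    @classmethod
    def uniform(cls) -> "BiasTable":
        return cls(b=np.ones(N_HEXAMERS), metadata={"source": "uniform"})

    @property
    def undefined(self) -> np.ndarray:
        if self.p is None:
            return np.zeros(N_HEXAMERS, dtype=bool)
        return self.p == 0

    def __getitem__(self, hexamer: str) -> float:
        return float(self.b[hexamer_index(hexamer)])

    def position_bias(self, sequence: str, offset: int = 0) -> np.ndarray:
        """b(w(i)) for every position of ``sequence`` (NaN where undefined).

        ``offset`` shifts indexing so the returned array aligns with a
        profile starting at ``offset`` within the sequence.
        """
        ids = hexamer_ids(sequence)
        out = np.full(len(sequence), np.nan)
        valid = ids >= 0
        out[valid] = self.b[ids[valid]]
        return out[offset:] if offset else out

    def to_tsv(self, path: str | Path) -> None:
        pc = self.pc if self.pc is not None else np.full(N_HEXAMERS, np.nan)
        p = self.p if self.p is not None else np.full(N_HEXAMERS, np.nan)
        with open(path, "w") as fh:
            fh.write("hexamer\tpc\tp\tb\n")
            for k in range(N_HEXAMERS):
                fh.write(f"{hexamer_from_index(k)}\t{pc[k]:.10g}\t{p[k]:.10g}\t{self.b[k]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BiasTable":
        b = np.zeros(N_HEXAMERS)
        pc = np.zeros(N_HEXAMERS)
        p = np.zeros(N_HEXAMERS)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["hexamer", "pc", "p", "b"]:
                raise ValueError("unrecognized bias table format")
            for line in fh:
                hexamer, pcv, pv, bv = line.rstrip("\n").split("\t")
                k = hexamer_index(hexamer)
                pc[k], p[k], b[k] = float(pcv), float(pv), float(bv)
        return cls(b=b, pc=pc, p=p, metadata={"source": str(path)})


def estimate_bias(naked_dna_cuts: CutProfile, genome: str) -> BiasTable:
    """Estimate b(w) = pc(w)/p(w) from a naked-DNA cut profile.

    ``pc(w)`` is the fraction of observed cuts falling at positions whose
    hexamer is ``w``; ``p(w)`` is the fraction of genomic positions carrying
    ``w``.  Cuts at positions without a full hexamer window (sequence edges)
    are excluded with a warning.  Naked-DNA libraries may be merged upstream
    with :func:`tn5foot.cuts.pool_profiles` before estimation.
    """
    if naked_dna_cuts.state not in ("raw", "pooled"):
        raise ValueError("bias estimation requires raw (or pooled raw) cut counts")
    if len(genome) < len(naked_dna_cuts) + naked_dna_cuts.start:
        raise ValueError("genome shorter than the cut profile's interval")
    ids = hexamer_ids(genome)[naked_dna_cuts.start : naked_dna_cuts.end]
    counts = naked_dna_cuts.counts
    valid = ids >= 0
    dropped = int(counts[~valid].sum())
    if dropped:
        warnings.warn(f"{dropped} cuts at positions without a full hexamer were excluded")
    total_cuts = int(counts[valid].sum())
    if total_cuts == 0:
        raise ValueError("no usable cuts to estimate bias from")
    cut_by_hex = np.bincount(ids[valid], weights=counts[valid].astype(float), minlength=N_HEXAMERS)
    pos_by_hex = np.bincount(ids[valid], minlength=N_HEXAMERS).astype(float)
    pc = cut_by_hex / total_cuts
    p = pos_by_hex / pos_by_hex.sum()
    inconsistent = (pc > 0) & (p == 0)
    if inconsistent.any():
        raise ValueError("cuts observed at hexamers absent from the genome")
    b = np.zeros(N_HEXAMERS)
    np.divide(pc, p, out=b, where=p > 0)
    return BiasTable(
        b=b,
        pc=pc,
        p=p,
        metadata={
            "total_cuts": total_cuts,
            "total_positions": int(pos_by_hex.sum()),
            "hexamer_window": "[i-3, i+3)",
            "sample_id": naked_dna_cuts.sample_id,
        },
    )


def _position_bias_for(profile: CutProfile, bias: BiasTable, genome: str) -> np.ndarray:
    """b(w(i)) aligned with the profile; NaN where the hexamer is unavailable."""
    if len(genome) < profile.end:
        raise ValueError("genome shorter than the profile interval")
    ids = hexamer_ids(genome)[profile.start : profile.end]
    out = np.full(len(profile), np.nan)
    valid = ids >= 0
    out[valid] = bias.b[ids[valid]]
    return out


def _divide_by_bias(y: np.ndarray, pos_bias: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """y / b at masked positions; positions without a defined bias are left as-is.

    A zero-bias hexamer is only an error where there is something to divide:
    y = 0 corrects to 0 whatever the bias.
    """
    x = y.astype(float).copy()
    usable = mask & np.isfinite(pos_bias)
    if (usable & (pos_bias == 0) & (y != 0)).any():
        raise ValueError("zero-bias hexamer at a position with nonzero cuts selected for correction")
    np.divide(y, pos_bias, out=x, where=usable & (pos_bias > 0))
    x[usable & (pos_bias == 0)] = 0.0
    return x


def correct_bagfoot(profile: CutProfile, bias: BiasTable, genome: str) -> CutProfile:
    """x_i = y_i / b(w(i)) at every position with a defined hexamer bias."""
    if profile.state not in ("raw", "normalized", "pooled"):
        raise ValueError("correction applies to raw, pooled, or normalized profiles")
    pos_bias = _position_bias_for(profile, bias, genome)
    x = _divide_by_bias(profile.counts, pos_bias, np.ones(len(profile), dtype=bool))
    meta = dict(profile.metadata, correction="bagfoot")
    return replace(profile, counts=x, state="corrected", metadata=meta)


def correct_hint(
    profile: CutProfile,
    bias: BiasTable,
    genome: str,
    window_statistic: str = "mean",
) -> CutProfile:
    """x_i = (y_i + 1) / (ŷ_i · b̂(w(i)) + 1) with a 50-bp window.

    ŷ_i is the mean of the observed cuts over [i-25, i+24] and b̂(w(i)) the
    bias at i divided by the window's summed bias; at interval edges the
    window truncates and b̂ renormalizes over the truncated window.  Note the
    +1 terms: a profile of zeros maps to a profile of ones.

    ``window_statistic="sum"`` replaces ŷ_i with the window *total*, the
    alternate reading under which the expected cuts at i are the window total
    times the relative bias.
    """
    if profile.state not in ("raw", "normalized", "pooled"):
        raise ValueError("correction applies to raw, pooled, or normalized profiles")
    if window_statistic not in ("mean", "sum"):
        raise ValueError("window_statistic must be 'mean' or 'sum'")
    y = profile.counts.astype(float)
    n = len(y)
    pos_bias = _position_bias_for(profile, bias, genome)
    # positions lacking a hexamer contribute neutral bias 1 to window sums
    b_pos = np.where(np.isfinite(pos_bias), pos_bias, 1.0)

    idx = np.arange(n)
    lo = np.clip(idx - HINT_BACK, 0, n)
    hi = np.clip(idx + HINT_FWD + 1, 0, n)
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cb = np.concatenate([[0.0], np.cumsum(b_pos)])
    win_y = cy[hi] - cy[lo]
    win_b = cb[hi] - cb[lo]
    width = (hi - lo).astype(float)

    y_hat = win_y / width if window_statistic == "mean" else win_y
    b_hat = b_pos / win_b
    x = (y + 1.0) / (y_hat * b_hat + 1.0)
    meta = dict(profile.metadata, correction="hint", hint_window=HINT_WINDOW, window_statistic=window_statistic)
    return replace(profile, counts=x, state="corrected", metadata=meta)


@dataclass(frozen=True)
class PoissonGate:
    """Genome-wide Poisson background deciding which positions get corrected.

    λ is the mean number of cuts per position across the genome
    (library_size / genome_size); a position's count ``y`` triggers
    correction when P(y; λ) < α/G with the familywise level α Bonferroni-
    corrected over the G genomic positions.
    """

    lam: float
    genome_size: float = MOUSE_GENOME_SIZE
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.genome_size <= 0 or self.alpha <= 0:
            raise ValueError("genome_size and alpha must be positive")

    @classmethod
    def from_profile(
        cls, profile: CutProfile, genome_size: float = MOUSE_GENOME_SIZE, alpha: float = 0.01
    ) -> "PoissonGate":
        """λ = genome-wide library size / genome size (pooled size for pooled profiles)."""
        return cls(lam=profile.library_size / genome_size, genome_size=genome_size, alpha=alpha)

    @property
    def log_threshold(self) -> float:
        return math.log(self.alpha) - math.log(self.genome_size)

    def triggers(self, y: np.ndarray | int) -> np.ndarray | bool:
        """Whether P(y; λ) < α/G, evaluated in log space."""
        return stats.poisson.logpmf(y, self.lam) < self.log_threshold


def gate_threshold(gate: PoissonGate) -> int:
    """Smallest count y* with P(y*; λ) < α/G, valid in the λ < 1 regime.

    For λ < 1 the Poisson PMF decreases monotonically in y, so the gate
    reduces to a single count threshold: every position with y ≥ y* is
    corrected and every position with y < y* is untouched.  For λ ≥ 1 the
    PMF is not monotone and no single threshold exists; use the per-position
    test (:meth:`PoissonGate.triggers`) instead.
    """
    if gate.lam >= 1:
        raise ValueError("count threshold requires lambda < 1; use the per-position PMF test")
    y = 0
    while not bool(gate.triggers(y)):
        y += 1
        if y > 10_000_000:  # pragma: no cover - unreachable for lam < 1
            raise RuntimeError("gate threshold scan did not terminate")
    return y


def correct_poisson_gated(
    profile: CutProfile, bias: BiasTable, genome: str, gate: PoissonGate
) -> CutProfile:
    """x_i = y_i / b(w(i)) where P(y_i; λ) < α/G, else x_i = y_i."""
    if profile.state not in ("raw", "pooled"):
        raise ValueError("the Poisson gate applies to raw (or pooled raw) counts")
    y = profile.counts
    pos_bias = _position_bias_for(profile, bias, genome)
    mask = np.asarray(gate.triggers(y))
    x = _divide_by_bias(y, pos_bias, mask)
    meta = dict(
        profile.metadata,
        correction="poisson_gated",
        gate_lambda=gate.lam,
        gate_genome_size=gate.genome_size,
        gate_alpha=gate.alpha,
    )
    return replace(profile, counts=x, state="corrected", metadata=meta)


def correct(
    profile: CutProfile,
    bias: BiasTable,
    genome: str,
    method: str,
    gate: PoissonGate | None = None,
    **kwargs,
) -> CutProfile:
    """Dispatch to one of the correction methods by name."""
    if method == "hint":
        return correct_hint(profile, bias, genome, **kwargs)
    if method == "bagfoot":
        return correct_bagfoot(profile, bias, genome)
    if method == "poisson":
        if gate is None:
            raise ValueError("the poisson method requires a PoissonGate")
        return correct_poisson_gated(profile, bias, genome, gate)
    raise ValueError(f"unknown correction method {method!r}")
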
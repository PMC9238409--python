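"""Synthetic cfDNA depth profiles with implanted copy-number events.

The generator emulates what a targeted myeloid panel sees in plasma: binned
read depths whose expectation is set by a per-bin capture efficiency
(on-target bins capture ~10x more than off-target bins), perturbed by
multiplicative lognormal noise, and scaled inside an event region by the
mixture copy number

    log2 ratio = log2( ((1 - f) * 2 + f * c) / 2 )

where ``f`` is the tumor fraction of the cfDNA and ``c`` the copy number in
the neoplastic fraction (2 = no event).  For a heterozygous autosomal driver
mutation in a diploid clone the reported VAF is half the tumor fraction, so
``f = 2 * VAF`` links the mutation tier of a sample to its copy-number
detectability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import Bin, Genome

#: log2 ratios are floored here when the mixture copy number reaches 0.
LOG2_FLOOR = -8.0

#: sentinel returned when no tumor fraction in [0, 1] attains a threshold
UNREACHABLE = float("inf")


def expected_log2(tumor_copies: int, tumor_fraction: float, *, floor: float = LOG2_FLOOR) -> float:
    """Expected log2 depth ratio of a region at ``tumor_copies`` in the clone.

    ``log2(((1 - f) * 2 + f * c) / 2)``, floored at ``floor`` when the
    mixture copy number is 0 (pure homozygous loss at f = 1).
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError(f"tumor_fraction must be in [0, 1], got {tumor_fraction}")
    if tumor_copies < 0:
        raise ValueError(f"tumor_copies must be >= 0, got {tumor_copies}")
    mixture = (1.0 - tumor_fraction) * 2.0 + tumor_fraction * tumor_copies
    if mixture <= 0.0:
        return floor
    return max(math.log2(mixture / 2.0), floor)


def min_detectable_fraction(tumor_copies: int, threshold: float) -> float:
    """Smallest tumor fraction whose expected log2 ratio attains ``threshold``.

    Closed-form inverse of :func:`expected_log2`:
    ``f = 2 * (2**threshold - 1) / (c - 2)``.  Returns the sentinel
    ``UNREACHABLE`` (inf) when no f in [0, 1] attains the threshold.  The
    threshold's sign must match the event direction (positive for gains,
    negative for losses).
    """
    if tumor_copies == 2:
        raise ValueError("tumor_copies == 2 is not an event")
    if (tumor_copies > 2) != (threshold > 0):
        raise ValueError(
            f"threshold sign {threshold:+g} inconsistent with copies={tumor_copies}"
        )
    f = 2.0 * (2.0**threshold - 1.0) / (tumor_copies - 2.0)
    if f > 1.0:
        return UNREACHABLE
    return max(f, 0.0)


@dataclass(frozen=True)
class SimEvent:
    """A copy-number event to implant: whole chromosome, arm, interval or gene.

    ``chrom`` alone = whole chromosome; ``chrom`` + ``arm`` = full arm;
    adding ``start``/``end`` restricts to a sub-arm interval; ``gene``
    restricts to one panel gene's bins.
    """

    chrom: str
    tumor_copies: int
    arm: Optional[str] = None  # "p" | "q"
    start: Optional[int] = None
    end: Optional[int] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tumor_copies < 0:
            raise ValueError("tumor_copies must be >= 0")
        if (self.start is None) != (self.end is None):
            raise ValueError("start and end must be given together")
        if self.start is not None and self.arm is None and self.gene is None:
            raise ValueError("sub-arm interval events need an arm")

    def mask(self, bins: Sequence[Bin], genome: Genome) -> np.ndarray:
        sel = np.zeros(len(bins), dtype=bool)
        for i, b in enumerate(bins):
            if b.chrom != self.chrom:
                continue
            if self.gene is not None:
                sel[i] = b.gene == self.gene
                continue
            if self.arm is not None:
                arm = genome.arm_of(b.chrom, b.start)
                if arm.arm != self.arm:
                    continue
            if self.start is not None and not (self.start <= b.start < self.end):
                continue
            sel[i] = True
        return sel


@dataclass
class SimSample:
    """One synthetic tumor sample: events, clonal fraction and noise."""

    sample_id: str
    events: list[SimEvent] = field(default_factory=list)
    tumor_fraction: float = 1.0
    mutation_vaf: Optional[float] = None
    mean_depth: float = 500.0
    noise_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.mutation_vaf is None:
            # heterozygous autosomal driver in a diploid clone
            self.mutation_vaf = self.tumor_fraction / 2.0


@dataclass
class ReferenceProfile:
    """Pooled-normal reference: per-bin expected depth and dispersion."""

    expected: np.ndarray  # per-bin median depth across the pool, > 0
    dispersion: np.ndarray  # per-bin std of log2(depth / median) across pool
    n_normals: int

    def __post_init__(self) -> None:
        self.expected = np.asarray(self.expected, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if np.any(self.expected <= 0):
            raise ValueError("reference expected depth must be > 0 for every bin")
        if np.any(self.dispersion < 0):
            raise ValueError("dispersion must be >= 0")


@dataclass
class DepthProfile:
    """Per-bin read-depth counts for one sample, ordered as the bin table."""

    sample_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")


def _bin_efficiencies(
    bins: Sequence[Bin], rng: np.random.Generator, on_off_ratio: float, efficiency_sigma: float
) -> np.ndarray:
    base = np.array([1.0 if b.target_class == "on" else 1.0 / on_off_ratio for b in bins])
    wobble = 2.0 ** rng.normal(0.0, efficiency_sigma, size=len(bins))
    return base * wobble


def simulate_reference_pool(
    bins: Sequence[Bin],
    n_normals: int,
    mean_depth: float = 500.0,
    noise_sigma: float = 0.15,
    seed: int = 0,
    *,
    on_off_ratio: float = 10.0,
    efficiency_sigma: float = 0.2,
) -> ReferenceProfile:
    """Pool ``n_normals`` simulated diploid plasma samples into a reference.

    Each bin has a fixed capture efficiency (on-target bins ``on_off_ratio``
    times the off-target mean, with lognormal bin-to-bin wobble); each normal
    draws lognormal depth noise of width ``noise_sigma`` (log2 scale) around
    it.  The reference stores the per-bin median depth (pseudo-counted to
    stay positive) and the per-bin dispersion of log2 ratios.
    """
    if n_normals < 2:
        raise ValueError("a pooled reference needs at least 2 normals")
    rng = np.random.default_rng(seed)
    eff = _bin_efficiencies(bins, rng, on_off_ratio, efficiency_sigma)
    expect = mean_depth * eff
    draws = expect[None, :] * 2.0 ** rng.normal(0.0, noise_sigma, size=(n_normals, len(bins)))
    median = np.maximum(np.median(draws, axis=0), 1e-6)
    log2r = np.log2(np.maximum(draws, 1e-6) / median[None, :])
    dispersion = np.std(log2r, axis=0, ddof=0)
    return ReferenceProfile(expected=median, dispersion=dispersion, n_normals=n_normals)


def simulate_sample(
    bins: Sequence[Bin],
    sample: SimSample,
    reference: ReferenceProfile,
    genome: Genome,
) -> DepthProfile:
    """Draw a depth profile with the sample's events implanted.

    Expected depth = reference expectation x 2**expected_log2(copies, f)
    inside each event, x1 elsewhere, then multiplicative lognormal noise of
    width ``noise_sigma``.  Overlapping events are rejected: the copy state
    of a doubly-claimed bin would be ambiguous.
    """
    if len(bins) != len(reference.expected):
        raise ValueError("bin table and reference profile are misaligned")
    claimed = np.zeros(len(bins), dtype=int)
    scale = np.ones(len(bins), dtype=float)
    for ev in sample.events:
        m = ev.mask(bins, genome)
        if not m.any():
            raise ValueError(f"event {ev} covers no panel bins")
        claimed += m
        scale[m] = 2.0 ** expected_log2(ev.tumor_copies, sample.tumor_fraction)
    if np.any(claimed > 1):
        raise ValueError("overlapping events claim the same bin; copy state ambiguous")
    rng = np.random.default_rng(sample.seed)
    expect = reference.expected * scale
    if sample.noise_sigma > 0:
        depths = expect * 2.0 ** rng.normal(0.0, sample.noise_sigma, size=len(bins))
    else:
        depths = expect.copy()
    return DepthProfile(sample_id=sample.sample_id, depths=depths)


# ---------------------------------------------------------------------------
# TSV round-trips keyed to the BED-like bin table


def write_depth_profile(profile: DepthProfile, bins: Sequence[Bin], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "depth": profile.depths,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_depth_profile(path: str | Path, sample_id: str | None = None) -> DepthProfile:
    df = pd.read_csv(path, sep="\t")
    return DepthProfile(sample_id=sample_id or Path(path).stem, depths=df["depth"].to_numpy())


def write_reference(reference: ReferenceProfile, bins: Sequence[Bin], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "expected": reference.expected,
            "dispersion": reference.dispersion,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    # n_normals rides along as a comment-free extra column would break BED
    # tools; store it in the filename-adjacent sidecar instead when needed.


def read_reference(path: str | Path, n_normals: int = 0) -> ReferenceProfile:
    df = pd.read_csv(path, sep="\t")
    return ReferenceProfile(
        expected=df["expected"].to_numpy(),
        dispersion=df["dispersion"].to_numpy(),
        n_normals=n_normals,
    )
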
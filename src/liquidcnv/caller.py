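"""Arm-level copy-number calling from binned depth ratios.

The caller converts a sample depth profile plus a pooled-normal reference
into gain/loss events via: per-bin log2 ratios (median-centered), per-arm
recursive binary segmentation, hard threshold calling (|log2| >= 0.4 for a
gain or loss, log2 <= -1.50 for homozygous loss, boundaries inclusive),
proximal/distal labeling when several called segments share an arm,
whole-chromosome promotion (monosomy/trisomy) when both arms — or the q arm
alone for acrocentrics — are in-state, and focal gene amplification.

Two-tier reporting reconciles the hard threshold with the reality of dilute
cfDNA: a segment whose mean falls short of the call threshold but whose
z-score shows it is statistically non-zero is reported as ``faint`` and is
never counted as called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Bin, Genome, arm_indices
from .iscn import Imbalance, ImbalanceSet
from .simulate import DepthProfile, ReferenceProfile

CALLED_STATES = ("gain", "loss", "homozygous-loss")
FAINT_STATES = ("faint-gain", "faint-loss")


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds and segmentation knobs (log2-ratio units)."""

    call_threshold: float = 0.4
    hom_loss_threshold: float = -1.50
    amplification_threshold: float = 1.0
    faint_z: float = 4.0
    min_seg_bins: int = 5
    split_alpha: float = 1e-3
    whole_chrom_rule: float = 0.9
    pseudo: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.call_threshold < abs(self.hom_loss_threshold):
            raise ValueError("need 0 < call_threshold < |hom_loss_threshold|")


@dataclass(frozen=True)
class SensitivityPolicy:
    """VAF tiers linking mutation burden to copy-number detectability."""

    vaf_clear: float = 0.13
    vaf_floor: float = 0.08

    def __post_init__(self) -> None:
        if not self.vaf_floor < self.vaf_clear:
            raise ValueError("vaf_floor must be below vaf_clear")

    def tier(self, vaf: Optional[float]) -> str:
        if vaf is None:
            return "unknown"
        if vaf >= self.vaf_clear:
            return "clear"
        if vaf >= self.vaf_floor:
            return "marginal"
        return "below-floor"


@dataclass
class Log2Profile:
    sample_id: str
    values: np.ndarray  # per-bin log2 ratio, median-centered
    dispersion: np.ndarray  # per-bin noise estimate from the reference


@dataclass
class Segment:
    arm: str
    start: int  # bin index, half-open within the whole bin table
    end: int
    mean_log2: float
    n_bins: int
    z: float
    low_resolution: bool = False


@dataclass
class CNVEvent:
    scope: str  # "arm" | "whole-chromosome" | "gene"
    chrom: str
    location: str  # arm name ("5q"), chromosome ("7"), or gene symbol
    direction: str  # "gain" | "loss"
    zygosity: str  # "heterozygous" | "homozygous"
    klass: str  # arm-gain | arm-loss | trisomy | monosomy | amplification | homozygous-loss
    position_label: str  # "whole" | "proximal" | "distal" | ""
    tier: str  # "called" | "faint"
    mean_log2: float


@dataclass
class CNVEventSet:
    sample_id: str
    events: list[CNVEvent]
    segments: list[Segment] = field(default_factory=list)
    detectability: str = "unknown"  # clear | marginal | below-floor | unknown

    def called(self) -> list[CNVEvent]:
        return [e for e in self.events if e.tier == "called"]

    def to_imbalance_set(self) -> ImbalanceSet:
        """Project called events into the common imbalance currency."""
        det = []
        amp = False
        for e in self.called():
            if e.scope == "gene":
                amp = True
                det.append(
                    Imbalance(e.chrom, "p" if e.location.endswith("p") else "q",
                              "gain", amplification=True)
                    if e.location[-1] in "pq"
                    else Imbalance(e.chrom, "chrom", "gain", amplification=True)
                )
                continue
            region = "chrom" if e.scope == "whole-chromosome" else e.location[-1]
            det.append(Imbalance(e.chrom, region, e.direction, zygosity=e.zygosity))
        return ImbalanceSet.build(
            determinate=det, indeterminate_count=0,
            abnormality_count=len(self.called()),
            fusion_only=False, evaluable=True, amplification_possible=amp,
        )


def normalize_bins(
    sample: DepthProfile, reference: ReferenceProfile, pseudo: float = 1.0
) -> Log2Profile:
    """Median-centered per-bin log2((depth + pseudo) / (reference + pseudo)).

    The pseudo-count keeps every ratio finite; median-centering removes the
    sample's sequencing-depth scale.
    """
    if len(sample.depths) != len(reference.expected):
        raise ValueError(
            f"profile has {len(sample.depths)} bins but reference has "
            f"{len(reference.expected)}"
        )
    raw = np.log2((sample.depths + pseudo) / (reference.expected + pseudo))
    values = raw - np.median(raw)
    return Log2Profile(sample.sample_id, values, reference.dispersion.copy())


def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float, float]:
    """Best breakpoint of ``x`` by pooled two-sample t; leftmost max wins.

    Returns (offset, t, bonferroni-corrected p) where offset is the left
    segment size.  Degenerate zero-variance splits get t=inf (means differ)
    or t=0 (means equal).
    """
    n = len(x)
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    k = np.arange(min_bins, n - min_bins + 1)
    s1, ss1 = cs[k - 1], css[k - 1]
    s2, ss2 = cs[-1] - s1, css[-1] - ss1
    n1, n2 = k, n - k
    m1, m2 = s1 / n1, s2 / n2
    rss = (ss1 - s1 * m1) + (ss2 - s2 * m2)
    sp2 = np.maximum(rss / (n - 2), 0.0)
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = np.where(sp2 <= 1e-300, np.where(diff > 1e-12, np.inf, 0.0), t)
    i = int(np.argmax(t))
    tbest = float(t[i])
    p = 0.0 if np.isinf(tbest) else 2.0 * float(sps.t.sf(tbest, n - 2))
    return int(k[i]), tbest, min(p * len(k), 1.0)


def segment_arm(
    values: np.ndarray,
    dispersion: np.ndarray,
    config: CallerConfig,
    *,
    arm_name: str = "",
    offset: int = 0,
) -> list[Segment]:
    """Recursive binary segmentation of one arm's log2 values.

    Splits at the breakpoint maximizing the pooled two-sample t statistic,
    accepting a split only when its p-value survives a Bonferroni correction
    over the candidate breakpoints at ``split_alpha``; recurses into both
    halves.  Segments have at least ``min_seg_bins`` bins; an arm shorter
    than that yields a single segment flagged low-resolution.
    """
    x = np.asarray(values, dtype=float)
    d = np.asarray(dispersion, dtype=float)
    n = len(x)

    def make(lo: int, hi: int, low_res: bool = False) -> Segment:
        seg = x[lo:hi]
        mean = float(np.mean(seg))
        disp = float(np.median(d[lo:hi]))
        nb = hi - lo
        if disp > 0:
            z = mean / (disp / np.sqrt(nb))
        else:
            z = np.inf * np.sign(mean) if mean != 0 else 0.0
        return Segment(arm_name, offset + lo, offset + hi, mean, nb, float(z), low_res)

    if n < config.min_seg_bins:
        return [make(0, n, low_res=True)]

    out: list[Segment] = []

    def split(lo: int, hi: int) -> None:
        if hi - lo < 2 * config.min_seg_bins:
            out.append(make(lo, hi))
            return
        off, _t, p = _best_split(x[lo:hi], config.min_seg_bins)
        if p <= config.split_alpha:
            split(lo, lo + off)
            split(lo + off, hi)
        else:
            out.append(make(lo, hi))

    split(0, n)
    return out


def call_segment(seg: Segment, config: CallerConfig) -> str:
    """Threshold state of one segment; boundary values are in-state."""
    m = seg.mean_log2
    if m >= config.call_threshold:
        return "gain"
    if m <= config.hom_loss_threshold:
        return "homozygous-loss"
    if m <= -config.call_threshold:
        return "loss"
    if abs(seg.z) >= config.faint_z and m != 0:
        return "faint-gain" if m > 0 else "faint-loss"
    return "neutral"


def label_positions(
    arm: str,
    segments: Sequence[Segment],
    states: Sequence[str],
    config: CallerConfig,
) -> list[tuple[Segment, str, str]]:
    """Attach whole/proximal/distal labels to an arm's non-neutral segments.

    With >= 2 called segments on one arm, the one nearest the centromere is
    "proximal" and the farthest "distal" (the rule is distance-based, not
    sign-based; middle segments keep coordinates only).  A single called
    segment spanning >= ``whole_chrom_rule`` of the arm is "whole".  On a p
    arm the centromere sits at the high-coordinate end, so proximity order is
    reversed.
    """
    arm_bins = sum(s.n_bins for s in segments)
    called = [i for i, st in enumerate(states) if st in CALLED_STATES]
    labels = [""] * len(segments)
    if len(called) >= 2:
        order = called if arm.endswith("q") else list(reversed(called))
        labels[order[0]] = "proximal"
        labels[order[-1]] = "distal"
    for i, st in enumerate(states):
        if st == "neutral" or labels[i]:
            continue
        if segments[i].n_bins >= config.whole_chrom_rule * arm_bins:
            labels[i] = "whole"
    return [(s, st, lb) for s, st, lb in zip(segments, states, labels)]


def _arm_events(
    arm: str, labeled: Sequence[tuple[Segment, str, str]]
) -> list[CNVEvent]:
    chrom = arm[:-1]
    out = []
    for seg, st, lb in labeled:
        if st == "neutral":
            continue
        tier = "called" if st in CALLED_STATES else "faint"
        direction = "gain" if "gain" in st else "loss"
        zyg = "homozygous" if st == "homozygous-loss" else "heterozygous"
        klass = "homozygous-loss" if st == "homozygous-loss" else f"arm-{direction}"
        out.append(
            CNVEvent("arm", chrom, arm, direction, zyg, klass, lb, tier, seg.mean_log2)
        )
    return out


def aggregate_chromosome(
    chrom: str, events: Sequence[CNVEvent], genome: Genome, config: CallerConfig
) -> list[CNVEvent]:
    """Promote matched whole-arm events to one monosomy/trisomy event.

    Both arms (or the q arm alone for acrocentric chromosomes) must carry the
    same direction over >= ``whole_chrom_rule`` of their bins — i.e. carry a
    "whole" position label.  The promoted event is called only if every
    contributing arm was called.
    """
    arms = [a.name for a in genome.chrom_arms(chrom) if not a.acrocentric]
    whole = {
        e.location: e
        for e in events
        if e.scope == "arm" and e.position_label == "whole"
    }
    if set(whole) != set(arms) or not arms:
        return list(events)
    directions = {e.direction for e in whole.values()}
    if len(directions) != 1:
        return list(events)
    direction = directions.pop()
    tier = "called" if all(e.tier == "called" for e in whole.values()) else "faint"
    zyg = (
        "homozygous"
        if all(e.zygosity == "homozygous" for e in whole.values())
        else "heterozygous"
    )
    klass = "trisomy" if direction == "gain" else "monosomy"
    mean = float(np.mean([e.mean_log2 for e in whole.values()]))
    promoted = CNVEvent(
        "whole-chromosome", chrom, chrom, direction, zyg, klass, "whole", tier, mean
    )
    rest = [e for e in events if not (e.scope == "arm" and e.location in whole)]
    return [promoted] + rest


def detect_gene_amplification(
    profile: Log2Profile,
    bins: Sequence[Bin],
    genome: Genome,
    config: CallerConfig,
    *,
    min_gene_bins: int = 3,
) -> list[CNVEvent]:
    """Focal amplification: gene mean >= threshold and above its arm background.

    The background is the median log2 of the gene's arm excluding the gene's
    own bins, so a focal high-copy gene is compared against its surroundings
    rather than against a segment it dominates.
    """
    by_gene: dict[str, list[int]] = {}
    for i, b in enumerate(bins):
        if b.target_class == "on" and b.gene:
            by_gene.setdefault(b.gene, []).append(i)
    arm_idx = arm_indices(bins, genome)
    out = []
    for gene, idx in sorted(by_gene.items()):
        if len(idx) < min_gene_bins:
            continue
        gmean = float(np.mean(profile.values[idx]))
        if gmean < config.amplification_threshold:
            continue
        arm = genome.arm_of(bins[idx[0]].chrom, bins[idx[0]].start)
        others = np.setdiff1d(arm_idx[arm.name], idx)
        background = float(np.median(profile.values[others])) if len(others) else 0.0
        if gmean - background >= config.call_threshold:
            out.append(
                CNVEvent(
                    "gene", arm.chrom, gene, "gain", "heterozygous",
                    "amplification", "", "called", gmean,
                )
            )
    return out


def call_sample(
    bins: Sequence[Bin],
    genome: Genome,
    sample: DepthProfile,
    reference: ReferenceProfile,
    config: CallerConfig = CallerConfig(),
    policy: SensitivityPolicy = SensitivityPolicy(),
    vaf: Optional[float] = None,
) -> CNVEventSet:
    """End-to-end call: normalize, segment, call, label, aggregate, amplify."""
    profile = normalize_bins(sample, reference, config.pseudo)
    idx = arm_indices(bins, genome)
    all_segments: list[Segment] = []
    events: list[CNVEvent] = []
    by_chrom: dict[str, list[CNVEvent]] = {}
    for arm_name in sorted(idx, key=lambda a: list(idx).index(a)):
        ai = idx[arm_name]
        segs = segment_arm(
            profile.values[ai], profile.dispersion[ai], config,
            arm_name=arm_name, offset=int(ai[0]),
        )
        all_segments.extend(segs)
        states = [call_segment(s, config) for s in segs]
        labeled = label_positions(arm_name, segs, states, config)
        for e in _arm_events(arm_name, labeled):
            by_chrom.setdefault(e.chrom, []).append(e)
    for chrom, evs in by_chrom.items():
        events.extend(aggregate_chromosome(chrom, evs, genome, config))
    events.extend(detect_gene_amplification(profile, bins, genome, config))
    return CNVEventSet(
        sample_id=sample.sample_id,
        events=events,
        segments=all_segments,
        detectability=policy.tier(vaf),
    )


def write_segments(
    eventset: CNVEventSet, bins: Sequence[Bin], config: CallerConfig, path: str | Path
) -> None:
    """SEG-style TSV: sample, chrom, start, end, n_bins, mean_log2, state."""
    rows = []
    for s in eventset.segments:
        rows.append(
            (
                eventset.sample_id,
                bins[s.start].chrom,
                bins[s.start].start,
                bins[s.end - 1].end,
                s.n_bins,
                round(s.mean_log2, 6),
                call_segment(s, config),
            )
        )
    pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_bins", "mean_log2", "state"]
    ).to_csv(path, sep="\t", index=False)
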
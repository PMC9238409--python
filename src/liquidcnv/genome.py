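"""Chromosome-arm model and synthetic targeted-panel layout.

Every other stage of the pipeline positions events against the arm table
defined here: a 24-chromosome genome with per-arm intervals, centromere
positions, and acrocentric flags (13, 14, 15, 21, 22).  Coordinates are
0-based, half-open throughout; the centromere base itself belongs to the q
arm, matching BED conventions used for bin I/O.

The packaged genome is a *synthetic scaled build*: arm lengths are
proportional to a real cytoband table but reduced ~100x so that whole-panel
simulations run in seconds.  Acrocentric p arms are modeled in the arm table
(so ISCN interpretation can name them) but carry no panel genes and no
off-target bins; copy-number events on them are unrepresentable, mirroring
real targeted panels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ACROCENTRIC = {"13", "14", "15", "21", "22"}
CHROMOSOMES = [str(c) for c in range(1, 23)] + ["X", "Y"]

ARM_TABLE_COLUMNS = ["chrom", "arm", "start", "end", "centromere", "acrocentric"]
BIN_TABLE_COLUMNS = ["chrom", "start", "end", "name", "target_class", "gene"]


class GenomeFormatError(ValueError):
    """Raised when an arm or bin table violates the format contract."""


@dataclass(frozen=True)
class ChromosomeArm:
    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int
    centromere_pos: int
    acrocentric: bool

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise GenomeFormatError(f"arm must be p or q, got {self.arm!r}")
        if not self.start < self.end:
            raise GenomeFormatError(
                f"{self.chrom}{self.arm}: start {self.start} must be < end {self.end}"
            )

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    chrom: str
    start: int
    end: int
    arm: ChromosomeArm

    def __post_init__(self) -> None:
        if not (self.arm.start <= self.start < self.end <= self.arm.end):
            raise GenomeFormatError(
                f"gene {self.symbol} [{self.start},{self.end}) not within arm "
                f"{self.arm.name} [{self.arm.start},{self.arm.end})"
            )


@dataclass(frozen=True)
class Bin:
    chrom: str
    start: int
    end: int
    target_class: str  # "on" | "off"
    gene: str = ""  # gene symbol for on-target bins, "" otherwise

    def __post_init__(self) -> None:
        if self.target_class not in ("on", "off"):
            raise GenomeFormatError(f"bad target_class {self.target_class!r}")
        if self.target_class == "on" and not self.gene:
            raise GenomeFormatError("on-target bin must reference a gene")
        if self.target_class == "off" and self.gene:
            raise GenomeFormatError("off-target bin must not reference a gene")


class Genome:
    """Ordered collection of chromosome arms with lookup helpers."""

    def __init__(self, arms: Sequence[ChromosomeArm]):
        order = {c: i for i, c in enumerate(CHROMOSOMES)}
        self.arms = sorted(arms, key=lambda a: (order.get(a.chrom, 99), a.arm))
        self._by_name = {a.name: a for a in self.arms}
        self._by_chrom: dict[str, list[ChromosomeArm]] = {}
        for a in self.arms:
            self._by_chrom.setdefault(a.chrom, []).append(a)
        self._validate()

    def _validate(self) -> None:
        for chrom, arms in self._by_chrom.items():
            if len(arms) == 2:
                p, q = arms
                if p.end != q.start or p.end != p.centromere_pos:
                    raise GenomeFormatError(
                        f"chromosome {chrom}: p-arm end ({p.end}) must equal q-arm "
                        f"start ({q.start}) and the centromere ({p.centromere_pos})"
                    )
            acro = chrom in ACROCENTRIC
            for a in arms:
                if a.acrocentric != (acro and a.arm == "p"):
                    raise GenomeFormatError(
                        f"arm {a.name}: acrocentric flag must be set exactly for "
                        f"the p arms of chromosomes {sorted(ACROCENTRIC)}"
                    )

    def __iter__(self):
        return iter(self.arms)

    def __len__(self) -> int:
        return len(self.arms)

    def arm(self, name: str) -> ChromosomeArm:
        return self._by_name[name]

    def chrom_arms(self, chrom: str) -> list[ChromosomeArm]:
        return self._by_chrom[chrom]

    def arm_of(self, chrom: str, pos: int) -> ChromosomeArm:
        """Containing arm of a position; the centromere base resolves to q.

        Positions on an acrocentric p arm raise, because the default panel
        models no bins there.
        """
        if chrom not in self._by_chrom:
            raise KeyError(f"unknown chromosome {chrom!r}")
        arms = self._by_chrom[chrom]
        lo = min(a.start for a in arms)
        hi = max(a.end for a in arms)
        if not lo <= pos < hi:
            raise ValueError(f"position {pos} outside chromosome {chrom} [{lo},{hi})")
        for a in arms:
            if a.start <= pos < a.end:
                if a.acrocentric:
                    raise ValueError(
                        f"position {pos} lies on acrocentric arm {a.name}; "
                        "no modeled p bins on acrocentric chromosomes"
                    )
                return a
        raise AssertionError("unreachable: arms tile the chromosome")


def load_arm_table(path: str | Path) -> Genome:
    """Read a chromosome-arm TSV into a :class:`Genome`.

    Expected columns: ``chrom  arm  start  end  centromere  acrocentric``.
    Raises :class:`GenomeFormatError` naming the offending row on a missing
    column, mismatched arm boundaries, or a mis-flagged acrocentric arm.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ARM_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GenomeFormatError(f"arm table {path}: missing column(s) {missing}")
    arms = []
    for i, row in df.iterrows():
        try:
            arms.append(
                ChromosomeArm(
                    chrom=str(row["chrom"]),
                    arm=str(row["arm"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    centromere_pos=int(row["centromere"]),
                    acrocentric=str(row["acrocentric"]).strip().lower()
                    in ("true", "1"),
                )
            )
        except (ValueError, TypeError) as exc:
            raise GenomeFormatError(f"arm table {path} row {i}: {exc}") from exc
    return Genome(arms)


def default_genome() -> Genome:
    """The packaged scaled synthetic genome (real arm proportions / 100)."""
    ref = importlib.resources.files("liquidcnv.data").joinpath("arms.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_arm_table(path)


def _panel_arms(genome: Genome, include_y: bool = False) -> list[ChromosomeArm]:
    """Arms eligible for panel genes: non-acrocentric, Y excluded by default."""
    return [
        a
        for a in genome
        if not a.acrocentric and (include_y or a.chrom != "Y")
    ]


def make_panel(
    n_genes: int,
    genome: Genome,
    seed: int,
    *,
    exon_bin_width: int = 150,
    min_bins_per_gene: int = 4,
    max_bins_per_gene: int = 8,
    off_bin_width: int = 10_000,
) -> tuple[list[PanelGene], list[Bin]]:
    """Lay out a synthetic targeted panel of ``n_genes`` genes plus bins.

    Genes are spread over every non-acrocentric autosome and X arm (each such
    arm receives at least one gene, the remainder allocated proportionally to
    arm length), deterministically under ``seed``.  Each gene contributes
    ``min_bins_per_gene``..``max_bins_per_gene`` contiguous on-target bins of
    ``exon_bin_width`` bp; off-target bins tile the inter-gene gaps at a fixed
    ``off_bin_width``.
    """
    arms = _panel_arms(genome)
    if n_genes < len(arms):
        raise ValueError(
            f"n_genes={n_genes} cannot cover all {len(arms)} non-acrocentric arms"
        )
    rng = np.random.default_rng(seed)

    lengths = np.array([len(a) for a in arms], dtype=float)
    counts = np.ones(len(arms), dtype=int)
    extra = n_genes - len(arms)
    if extra > 0:
        # proportional allocation of the remaining genes by arm length
        alloc = np.floor(extra * lengths / lengths.sum()).astype(int)
        counts += alloc
        short = n_genes - counts.sum()
        if short > 0:
            top = np.argsort(-lengths)[:short]
            counts[top] += 1

    genes: list[PanelGene] = []
    bins: list[Bin] = []
    gi = 0
    for arm, k in zip(arms, counts):
        n_bins = rng.integers(min_bins_per_gene, max_bins_per_gene + 1, size=k)
        spans = n_bins * exon_bin_width
        usable = len(arm) - int(spans.sum())
        if usable < 0:
            raise ValueError(f"arm {arm.name} too short for {k} genes")
        # gene start offsets: sorted random placement without overlap
        slack = np.sort(rng.integers(0, usable + 1, size=k))
        starts = arm.start + slack + np.concatenate(([0], np.cumsum(spans[:-1])))
        prev_end = arm.start
        for s, nb in zip(starts, n_bins):
            s = int(s)
            e = s + int(nb) * exon_bin_width
            symbol = f"G{gi + 1:03d}"
            genes.append(PanelGene(symbol, arm.chrom, s, e, arm))
            bins.extend(_tile_off(arm.chrom, prev_end, s, off_bin_width))
            for b in range(int(nb)):
                bs = s + b * exon_bin_width
                bins.append(Bin(arm.chrom, bs, bs + exon_bin_width, "on", symbol))
            prev_end = e
            gi += 1
        bins.extend(_tile_off(arm.chrom, prev_end, arm.end, off_bin_width))

    bins.sort(key=lambda b: (CHROMOSOMES.index(b.chrom), b.start))
    return genes, bins


def _tile_off(chrom: str, start: int, end: int, width: int) -> list[Bin]:
    out = []
    pos = start
    while pos + width <= end:
        out.append(Bin(chrom, pos, pos + width, "off"))
        pos += width
    return out


def uniform_bins(genome: Genome, bins_per_arm: int, *, include_y: bool = False) -> list[Bin]:
    """Evenly tiled off-target bins, ``bins_per_arm`` per modeled arm.

    A convenience layout for caller characterization runs where a fixed,
    arm-balanced bin count matters more than a realistic exon structure.
    Acrocentric p arms stay unmodeled, as in the default panel.
    """
    bins: list[Bin] = []
    for arm in genome:
        if arm.acrocentric or (arm.chrom == "Y" and not include_y):
            continue
        edges = np.linspace(arm.start, arm.end, bins_per_arm + 1).astype(int)
        for s, e in zip(edges[:-1], edges[1:]):
            if e > s:
                bins.append(Bin(arm.chrom, int(s), int(e), "off"))
    return bins


def bins_to_frame(bins: Iterable[Bin]) -> pd.DataFrame:
    rows = [
        (b.chrom, b.start, b.end, f"{b.chrom}:{b.start}-{b.end}", b.target_class, b.gene)
        for b in bins
    ]
    return pd.DataFrame(rows, columns=BIN_TABLE_COLUMNS)


def write_bin_table(bins: Iterable[Bin], path: str | Path) -> None:
    bins_to_frame(bins).to_csv(path, sep="\t", index=False)


def read_bin_table(path: str | Path) -> list[Bin]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    missing = [c for c in BIN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GenomeFormatError(f"bin table {path}: missing column(s) {missing}")
    return [
        Bin(str(r.chrom), int(r.start), int(r.end), str(r.target_class), str(r.gene))
        for r in df.itertuples()
    ]


def arm_indices(bins: Sequence[Bin], genome: Genome) -> dict[str, np.ndarray]:
    """Map arm name -> array of bin indices, in coordinate order.

    Total over on-panel bins: every bin maps to exactly one arm.
    """
    out: dict[str, list[int]] = {}
    for i, b in enumerate(bins):
        arm = genome.arm_of(b.chrom, b.start)
        out.setdefault(arm.name, []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}
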
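"""Paired NGS-vs-cytogenetics concordance and simulator sensitivity sweeps.

Pairs the two classifications sample by sample, applies the categories used
for cohort bookkeeping (abnormal-or-fusion / sole fusion / no metaphases /
normal karyotype), computes the agreement rate over evaluable pairs, and
runs tumor-fraction detection sweeps against the closed-form minimal
detectable fraction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .caller import CallerConfig, SensitivityPolicy, call_sample
from .genome import Genome, default_genome, uniform_bins
from .iscn import ImbalanceSet, net_imbalances, parse_karyotype, parse_ngs_shorthand
from .risk import RiskClass, RiskRuleSet, classify, default_rules
from .simulate import (
    SimEvent,
    SimSample,
    min_detectable_fraction,
    simulate_reference_pool,
    simulate_sample,
)
from .table2 import Table2Record, load_table2_fixture

CATEGORIES = ("abnormal_or_fusion", "sole_fusion", "no_metaphases", "normal")

#: canonical strings used when expanding the aggregate normal-karyotype row
NORMAL_NGS = "Normal"
NORMAL_KARYOTYPE = "46,XX[20]"


@dataclass
class ConcordanceRecord:
    sample_id: str
    ngs_class: RiskClass
    cyto_class: RiskClass
    category: str
    evaluable: bool
    agree: Optional[bool]  # defined only when evaluable
    ngs_abnormal: bool = False  # NGS side reported >= 1 event

    def __post_init__(self) -> None:
        assert self.evaluable == (self.cyto_class != RiskClass.NOT_EVALUABLE)
        assert (self.agree is not None) == self.evaluable


@dataclass
class CohortSummary:
    n_pairs: int
    n_abnormal_or_fusion: int
    n_sole_fusion: int
    n_no_metaphases: int
    n_normal_karyotype: int
    n_nometa_ngs_abnormal: int
    n_nometa_ngs_normal: int
    concordance_pct: Optional[float]  # over evaluable pairs; None if none

    def __post_init__(self) -> None:
        parts = (
            self.n_abnormal_or_fusion
            + self.n_sole_fusion
            + self.n_no_metaphases
            + self.n_normal_karyotype
        )
        assert parts == self.n_pairs, "category counts must partition the cohort"
        assert (
            self.n_nometa_ngs_abnormal + self.n_nometa_ngs_normal
            == self.n_no_metaphases
        )


def categorize_pair(ngs: ImbalanceSet, cyto: ImbalanceSet) -> str:
    """Cohort category of one pair.

    No-metaphases and sole-fusion status come from the cytogenetic side; a
    pair then counts as abnormal when either assay shows a clonal
    abnormality (the published tallies place NGS-only-abnormal pairs with
    normal karyotypes in the abnormal group), and normal otherwise.
    """
    if not cyto.evaluable:
        return "no_metaphases"
    if cyto.fusion_only:
        return "sole_fusion"
    if cyto.abnormality_count > 0 or not ngs.is_empty():
        return "abnormal_or_fusion"
    return "normal"


def _pair_agrees(
    ngs_class: RiskClass, cyto_class: RiskClass, ngs: ImbalanceSet, cyto: ImbalanceSet
) -> bool:
    if ngs_class == cyto_class:
        return True
    # a sole balanced fusion carries no dosage signal the panel could see:
    # "no loss/gain" against an empty NGS result counts as agreement
    pair = {ngs_class, cyto_class}
    if pair == {RiskClass.NO_LOSS_GAIN, RiskClass.INTERMEDIATE}:
        empty_side = ngs if ngs_class == RiskClass.INTERMEDIATE else cyto
        return empty_side.is_empty()
    return False


def evaluate_pair(
    sample_id: str,
    ngs_text: str,
    karyotype_text: str,
    genome: Genome,
    rules: RiskRuleSet,
) -> tuple[ConcordanceRecord, ImbalanceSet, ImbalanceSet]:
    ngs = parse_ngs_shorthand(ngs_text, genome)
    cyto = net_imbalances(parse_karyotype(karyotype_text), genome)
    ngs_class = classify(ngs, rules)
    cyto_class = classify(cyto, rules)
    evaluable = cyto.evaluable
    record = ConcordanceRecord(
        sample_id=sample_id,
        ngs_class=ngs_class,
        cyto_class=cyto_class,
        category=categorize_pair(ngs, cyto),
        evaluable=evaluable,
        agree=_pair_agrees(ngs_class, cyto_class, ngs, cyto) if evaluable else None,
    )
    return record, ngs, cyto


def cohort_summary_generic(records: Sequence[ConcordanceRecord]) -> CohortSummary:
    """Cohort bookkeeping for any collection of paired records."""
    counts = {c: 0 for c in CATEGORIES}
    agree = total_eval = 0
    for r in records:
        counts[r.category] += 1
    # ngs_class alone cannot distinguish an empty set from e.g. a single 12p
    # loss (both intermediate); the NGS-normal split uses the recorded flag
    nometa_abnormal = sum(
        1 for r in records if r.category == "no_metaphases" and r.ngs_abnormal
    )
    for r in records:
        if r.evaluable:
            total_eval += 1
            agree += bool(r.agree)
    return CohortSummary(
        n_pairs=len(records),
        n_abnormal_or_fusion=counts["abnormal_or_fusion"],
        n_sole_fusion=counts["sole_fusion"],
        n_no_metaphases=counts["no_metaphases"],
        n_normal_karyotype=counts["normal"],
        n_nometa_ngs_abnormal=nometa_abnormal,
        n_nometa_ngs_normal=counts["no_metaphases"] - nometa_abnormal,
        concordance_pct=round(100.0 * agree / total_eval, 10) if total_eval else None,
    )


def run_table2(
    fixture: Optional[Sequence[Table2Record]] = None,
    genome: Optional[Genome] = None,
    rules: Optional[RiskRuleSet] = None,
) -> tuple[list[ConcordanceRecord], CohortSummary]:
    """Classify and pair every fixture sample; expand the aggregate row.

    The aggregate normal row becomes 45 identical synthetic pairs (empty NGS
    result against a normal 20-cell karyotype).  Concordance is computed over
    evaluable pairs only: no-metaphases pairs have no karyotype class and are
    excluded from the denominator.
    """
    fixture = load_table2_fixture() if fixture is None else fixture
    genome = default_genome() if genome is None else genome
    rules = default_rules() if rules is None else rules
    records: list[ConcordanceRecord] = []
    for rec in fixture:
        if rec.is_aggregate:
            pairs = [
                (f"normal_{i + 1:02d}", NORMAL_NGS, NORMAL_KARYOTYPE)
                for i in range(rec.count)
            ]
        else:
            pairs = [(str(rec.sample), rec.ngs_cnv, rec.karyotype)]
        for sample_id, ngs_text, kar_text in pairs:
            record, ngs, _cyto = evaluate_pair(sample_id, ngs_text, kar_text, genome, rules)
            record.ngs_abnormal = not ngs.is_empty()
            records.append(record)
    return records, cohort_summary_generic(records)


def report_json(records: Sequence[ConcordanceRecord], summary: CohortSummary) -> str:
    """Deterministic JSON report (stable key order, no float drift)."""
    payload = {
        "summary": asdict(summary),
        "records": [
            {
                "sample": r.sample_id,
                "ngs_class": r.ngs_class.value,
                "cyto_class": r.cyto_class.value,
                "category": r.category,
                "evaluable": r.evaluable,
                "agree": r.agree,
            }
            for r in records
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Simulator-based sensitivity sweep


@dataclass
class SweepRow:
    tumor_fraction: float
    called_rate: float
    faint_or_called_rate: float


@dataclass
class SweepResult:
    event: str
    tumor_copies: int
    rows: list[SweepRow]
    min_detectable_called: float  # closed-form f attaining the call threshold
    reps: int

    def crossing(self, level: float = 0.5) -> Optional[float]:
        """First f at which the called rate crosses ``level`` (linear
        interpolation between grid points); None if never crossed."""
        fs = [r.tumor_fraction for r in self.rows]
        ys = [r.called_rate for r in self.rows]
        for (f0, y0), (f1, y1) in zip(zip(fs, ys), zip(fs[1:], ys[1:])):
            if y0 < level <= y1:
                if y1 == y0:
                    return f1
                return f0 + (level - y0) * (f1 - f0) / (y1 - y0)
        if ys and ys[0] >= level:
            return fs[0]
        return None


_EVENT_SPECS = {
    # name -> (tumor_copies, event template on chromosome 5q / whole 8)
    "het-loss": (1, SimEvent(chrom="5", arm="q", tumor_copies=1)),
    "hom-loss": (0, SimEvent(chrom="5", arm="q", tumor_copies=0)),
    "trisomy": (3, SimEvent(chrom="8", tumor_copies=3)),
}


def sensitivity_sweep(
    event: str,
    f_grid: Sequence[float],
    reps: int,
    seed: int,
    config: CallerConfig = CallerConfig(),
    policy: SensitivityPolicy = SensitivityPolicy(),
    *,
    genome: Optional[Genome] = None,
    bins_per_arm: int = 200,
    noise_sigma: float = 0.15,
    n_normals: int = 20,
    mean_depth: float = 500.0,
) -> SweepResult:
    """Empirical detection rates over a tumor-fraction grid.

    For each grid point and replicate, implants the named event, simulates a
    depth profile against a pooled-normal reference, calls it, and records
    whether the implanted event was recovered as called (and as faint or
    called).  The closed-form minimal detectable fraction for the call
    threshold is reported alongside.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if event not in _EVENT_SPECS:
        raise ValueError(f"unknown event {event!r}; choose from {sorted(_EVENT_SPECS)}")
    copies, template = _EVENT_SPECS[event]
    genome = default_genome() if genome is None else genome
    bins = uniform_bins(genome, bins_per_arm)
    reference = simulate_reference_pool(
        bins, n_normals, mean_depth, noise_sigma, seed=seed
    )
    threshold = config.call_threshold if copies > 2 else -config.call_threshold
    rows: list[SweepRow] = []
    rng = np.random.default_rng(seed + 1)
    for f in f_grid:
        called = faint = 0
        for _ in range(reps):
            sim = SimSample(
                sample_id=f"{event}_f{f:.3f}",
                events=[template] if f > 0 else [],
                tumor_fraction=f,
                noise_sigma=noise_sigma,
                mean_depth=mean_depth,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            depths = simulate_sample(bins, sim, reference, genome)
            result = call_sample(bins, genome, depths, reference, config, policy)
            hit_called, hit_faint = _recovered(result, template, copies)
            called += hit_called
            faint += hit_faint
        rows.append(SweepRow(f, called / reps, faint / reps))
    return SweepResult(
        event=event,
        tumor_copies=copies,
        rows=rows,
        min_detectable_called=min_detectable_fraction(copies, threshold),
        reps=reps,
    )


def _recovered(result, template: SimEvent, copies: int) -> tuple[bool, bool]:
    direction = "gain" if copies > 2 else "loss"
    want_arm = f"{template.chrom}{template.arm}" if template.arm else None
    called = faint = False
    for e in result.events:
        if e.chrom != template.chrom or e.direction != direction:
            continue
        if want_arm is not None and e.scope == "arm" and e.location != want_arm:
            continue
        if e.tier == "called":
            called = True
        faint = True
    return called, faint
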
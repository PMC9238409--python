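# Methods

## Scope and data flow

The package models the *interpretation* layer of cfDNA copy-number analysis
on a targeted panel. Sequencing, UMI handling, alignment and point-mutation
calling are out of scope; depths arrive as binned counts, and mutation VAFs
are treated as given inputs. Two input dialects are projected into one
common currency (`ImbalanceSet`: determinate arm/whole-chromosome dosage
events + a count of dosage-indeterminate abnormalities + quality flags),
which a single ordered rule table maps to a myeloid risk class. That the
same rule table is applied to both sides of every pair is the point: the
concordance claim is about classification agreement, not string agreement.

## Genome and panel model

Coordinates are 0-based half-open; the centromere base belongs to the q arm
(BED convention). The packaged genome has 24 chromosomes × 2 arms with
lengths proportional to a real cytoband table scaled down ~100×, so
whole-panel simulations run in seconds; no real coordinates, gene
annotations or liftover are implied. Acrocentric p arms (13/14/15/21/22)
exist in the arm table — the karyotype parser needs to name them — but
carry no bins and never yield a determinate imbalance, mirroring real
panels; whole-chromosome events on acrocentrics are inferred from the q arm
alone. The synthetic default panel spreads 275 genes over every
non-acrocentric autosome and X arm (at least one gene per arm, the rest
proportional to arm length), 4–8 on-target bins of 150 bp per gene, with
off-target bins tiling inter-gene gaps at 10 kb. The Y chromosome is in the
arm table but excluded from the panel: the shorthand dialect does contain a
"+Y" call, but sex-chromosome dosage from cfDNA is confounded enough that
the caller stays autosome+X. A `uniform_bins` layout (equal bins per arm)
is provided for caller characterization where arm balance matters more than
exon realism.

## Simulator

Per-bin expected depth = mean depth × capture efficiency; on-target bins
capture 10× the off-target mean, with fixed per-bin lognormal wobble
(σ = 0.2 log2) representing probe efficiency differences. Noise is
multiplicative lognormal with σ on the log2 scale (default 0.15), chosen to
act directly in the domain the caller thresholds; no GC or mappability
structure is simulated, so passing recovery tests demonstrate threshold and
segmentation behavior, not robustness to real-world coverage waves. The
pooled reference stores the per-bin median and log2-ratio dispersion over
(default) 20 normals at 500× mean depth — depth and pool size are
configuration, not claims. Tumor samples scale reference expectations by
`2^log2((2(1−f)+fc)/2)` inside implanted events; overlapping events are
rejected as ambiguous. The VAF link `f = 2·VAF` assumes a heterozygous
autosomal driver in a diploid clone.

## Caller

Per-bin `log2((depth+1)/(reference+1))`, median-centered per sample (the
pseudo-count guarantees finiteness; centering removes library-size scale).
Segmentation is recursive binary splitting *within* arms — segments never
cross centromeres, because the interpretation vocabulary is arm-scoped —
accepting a split when the pooled two-sample t statistic's p-value survives
Bonferroni correction over the candidate breakpoints (α = 1e−3 per arm,
min 5 bins per segment; ties broken leftmost; zero-variance splits accept
iff the means differ). Calling is boundary-inclusive: mean ≥ +0.4 → gain,
≤ −1.50 → homozygous loss, ≤ −0.4 → loss. Otherwise a segment whose
z-score (mean over dispersion/√n) reaches 4.0 is reported `faint`. The
two-tier design keeps the hard threshold semantics exact while still
surfacing dilute events a reviewer could see by eye; faint events are never
counted as called anywhere downstream. A single called segment covering
≥ 90% of its arm is "whole" (the 10% slack tolerates edge-bin noise while
still distinguishing whole-arm from sub-arm events); two or more called
segments on one arm get proximal/distal labels by centromere distance —
the rule is distance-based, not sign-based. Matched whole-arm events of one
direction promote to monosomy/trisomy. Gene amplification requires a gene
mean ≥ +1.0 *and* ≥ 0.4 above the median of its arm excluding the gene's
own bins; the exclusion makes the comparison meaningful when the focal
event forms its own segment.

## Karyotype and shorthand parsing

The grammar targets the dialect of real clinical reports, not textbook
ISCN: space-written modal ranges ("46 48,XX"), a period standing for the
comma ("46.xx"), stray spaces before parenthesis groups, and malformed
derivative tokens all occur in the packaged corpus. The parser therefore
degrades unknown constructs to indeterminate-with-warning instead of
rejecting; warnings are bounded (≤10) over the corpus, and every token's
verbatim `raw` is preserved. Clone separators are "/" outside parentheses;
abnormality separators are commas only, since ";" appears *inside*
malformed tokens. `idem` inherits the stemline clone; `sl`/`slx2` is a
ploidy modifier, not an abnormality; constitutional findings ("XYY?c") are
excluded from abnormality counts; a marker-chromosome group ("+2 5mar")
counts once and raises an amplification-possible flag, reflecting that
sequencing resolves markers as gene amplifications.

Dosage semantics: `+N`/`−N` whole-chromosome; `del`/`dup` arm loss/gain;
`i(17)(q10)` = 17q gain + 17p loss (acrocentric p suppressed); `idic` as
`i` plus distal loss of the cited arm; `dic(A;B)` loses distal to both
breakpoints; rings count as whole-chromosome loss; whole-arm derivatives
(`der(1;7)(q10;p10)`, directly or via a cited t component) lose the uncited
arms; derivatives with cited `del` components contribute those deletions;
`add`/`ins`/`mar`/`inc` and balanced-looking derivatives are indeterminate;
`t`/`inv` are balanced fusions with no dosage effect. `add` is kept
strictly indeterminate even though distal loss is plausible — the corpus
contains a tetraploid add×2 karyotype paired with a normal NGS result, and
any determinate reading would manufacture a false disagreement.
Whole-chromosome events subsume same-direction arm events on dedup;
opposite directions coexist.

## Risk rule engine

Ordered, first-match-wins, total (a default clause is mandatory):
not-evaluable → no metaphases; sole balanced fusion → "no loss/gain";
complexity score (determinate + 1.0 × indeterminate) ≥ 3 → complex; any of
{−7 or 7q−, 17p− or −17, amplification-or-marker, CDKN2A/B-annotated 9p−}
→ poor; anything else, including a normal result, → intermediate. Both the
threshold and the indeterminate weight are exposed in `rules.yaml` because
published per-case labels are not consistent with any single counting rule
(cohorts contain 7-abnormality "poor" cases alongside 4-abnormality
"complex" ones); the packaged defaults were chosen as the configuration
under which NGS- and karyotype-derived classes agree on every evaluable
pair of the packaged corpus, with label-forced sentinel rows reproduced
exactly. Indeterminate abnormalities count toward complexity but never
trigger the poor rule except through the marker/amplification flag.
"No loss/gain" is kept distinct from "intermediate" because clinical
reports print both; concordance treats a sole-fusion "no loss/gain" against
an empty NGS result as agreement, since a fusion-blind dosage panel cannot
see a balanced rearrangement.

## Concordance and cohort bookkeeping

Pair categories: no-metaphases (culture failure, cytogenetics side), sole
fusion, abnormal-or-fusion when *either* side shows a clonal abnormality,
else normal. The either-side rule matters: pairs where NGS finds an event
against a normal karyotype belong in the abnormal tally. Concordance is
computed over evaluable pairs only — no-metaphases pairs have no karyotype
class and are excluded from the denominator (81 of 89 in the packaged
cohort). The aggregate normal row is expanded to 45 identical synthetic
pairs (empty NGS vs "46,XX[20]"); individual strings are not recoverable
from a printed tally. The fixture run is fully deterministic (byte-identical
JSON across runs).

## Problem sizes and numerical choices

Characterization runs use the uniform 200-bins/arm layout (8,200 bins),
σ = 0.15, 20-normal references at 500×: caller recovery uses 100 samples
with single implanted events at f = 0.9; the detection sweep uses 20
replicates per grid point (50 for the dilute-trisomy check); segmentation
is verified against an exhaustive-search oracle on 250 random 8–12-bin
arms with min 2 bins per segment and α = 0.05 so that splits actually
occur at that size. These sizes give stable rates in seconds while leaving
the asserted margins (sensitivity ≥ 0.95, crossing within ±0.05 of the
closed form) comfortably wide.

## Known limitations

Ratio-only data: tetraploidy and other balanced genome doublings are
invisible, as are translocations and fusions (by panel design); no BAF or
purity/ploidy joint modeling; band-level ISCN arithmetic beyond arm
assignment is not attempted; the simulator's noise is i.i.d. per bin, so
segmentation performance on autocorrelated real coverage will be worse than
the synthetic figures; the closed-form detectability fractions assume the
event spans enough bins that segment-mean noise is negligible.
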
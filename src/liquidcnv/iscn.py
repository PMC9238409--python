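"""Parser for cytogenetic report strings and NGS copy-number shorthand.

Two text dialects feed the risk comparison: conventional karyotype reports
in (loose) ISCN nomenclature — clones separated by "/", abnormality tokens
like ``del(5)(q13q33)``, ``+mar``, ``i(17)(q10)``, cell counts in brackets —
and the compact NGS shorthand used for cfDNA calls (``5q-``, ``monosomy 7``,
``21q+(amplification)``).  Both are projected into a common
:class:`ImbalanceSet`: determinate arm/whole-chromosome gains and losses,
a count of dosage-indeterminate abnormalities, and quality flags.

The grammar deliberately targets the dialect as printed in clinical reports,
not textbook ISCN: modal ranges written with a space instead of "~"
(``46 48,XX``), lower-case ``46.xx``, stray spaces inside tokens, and
malformed derivatives are all accepted via permissive fallbacks that degrade
to indeterminate-with-warning rather than reject.  Dosage semantics follow
standard cytogenetic reading: ``+N``/``-N`` are whole-chromosome gain/loss,
``del``/``dup`` arm-level loss/gain, ``i(17)(q10)`` gains one arm and loses
the other, ``dic`` loses the material distal to both breakpoints, ring
chromosomes count as loss of the chromosome, while ``add``/``mar``/``ins``
contribute unknown material and stay indeterminate.  Acrocentric p arms
(13/14/15/21/22) never yield a determinate imbalance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .genome import ACROCENTRIC, Genome

NO_METAPHASES = "no_metaphases"
LIMITED_STUDY = "limited_study"
INCOMPLETE_STUDY = "incomplete_study"

_FLAG_PATTERNS = {
    NO_METAPHASES: re.compile(r"no\s+metaphases\s+detected", re.I),
    LIMITED_STUDY: re.compile(r"limited\s+(?:study|analysis)", re.I),
    INCOMPLETE_STUDY: re.compile(r"incomplete\s+study", re.I),
}

_CHROM = r"(?:\d{1,2}|X|Y)"


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class Imbalance:
    """One determinate dosage change: an arm or whole chromosome, signed."""

    chrom: str
    region: str  # "p" | "q" | "chrom"
    direction: str  # "gain" | "loss"
    zygosity: str = "heterozygous"
    amplification: bool = False
    genes: tuple[str, ...] = ()
    position: str = ""  # "" | "proximal" | "distal"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.chrom, self.region, self.direction)


@dataclass
class Abnormality:
    kind: str  # del|add|der|dup|inv|t|ins|i|idic|dic|r|mar|gain|loss|other|inc
    chromosomes: tuple[str, ...]
    bands: str
    raw: str  # verbatim token, reproduced exactly
    multiplier: int = 1
    imbalances: tuple[Imbalance, ...] = ()
    indeterminate: bool = False
    fusion: bool = False
    constitutional: bool = False
    warning: Optional[str] = None


@dataclass
class KaryotypeClone:
    modal_number: tuple[Optional[int], Optional[int]]
    sex_designation: str
    abnormalities: list[Abnormality]
    cell_count: int
    composite: bool = False
    idem: bool = False
    stemline_multiplier: int = 1  # sl / slx2 ploidy modifier, not an abnormality
    raw: str = ""

    @property
    def is_normal(self) -> bool:
        return not self.abnormalities and not self.idem


@dataclass
class KaryotypeReport:
    clones: list[KaryotypeClone]
    flags: set[str]
    raw: str
    warnings: list[str] = field(default_factory=list)


@dataclass
class ImbalanceSet:
    """Common currency into which both karyotypes and NGS calls project."""

    determinate: list[Imbalance]
    indeterminate_count: int
    abnormality_count: int
    fusion_only: bool
    evaluable: bool
    amplification_possible: bool = False
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def build(cls, determinate: Iterable[Imbalance], **kw) -> "ImbalanceSet":
        return cls(determinate=dedup_imbalances(determinate), **kw)

    @property
    def determinate_count(self) -> int:
        return len(self.determinate)

    def is_empty(self) -> bool:
        return self.determinate_count == 0 and self.indeterminate_count == 0

    def has_amplification(self) -> bool:
        return self.amplification_possible or any(
            i.amplification for i in self.determinate
        )

    def has_loss(self, chrom: str, region: str) -> bool:
        """Loss of an arm, counting a whole-chromosome loss as covering it."""
        for i in self.determinate:
            if i.chrom == chrom and i.direction == "loss":
                if region == "chrom" or i.region in (region, "chrom"):
                    return True
        return False


def dedup_imbalances(imbalances: Iterable[Imbalance]) -> list[Imbalance]:
    """Region-deduplicate: a whole-chromosome event subsumes same-direction
    arm events on that chromosome; homozygous annotations are kept."""
    seen: dict[tuple, Imbalance] = {}
    for im in imbalances:
        prev = seen.get(im.key)
        if prev is None:
            seen[im.key] = im
        elif im.zygosity == "homozygous" and prev.zygosity != "homozygous":
            seen[im.key] = replace(prev, zygosity="homozygous")
    whole = {(c, d) for (c, r, d) in seen if r == "chrom"}
    out = []
    for (c, r, d), im in seen.items():
        if r != "chrom" and (c, d) in whole:
            continue
        out.append(im)
    return out


# ---------------------------------------------------------------------------
# Karyotype tokenization


def _split_outside_parens(s: str, seps: str) -> list[str]:
    parts, depth, cur = [], 0, []
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        if ch in seps and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return [p for p in (p.strip() for p in parts) if p]


def karyotype_flags(raw: str) -> set[str]:
    """Quality flags detected case-insensitively anywhere in the string."""
    return {name for name, pat in _FLAG_PATTERNS.items() if pat.search(raw)}


def tokenize_karyotype(raw: str) -> tuple[list[str], set[str]]:
    """Split a report into clone strings and quality flags.

    Clones separate on "/" outside parentheses; flag phrases are removed
    before splitting.  A no-metaphases report yields zero clones.
    """
    flags = karyotype_flags(raw)
    body = raw
    for pat in _FLAG_PATTERNS.values():
        body = pat.sub("", body)
    if NO_METAPHASES in flags:
        return [], flags
    clones = _split_outside_parens(body, "/")
    clones = [c.strip().strip(",").strip() for c in clones]
    return [c for c in clones if c], flags


_CELLS_RE = re.compile(r"\[(cp)?(\d+)\]\s*$")
_MODAL_RE = re.compile(r"^(\d+)(?:\s+(\d+))?$")
_SEX_RE = re.compile(r"^[XYxy?]+c?$")
_MAR_RE = re.compile(r"^\+?(\d+)?(?:\s+(\d+))?\s*mar$")


def parse_clone(
    clone: str, stemline: Optional[KaryotypeClone] = None
) -> KaryotypeClone:
    """Parse one clone string into modal number, sex, and abnormality tokens.

    ``idem`` inherits the stemline clone's abnormalities; ``sl``/``slx2`` is
    a ploidy modifier, not an abnormality; the modal number may be a
    space-written range.  Unparseable tokens degrade to kind="other" with a
    warning, never a crash.
    """
    raw = clone
    composite = False
    cells = 1
    m = _CELLS_RE.search(clone)
    if m:
        composite = m.group(1) == "cp"
        cells = int(m.group(2))
        clone = clone[: m.start()].strip()
    # "46.xx" — period standing for the comma after the modal number
    clone = re.sub(r"^(\d+(?:\s+\d+)?)\.\s*", r"\1,", clone)
    # "," is the only abnormality separator: ";" occurs inside malformed
    # derivative tokens at top level, e.g. "der(19)ins(19);?(q13.1);?"
    tokens = _split_outside_parens(clone, ",")

    modal: tuple[Optional[int], Optional[int]] = (None, None)
    sex = ""
    abns: list[Abnormality] = []
    idem = False
    sl_mult = 1
    warnings: list[str] = []

    rest = tokens
    if rest:
        m = _MODAL_RE.match(rest[0])
        if m:
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            modal = (lo, hi)
            rest = rest[1:]
    if rest and _SEX_RE.match(rest[0]):
        sex = rest[0]
        rest = rest[1:]

    for tok in rest:
        low = tok.lower().replace(" ", "")
        m = re.fullmatch(r"(idem|sl)(?:x(\d+))?", low)
        if m:
            mult = int(m.group(2)) if m.group(2) else 1
            if m.group(1) == "idem":
                idem = True
                sl_mult = mult
            else:
                sl_mult = mult
            continue
        abns.append(parse_abnormality(tok))

    if idem and stemline is not None:
        abns = list(stemline.abnormalities) + abns

    return KaryotypeClone(
        modal_number=modal,
        sex_designation=sex,
        abnormalities=abns,
        cell_count=cells,
        composite=composite,
        idem=idem,
        stemline_multiplier=sl_mult,
        raw=raw,
    )


def parse_karyotype(raw: str) -> KaryotypeReport:
    """Tokenize and parse a full report; idem clones inherit the stemline."""
    clone_strings, flags = tokenize_karyotype(raw)
    clones: list[KaryotypeClone] = []
    stemline: Optional[KaryotypeClone] = None
    warnings: list[str] = []
    seen_warned: set[str] = set()
    for cs in clone_strings:
        clone = parse_clone(cs, stemline=stemline)
        if stemline is None and clone.abnormalities:
            stemline = clone
        for a in clone.abnormalities:
            # idem clones inherit stemline tokens; warn once per raw token
            if a.warning and a.raw not in seen_warned:
                warnings.append(a.warning)
                seen_warned.add(a.raw)
        clones.append(clone)
    return KaryotypeReport(clones=clones, flags=flags, raw=raw, warnings=warnings)


# ---------------------------------------------------------------------------
# Abnormality parsing and dosage interpretation


def _arm_from_bands(bands: str) -> Optional[str]:
    m = re.search(r"[pq]", bands)
    return m.group(0) if m else None


def parse_abnormality(token: str) -> Abnormality:
    """Structural parse of one abnormality token (no dosage semantics yet).

    The verbatim token is preserved in ``raw``; parsing works on a
    whitespace-normalized copy (clinical reports scatter spaces before
    parenthesis groups).
    """
    raw = token
    t = re.sub(r"\s+(?=\()", "", token.strip())
    mult = 1
    m = re.search(r"x(\d+)$", t)
    if m:
        mult = int(m.group(1))
        t = t[: m.start()]

    if t.lower() == "inc":
        return Abnormality("inc", (), "", raw, mult, indeterminate=True)

    m = _MAR_RE.match(t)
    if m:
        return Abnormality("mar", (), "", raw, mult, indeterminate=True)

    m = re.fullmatch(rf"([+-])({_CHROM})", t)
    if m:
        kind = "gain" if m.group(1) == "+" else "loss"
        return Abnormality(kind, (m.group(2),), "", raw, mult)

    # typo fallback: "1-18" read as loss of 18, flagged
    m = re.fullmatch(rf"\d+-({_CHROM})", t)
    if m:
        return Abnormality(
            "loss", (m.group(1),), "", raw, mult,
            warning=f"token {raw!r}: read as loss of chromosome {m.group(1)}",
        )

    if t == "+r":
        return Abnormality("r", (), "", raw, mult, indeterminate=True)

    m = re.match(
        rf"^([+-])?(idic|dic|del|dup|add|inv|ins|der|i|r|t)\(({_CHROM}?(?:;{_CHROM}?)*)\)",
        t,
    )
    if m:
        kind = m.group(2)
        chroms = tuple(c for c in m.group(3).split(";") if c)
        tail = t[m.end():]
        bands_m = re.match(r"^\(([^()]*)\)", tail)
        bands = bands_m.group(1) if bands_m else ""
        warn = None
        if not chroms:
            warn = f"token {raw!r}: unidentifiable {kind} material"
        return Abnormality(kind, chroms, bands, raw, mult, warning=warn)

    return Abnormality(
        "other", (), "", raw, mult, indeterminate=True,
        warning=f"unrecognized abnormality token {raw!r}",
    )


def _arm_loss(chrom: str, arm: str, genome: Genome) -> list[Imbalance]:
    if arm == "p" and chrom in ACROCENTRIC:
        return []  # acrocentric p arms carry no dosage-relevant material
    return [Imbalance(chrom, arm, "loss")]


def _arm_gain(chrom: str, arm: str, genome: Genome) -> list[Imbalance]:
    if arm == "p" and chrom in ACROCENTRIC:
        return []
    return [Imbalance(chrom, arm, "gain")]


def interpret_abnormality(abn: Abnormality, genome: Genome) -> Abnormality:
    """Attach the deterministic dosage interpretation to an abnormality.

    Determinate kinds yield :class:`Imbalance` entries; ``add``, ``mar``,
    ``ins``, malformed derivatives and unknown kinds stay indeterminate;
    balanced translocations and inversions carry no imbalance but are
    fusion-relevant.
    """
    kind, chroms, bands = abn.kind, abn.chromosomes, abn.bands
    imbalances: list[Imbalance] = []
    indeterminate = abn.indeterminate
    fusion = False
    warning = abn.warning

    if kind == "gain" and chroms:
        imbalances = [Imbalance(chroms[0], "chrom", "gain")]
    elif kind == "loss" and chroms:
        imbalances = [Imbalance(chroms[0], "chrom", "loss")]
    elif kind == "del" and chroms:
        arm = _arm_from_bands(bands)
        if arm:
            imbalances = _arm_loss(chroms[0], arm, genome)
        else:
            indeterminate = True
            warning = warning or f"del without arm-resolvable bands: {abn.raw!r}"
    elif kind == "dup" and chroms:
        arm = _arm_from_bands(bands)
        if arm:
            imbalances = _arm_gain(chroms[0], arm, genome)
        else:
            indeterminate = True
    elif kind == "i" and chroms:
        arm = _arm_from_bands(bands)
        if arm:
            other = "q" if arm == "p" else "p"
            imbalances = _arm_gain(chroms[0], arm, genome) + _arm_loss(
                chroms[0], other, genome
            )
        else:
            indeterminate = True
    elif kind == "idic" and chroms:
        # isodicentric: the cited arm is lost distal to the break, the other
        # arm is doubled — same dosage shape as an isochromosome
        arm = _arm_from_bands(bands)
        if arm:
            other = "q" if arm == "p" else "p"
            imbalances = _arm_gain(chroms[0], other, genome) + _arm_loss(
                chroms[0], arm, genome
            )
        else:
            indeterminate = True
    elif kind == "dic" and len(chroms) == 2:
        parts = bands.split(";") if bands else []
        for chrom, band in zip(chroms, parts + [""] * (2 - len(parts))):
            arm = _arm_from_bands(band)
            if arm:
                imbalances += _arm_loss(chrom, arm, genome)
            else:
                indeterminate = True
    elif kind == "r":
        # ring chromosome: treated as loss of the chromosome's distal
        # material, i.e. a whole-chromosome-level loss
        if chroms:
            imbalances = [Imbalance(chroms[0], "chrom", "loss")]
        else:
            indeterminate = True
    elif kind == "der":
        imbalances, indeterminate, fusion, warning = _interpret_der(
            abn, genome, indeterminate, warning
        )
    elif kind in ("t", "inv"):
        fusion = True
    elif kind in ("add", "ins", "inc", "mar", "other"):
        indeterminate = True
    else:
        indeterminate = True
        warning = warning or f"unknown abnormality kind {kind!r} in {abn.raw!r}"

    return replace(
        abn,
        imbalances=tuple(imbalances),
        indeterminate=indeterminate or (not imbalances and not fusion),
        fusion=fusion,
        warning=warning,
    )


_COMPONENT_RE = re.compile(
    rf"(del|dup|add|ins|inv|t)\(({_CHROM}?(?:;{_CHROM}?)*)\)(?:\(([^()]*)\))?"
)
_WHOLE_ARM_RE = re.compile(r"^([pq])10;([pq])10$")


def _interpret_der(
    abn: Abnormality, genome: Genome, indeterminate: bool, warning: Optional[str]
):
    """Derivative chromosomes: whole-arm translocations lose the uncited
    arms; cited del/dup components contribute their own interpretation;
    everything else about the derivative stays indeterminate."""
    imbalances: list[Imbalance] = []
    fusion = False
    t = re.sub(r"\s+(?=\()", "", abn.raw)
    if not abn.chromosomes:
        return [], True, False, warning

    head = re.match(rf"^\+?der\(({_CHROM})(?:;({_CHROM}))?\)(?:\(([^()]*)\))?", t)
    tail = t[head.end():] if head else ""

    if head and head.group(2):
        # der(A;B): whole-arm translocation if centromeric bands are cited
        # either directly or through a t() component
        bands = head.group(3) or ""
        if not _WHOLE_ARM_RE.match(bands):
            comp = _COMPONENT_RE.search(tail)
            if comp and comp.group(1) == "t" and comp.group(3):
                m = _WHOLE_ARM_RE.match(comp.group(3))
                bands = comp.group(3) if m else bands
        m = _WHOLE_ARM_RE.match(bands)
        if m:
            for chrom, kept in zip(abn.chromosomes, m.groups()):
                lost = "q" if kept == "p" else "p"
                imbalances += _arm_loss(chrom, lost, genome)
            return imbalances, False, False, warning
        return [], True, False, warning

    any_indet_component = False
    for comp in _COMPONENT_RE.finditer(tail):
        ckind, cchroms, cbands = comp.group(1), comp.group(2), comp.group(3) or ""
        arm = _arm_from_bands(cbands)
        if ckind == "del" and arm:
            imbalances += _arm_loss(cchroms.split(";")[0], arm, genome)
        elif ckind == "dup" and arm:
            imbalances += _arm_gain(cchroms.split(";")[0], arm, genome)
        else:
            any_indet_component = True
    indeterminate = any_indet_component or not imbalances
    return imbalances, indeterminate, fusion, warning


# ---------------------------------------------------------------------------
# Report-level projection


def net_imbalances(report: KaryotypeReport, genome: Genome) -> ImbalanceSet:
    """Union of determinate imbalances over all non-normal clones.

    The abnormality count tallies distinct clonal abnormality tokens (a
    marker-chromosome group counts once; constitutional findings and ploidy
    modifiers are excluded).  ``fusion_only`` is true when the only clonal
    finding is one or more balanced fusions.  A no-metaphases report is not
    evaluable.
    """
    if NO_METAPHASES in report.flags:
        return ImbalanceSet.build(
            determinate=[], indeterminate_count=0, abnormality_count=0,
            fusion_only=False, evaluable=False,
        )
    determinate: list[Imbalance] = []
    indeterminate_raws: set[str] = set()
    abnormality_raws: set[str] = set()
    fusions = 0
    amp_possible = False
    warnings = list(report.warnings)
    for clone in report.clones:
        for abn in clone.abnormalities:
            interp = interpret_abnormality(abn, genome)
            if interp.constitutional:
                continue
            abnormality_raws.add(interp.raw)
            determinate.extend(interp.imbalances)
            if interp.kind == "mar":
                amp_possible = True
            if interp.fusion:
                fusions += 1
            elif interp.indeterminate and not interp.imbalances:
                indeterminate_raws.add(interp.raw)
    det = dedup_imbalances(determinate)
    fusion_only = fusions > 0 and not det and not indeterminate_raws
    return ImbalanceSet(
        determinate=det,
        indeterminate_count=len(indeterminate_raws),
        abnormality_count=len(abnormality_raws),
        fusion_only=fusion_only,
        evaluable=True,
        amplification_possible=amp_possible,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# NGS shorthand


_NORMAL_RE = re.compile(r"^\s*normal\s*\.?\s*$", re.I)
_WHOLE_RE = re.compile(rf"^([+-])({_CHROM})$")
_WORD_WHOLE_RE = re.compile(rf"^(monosomy|trisomy)\s+({_CHROM})$", re.I)
_ARM_EVENT_RE = re.compile(rf"^({_CHROM})([pq])([+-])?$")
_GENE_RE = re.compile(r"\b([A-Z][A-Z0-9]+(?:/[A-Z0-9]+)?)\b")
_GENE_STOP = {"CNV", "NGS"}


def parse_ngs_shorthand(text: str, genome: Genome) -> ImbalanceSet:
    """Parse the compact cfDNA CNV shorthand into an :class:`ImbalanceSet`.

    Comma/"and"-separated tokens; ``Xq-``/``Xq+`` arm events,
    ``+N``/``-N``/``monosomy N``/``trisomy N`` whole-chromosome events;
    parentheticals carry attributes — ``(amplification)``,
    ``(bi-allelic ...)``, ``(proximal)``/``(distal)``, gene lists.
    ``Normal`` means an empty set.  Unrecognized tokens are retained raw
    with a warning.
    """
    text = text.strip()
    if _NORMAL_RE.match(text) or "no chromosomal abnormalities" in text.lower():
        return ImbalanceSet.build(
            determinate=[], indeterminate_count=0, abnormality_count=0,
            fusion_only=False, evaluable=True,
        )
    tokens: list[str] = []
    for part in _split_outside_parens(text, ",;"):
        tokens.extend(_split_and(part))
    determinate: list[Imbalance] = []
    indeterminate = 0
    warnings: list[str] = []
    amp_possible = False
    n_tokens = 0
    for tok in tokens:
        tok = tok.strip().rstrip(".").strip()
        if not tok:
            continue
        n_tokens += 1
        if tok.lower() in ("others", "other"):
            indeterminate += 1
            continue
        base, attrs = _split_attrs(tok)
        base = re.sub(r"^(?:gain|loss):", "", base).strip()
        amp = "amplification" in attrs.lower()
        homozygous = "bi-allelic" in attrs.lower() or "biallelic" in attrs.lower()
        position = ""
        for p in ("proximal", "distal"):
            if p in attrs.lower():
                position = p
        genes = tuple(
            g for g in _GENE_RE.findall(attrs)
            if g not in _GENE_STOP and not g.isdigit()
        )
        parsed = _parse_shorthand_base(base, amp, homozygous, genes, position)
        if parsed is None:
            warnings.append(f"unrecognized NGS token {tok!r}")
            indeterminate += 1
            continue
        determinate.extend(parsed)
        if amp:
            amp_possible = True
        # a parenthetical may itself name an event, e.g. "-18 (bi-allelic 18p-)"
        inner = _ARM_EVENT_RE.match(attrs.replace("bi-allelic", "").strip())
        if homozygous and inner and inner.group(3):
            determinate.append(
                Imbalance(
                    inner.group(1), inner.group(2),
                    "gain" if inner.group(3) == "+" else "loss",
                    zygosity="homozygous",
                )
            )
    return ImbalanceSet.build(
        determinate=determinate,
        indeterminate_count=indeterminate,
        abnormality_count=n_tokens,
        fusion_only=False,
        evaluable=True,
        amplification_possible=amp_possible,
        warnings=warnings,
    )


def _split_and(part: str) -> list[str]:
    out, depth, cur = [], 0, []
    words = part.split(" ")
    pieces, buf = [], []
    for w in words:
        depth += w.count("(") - w.count(")")
        if w.lower() == "and" and depth == 0:
            pieces.append(" ".join(buf))
            buf = []
        else:
            buf.append(w)
    pieces.append(" ".join(buf))
    return [p for p in (p.strip() for p in pieces) if p]


def _split_attrs(tok: str) -> tuple[str, str]:
    m = re.match(r"^(.*?)\s*\((.*)\)\.?$", tok)
    if m:
        return m.group(1).strip(), m.group(2).strip()
    return tok, ""


def _parse_shorthand_base(
    base: str, amp: bool, homozygous: bool, genes: tuple[str, ...], position: str
) -> Optional[list[Imbalance]]:
    zyg = "homozygous" if homozygous else "heterozygous"
    m = _WORD_WHOLE_RE.match(base)
    if m:
        direction = "loss" if m.group(1).lower() == "monosomy" else "gain"
        return [Imbalance(m.group(2), "chrom", direction, zyg, amp, genes, position)]
    m = _WHOLE_RE.match(base)
    if m:
        direction = "gain" if m.group(1) == "+" else "loss"
        return [Imbalance(m.group(2), "chrom", direction, zyg, amp, genes, position)]
    m = _ARM_EVENT_RE.match(base)
    if m:
        sign = m.group(3)
        if sign is None:
            if not amp:  # bare arm token only meaningful with an attribute
                return None
            sign = "+"
        direction = "gain" if sign == "+" else "loss"
        return [Imbalance(m.group(1), m.group(2), direction, zyg, amp, genes, position)]
    if not base and (amp or genes):
        return []
    return None
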